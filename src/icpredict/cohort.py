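"""Synthetic multi-wave cohort generation.

Produces panel tables with the same schema the dataset builder consumes:
one row per subject-wave, waves two years apart, per-domain latent health
traits that decline over waves, instrument values emitted from the latents
through the inverse direction of the scoring maps plus observation noise,
and MCAR missingness with elevated rates for grip strength and SPPB (whose
real-world counterparts require qualified personnel and are sparsely
observed).

The latent-trait design makes next-wave IC predictable from current-wave
features by construction, which is what the prediction harness needs from a
test cohort. No attempt is made to match any real survey's marginal
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .datasets import DEFAULT_HORIZONS, SupervisedDataset
from .preprocessing import DataDictionary, build_feature_matrix, load_dictionary
from .scoring import DOMAINS

__all__ = ["CohortConfig", "simulate_cohort", "plant_linear_signal"]


class CohortConfigError(ValueError):
    pass


def _default_decline() -> dict:
    return {d: 0.03 for d in DOMAINS}


def _default_noise() -> dict:
    return {
        "sensory": 0.06,
        "sppb": 0.06,
        "moca": 0.05,
        "phq": 0.06,
        "sf12": 0.10,
        "iadl": 0.10,
        "ucla": 0.12,
        "lubben": 0.15,
        "eq5d": 0.10,
        "grip": 0.05,
        "bmi": 0.6,
    }


def _default_missing() -> dict:
    # grip/SPPB markedly sparser than questionnaire instruments
    return {
        "grip": 0.5,
        "sppb": 0.5,
        "sensory": 0.05,
        "moca": 0.05,
        "phq": 0.05,
        "sf12": 0.05,
        "iadl": 0.05,
        "ucla": 0.05,
        "lubben": 0.05,
        "eq5d": 0.05,
        "bmi": 0.05,
    }


@dataclass
class CohortConfig:
    n_subjects: int = 500
    n_waves: int = 4
    seed: int = 0
    baseline_age_range: Tuple[float, float] = (60.0, 85.0)
    latent_decline_per_wave: dict = field(default_factory=_default_decline)
    observation_noise_sd: dict = field(default_factory=_default_noise)
    missing_prob: dict = field(default_factory=_default_missing)
    dropout_prob_per_wave: float = 0.05

    def __post_init__(self) -> None:
        if self.n_waves < 2:
            raise CohortConfigError("n_waves must be >= 2")
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be >= 1")
        if not 0.0 <= self.dropout_prob_per_wave <= 1.0:
            raise CohortConfigError("dropout_prob_per_wave must be in [0, 1]")
        for key, p in self.missing_prob.items():
            if not 0.0 <= p <= 1.0:
                raise CohortConfigError(f"missing_prob[{key!r}]={p} outside [0, 1]")
        for key, sd in self.observation_noise_sd.items():
            if sd < 0:
                raise CohortConfigError(f"observation_noise_sd[{key!r}] must be >= 0")

    def without_missingness(self) -> "CohortConfig":
        cfg = CohortConfig(**asdict(self))
        cfg.missing_prob = {k: 0.0 for k in cfg.missing_prob}
        cfg.dropout_prob_per_wave = 0.0
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_age_range"] = list(self.baseline_age_range)
        return d


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


# instrument group -> wave-table columns
_GROUPS = {
    "sensory": ["hearing_left", "hearing_right", "vision_far", "vision_near"],
    "sppb": ["sppb_balance", "sppb_gait", "sppb_chair", "sppb_gait_time", "sppb_chair_time"],
    "moca": ["moca_total"],
    "phq": ["phq9_total"],
    "sf12": ["sf12_q1", "sf12_q2", "sf12_q3", "sf12_q4", "sf12_q5", "sf12_q6",
             "sf12_q8", "sf12_q10", "sf12_q11"],
    "iadl": ["iadl_q1", "iadl_q2", "iadl_q3", "iadl_q4", "iadl_q5", "iadl_q7", "iadl_q8"],
    "ucla": ["ucla_q1", "ucla_q2", "ucla_q4", "ucla_q11", "ucla_q14"],
    "lubben": ["lubben_q6", "lubben_q12"],
    "eq5d": ["eq5d_q1", "eq5d_q2", "eq5d_q4", "eq5d_q5"],
    "grip": ["grip_kg"],
    "bmi": ["bmi"],
}

_SF12_RANGES = {
    "sf12_q1": (1, 5), "sf12_q2": (1, 3), "sf12_q3": (1, 3), "sf12_q4": (1, 2),
    "sf12_q5": (1, 2), "sf12_q6": (1, 2), "sf12_q8": (1, 5), "sf12_q10": (1, 6),
    "sf12_q11": (1, 6),
}


def _ordinal_from_latent(rng, latent, lo, hi, noise_sd, higher_is_better=True):
    """Emit an integer item in [lo, hi] monotone in the latent trait."""
    level = latent if higher_is_better else 1.0 - latent
    noisy = _clip01(level + rng.normal(0.0, noise_sd, size=latent.shape))
    return np.rint(lo + (hi - lo) * noisy).astype(int)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a wave table; identical config (incl. seed) gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    n, w = config.n_subjects, config.n_waves
    noise = config.observation_noise_sd

    lo_age, hi_age = config.baseline_age_range
    baseline_age = rng.uniform(lo_age, hi_age, size=n)
    sex = rng.integers(0, 2, size=n)
    marital = rng.choice(
        ["married", "partnered", "single", "divorced", "separated", "widowed"],
        size=n, p=[0.45, 0.1, 0.1, 0.1, 0.05, 0.2],
    )
    education = rng.integers(1, 8, size=n)
    bmi0 = np.clip(rng.normal(27.0, 4.0, size=n), 16.0, 45.0)

    # correlated per-domain latents: shared frailty plus domain-specific part
    frailty = rng.normal(0.0, 1.0, size=n)
    latents0 = {}
    for d in DOMAINS:
        latents0[d] = _clip01(0.78 - 0.08 * frailty + rng.normal(0.0, 0.08, size=n))

    rows = {c: [] for c in ["subject_id", "wave_index", "age", "sex",
                            "marital_status", "education"]}
    frames = []
    for t in range(1, w + 1):
        lat = {d: _clip01(latents0[d] - config.latent_decline_per_wave[d] * (t - 1))
               for d in DOMAINS}
        df = pd.DataFrame({
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "wave_index": t,
            "age": baseline_age + 2.0 * (t - 1),
            "sex": sex,
            "marital_status": marital,
            "education": education,
            "bmi": np.clip(bmi0 + 0.1 * (t - 1)
                           + rng.normal(0.0, noise["bmi"], size=n), 12.0, 55.0),
        })

        z = lat["sensory"]
        for col in _GROUPS["sensory"]:
            df[col] = _ordinal_from_latent(rng, z, 1, 5, noise["sensory"])

        z = lat["locomotion"]
        sppb_total = np.rint(
            12 * _clip01(z + rng.normal(0.0, noise["sppb"], size=n))).astype(int)
        df["sppb_balance"] = np.minimum(sppb_total, 4)
        df["sppb_gait"] = np.clip(sppb_total - 4, 0, 4)
        df["sppb_chair"] = np.clip(sppb_total - 8, 0, 4)
        df["sppb_gait_time"] = np.clip(
            3.0 + 10.0 * (1 - z) + rng.normal(0.0, 0.8, size=n), 0.5, 60.0)
        df["sppb_chair_time"] = np.clip(
            8.0 + 20.0 * (1 - z) + rng.normal(0.0, 1.5, size=n), 1.0, 60.0)

        df["moca_total"] = np.rint(
            30 * _clip01(lat["cognition"] + rng.normal(0.0, noise["moca"], size=n))
        ).astype(int)
        df["phq9_total"] = np.rint(
            27 * _clip01(1.0 - lat["psychology"] + rng.normal(0.0, noise["phq"], size=n))
        ).astype(int)

        z_overall = np.mean([lat[d] for d in DOMAINS], axis=0)
        for col, (lo, hi) in _SF12_RANGES.items():
            if col == "sf12_q10":
                # energy item: 1 = most energetic, driven by vitality latent
                df[col] = _ordinal_from_latent(
                    rng, lat["vitality"], 1, 6, noise["sf12"], higher_is_better=False)
            else:
                df[col] = _ordinal_from_latent(
                    rng, z_overall, lo, hi, noise["sf12"], higher_is_better=False)
        for col in _GROUPS["iadl"]:
            df[col] = _ordinal_from_latent(
                rng, lat["locomotion"], 1, 3, noise["iadl"], higher_is_better=False)
        for col in _GROUPS["ucla"]:
            df[col] = _ordinal_from_latent(
                rng, lat["psychology"], 1, 4, noise["ucla"], higher_is_better=False)
        for col in _GROUPS["lubben"]:
            df[col] = _ordinal_from_latent(rng, lat["psychology"], 0, 5, noise["lubben"])
        for col in _GROUPS["eq5d"]:
            df[col] = _ordinal_from_latent(
                rng, z_overall, 1, 5, noise["eq5d"], higher_is_better=False)

        # grip kept in a range where the vitality composite does not saturate
        df["grip_kg"] = np.clip(
            11.0 * lat["vitality"] + rng.normal(0.0, noise["grip"] * 11.0, size=n),
            0.0, 90.0)
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)

    # monotone dropout: once out, out for good
    if config.dropout_prob_per_wave > 0:
        drop_draws = rng.random((n, w))
        out = np.zeros((n, w), dtype=bool)
        for t in range(1, w):
            out[:, t] = out[:, t - 1] | (drop_draws[:, t] < config.dropout_prob_per_wave)
        keep_mask = ~out.T.reshape(-1)  # frames stacked wave-major
        table = table[keep_mask].reset_index(drop=True)
    else:
        rng.random((n, w))  # keep stream alignment across configs

    # MCAR missingness per instrument group
    for group, cols in _GROUPS.items():
        p = config.missing_prob.get(group, 0.0)
        draws = rng.random(len(table))
        if p > 0:
            mask = draws < p
            cols_present = [c for c in cols if c in table.columns]
            table.loc[mask, cols_present] = np.nan

    table = table.sort_values(["subject_id", "wave_index"]).reset_index(drop=True)
    return table


def plant_linear_signal(
    config: CohortConfig,
    coefficients: Mapping[str, float],
    noise_sd: float,
    domain: str = "cognition",
    intercept: float = 0.5,
    dictionary: Optional[DataDictionary] = None,
    horizon: Optional[int] = None,
):
    """Generate a supervised dataset whose labels are exactly linear in the
    preprocessed wave-``t`` features plus Gaussian noise, clipped to [0, 1].

    ``coefficients`` maps expanded feature names (a subset) to generative
    weights; unnamed features have weight zero. Returns ``(dataset,
    metadata)`` where metadata records the generative parameters. Clipping
    mildly attenuates the signal at the boundaries; choose ``intercept``
    and weights so labels rarely hit 0 or 1 if exact linearity matters.
    """
    dictionary = dictionary or load_dictionary()
    horizon = DEFAULT_HORIZONS[domain] if horizon is None else int(horizon)
    cfg = config.without_missingness()
    table = simulate_cohort(cfg)
    feature_waves = table[table["wave_index"] <= cfg.n_waves - horizon]

    Xdf = build_feature_matrix(feature_waves.reset_index(drop=True), domain, dictionary)
    names = list(Xdf.columns)
    unknown = [k for k in coefficients if k not in names]
    if unknown:
        raise CohortConfigError(f"unknown feature names in coefficients: {unknown}")
    beta = np.array([float(coefficients.get(nm, 0.0)) for nm in names])

    rng = np.random.default_rng([cfg.seed, 0xC0FFEE])
    X = Xdf.to_numpy()
    y = np.clip(intercept + X @ beta + rng.normal(0.0, noise_sd, size=len(X)), 0.0, 1.0)

    ds = SupervisedDataset(
        domain=domain,
        horizon_waves=horizon,
        feature_names=names,
        X=X,
        y=y,
        subject_id=feature_waves["subject_id"].to_numpy(),
        wave_index=feature_waves["wave_index"].to_numpy(),
        n_rows_in=len(table),
    )
    metadata = {
        "intercept": float(intercept),
        "coefficients": {k: float(v) for k, v in coefficients.items()},
        "noise_sd": float(noise_sd),
        "seed": cfg.seed,
        "domain": domain,
        "horizon_waves": horizon,
        "n_examples": int(len(y)),
    }
    return ds, metadata
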