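"""Longitudinal supervised dataset construction.

Each supervised example pairs the preprocessed features of a subject at wave
``t`` with that subject's IC score in one domain at wave ``t + h``. Waves are
two years apart; the horizon ``h`` is 2 waves (four years) for locomotion and
vitality — whose instruments require qualified personnel and are collected
less often — and 1 wave (two years) for the other domains.

Labels are computed from raw (never imputed) instrument values; pairs whose
label wave is absent or whose label instruments are missing are dropped.
Feature completeness, by contrast, is judged after imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import (
    DataDictionary,
    MissingFeatureError,
    build_features,
    impute_features,
    load_dictionary,
)
from .scoring import DOMAINS, compute_profile

__all__ = [
    "InputError",
    "DEFAULT_HORIZONS",
    "SupervisedDataset",
    "label_wave",
    "score_table",
    "pair_waves",
    "summarize_dataset",
]

#: Prediction horizon in waves per domain (1 wave = 2 calendar years).
DEFAULT_HORIZONS = {
    "locomotion": 2,
    "sensory": 1,
    "psychology": 1,
    "cognition": 1,
    "vitality": 2,
}


class InputError(ValueError):
    pass


@dataclass
class SupervisedDataset:
    """Per-domain design matrix, labels, and provenance columns."""

    domain: str
    horizon_waves: int
    feature_names: list
    X: np.ndarray
    y: np.ndarray
    subject_id: np.ndarray
    wave_index: np.ndarray
    n_rows_in: int = 0
    n_dropped_missing_label: int = 0
    n_dropped_missing_features: int = 0

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_id)
        df.insert(1, "wave_index", self.wave_index)
        df["label"] = self.y
        return df


def label_wave(record, domain: str) -> Optional[float]:
    """IC score of ``domain`` at a (label) wave, or ``None`` when the
    domain's instruments are missing. Missingness propagates; it is never
    imputed at the label side."""
    profile = compute_profile(record)
    return getattr(profile, domain)


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``ic_<domain>`` columns computed row-wise from raw values."""
    out = table.copy()
    profiles = [compute_profile(rec) for rec in table.to_dict("records")]
    for domain in DOMAINS:
        out[f"ic_{domain}"] = [
            getattr(p, domain) if getattr(p, domain) is not None else np.nan
            for p in profiles
        ]
    return out


def _validate_panel(table: pd.DataFrame) -> None:
    if "subject_id" not in table.columns or "wave_index" not in table.columns:
        raise InputError("wave table requires subject_id and wave_index columns")
    keys = table[["subject_id", "wave_index"]]
    if keys.duplicated().any():
        raise InputError("duplicated subject-wave rows")
    for _, waves in table.groupby("subject_id", sort=False)["wave_index"]:
        if not waves.is_monotonic_increasing:
            raise InputError("wave table must be sorted by wave within subject")


def pair_waves(
    table: pd.DataFrame,
    domain: str,
    dictionary: Optional[DataDictionary] = None,
    impute_policy: str = "column-mean",
    horizon: Optional[int] = None,
) -> SupervisedDataset:
    """Build the supervised dataset for one domain from a raw wave table.

    For every subject and wave ``t``, an example is emitted iff wave
    ``t + horizon`` exists for that subject and yields a non-missing label
    (strict horizon: a later wave does not substitute). Features come from
    the imputed table; labels from the raw one.
    """
    if domain not in DOMAINS:
        raise InputError(f"unknown domain {domain!r}")
    dictionary = dictionary or load_dictionary()
    horizon = DEFAULT_HORIZONS[domain] if horizon is None else int(horizon)
    _validate_panel(table)

    labeled = table if any(f"ic_{d}" in table.columns for d in DOMAINS) else score_table(table)
    imputed = impute_features(labeled, impute_policy, dictionary)

    label_col = f"ic_{domain}"
    # label lookup on the raw (pre-imputation) scores
    label_map = labeled.set_index(["subject_id", "wave_index"])[label_col]

    n_dropped_label = 0
    n_dropped_features = 0
    rows = []
    labels = []
    for rec in imputed.to_dict("records"):
        key = (rec["subject_id"], rec["wave_index"] + horizon)
        if key not in label_map.index:
            continue
        label = label_map.loc[key]
        if pd.isna(label):
            n_dropped_label += 1
            continue
        try:
            fv = build_features(rec, domain, dictionary)
        except MissingFeatureError:
            n_dropped_features += 1
            continue
        rows.append((rec["subject_id"], rec["wave_index"], fv.values))
        labels.append(float(label))

    names = dictionary.feature_names(domain)
    if rows:
        X = np.vstack([r[2] for r in rows])
        subj = np.array([r[0] for r in rows])
        wave = np.array([r[1] for r in rows])
    else:
        X = np.empty((0, len(names)))
        subj = np.array([], dtype=object)
        wave = np.array([], dtype=int)
    return SupervisedDataset(
        domain=domain,
        horizon_waves=horizon,
        feature_names=names,
        X=X,
        y=np.asarray(labels, dtype=float),
        subject_id=subj,
        wave_index=wave,
        n_rows_in=len(table),
        n_dropped_missing_label=n_dropped_label,
        n_dropped_missing_features=n_dropped_features,
    )


def summarize_dataset(datasets) -> dict:
    """Example counts and label distribution summaries per domain.

    Accepts a single :class:`SupervisedDataset` or an iterable of them.
    """
    if isinstance(datasets, SupervisedDataset):
        datasets = [datasets]
    summary = {}
    for ds in datasets:
        y = ds.y
        summary[ds.domain] = {
            "n_examples": int(len(y)),
            "horizon_waves": ds.horizon_waves,
            "label_mean": float(np.mean(y)) if len(y) else None,
            "label_sd": float(np.std(y)) if len(y) else None,
            "label_min": float(np.min(y)) if len(y) else None,
            "label_max": float(np.max(y)) if len(y) else None,
            "n_dropped_missing_label": ds.n_dropped_missing_label,
            "n_dropped_missing_features": ds.n_dropped_missing_features,
        }
    return summary
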