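"""End-to-end orchestration: simulate → score → build datasets → train →
evaluate → export, with a reproducibility manifest.

Scheduling (the periodic re-prognosis cycle) is deliberately out of scope:
a run is a pure batch execution; cadence is the caller's concern.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort
from .datasets import pair_waves, summarize_dataset
from .models import ModelSpec, compare_models, make_model, predict_ic, train
from .preprocessing import build_features, load_dictionary
from .scoring import DOMAINS, ICProfile, compute_profile

logger = logging.getLogger("icpredict")

__all__ = ["PipelineConfig", "run_pipeline", "export_profile"]


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    input_table: Optional[str] = None  # CSV path; None -> simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    domains: tuple = DOMAINS
    impute_policy: str = "column-mean"
    model_families: tuple = ("linear", "random_forest", "gradient_boosting", "dense_nn")
    tree_count: int = 100
    k_folds: int = 10

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "input_table": self.input_table,
            "cohort": self.cohort.to_dict(),
            "domains": list(self.domains),
            "impute_policy": self.impute_policy,
            "model_families": list(self.model_families),
            "tree_count": self.tree_count,
            "k_folds": self.k_folds,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()


def export_profile(profile: ICProfile, predicted: Optional[ICProfile] = None) -> dict:
    """Radar-ready five-axis document: current (and optionally predicted)
    scores plus availability flags. Unavailable axes are flagged, never
    zero-filled, and no aggregate-IC scalar is emitted (there is no
    standardized formula for one)."""
    doc = {"axes": {}}
    predicted = predicted or ICProfile()
    for domain in DOMAINS:
        current = getattr(profile, domain)
        future = getattr(predicted, domain)
        doc["axes"][domain] = {
            "current": current,
            "current_available": current is not None,
            "predicted": future,
            "predicted_available": future is not None,
        }
    return doc


def _specs_for(config: PipelineConfig, domain: str) -> list:
    specs = []
    for family in config.model_families:
        kwargs = {"seed": config.seed}
        if family in ("random_forest", "gradient_boosting"):
            kwargs["tree_count"] = config.tree_count
        specs.append(ModelSpec.for_domain(family, domain, **kwargs))
    return specs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Writes, under ``config.out_dir``: the (simulated or copied) wave table,
    per-domain metric tables, per-subject current/predicted profile JSON,
    dataset summaries, and ``manifest.json`` with the seed, config hash and
    library versions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = load_dictionary()

    # stage: acquire table
    try:
        if config.input_table:
            table = pd.read_csv(config.input_table)
        else:
            cohort_cfg = config.cohort
            table = simulate_cohort(cohort_cfg)
            table.to_csv(out / "cohort.csv", index=False)
        logger.info("stage=acquire rows=%d subjects=%d", len(table),
                    table["subject_id"].nunique())
    except Exception as exc:
        raise RuntimeError(f"stage 'acquire' failed: {exc}") from exc

    # stage: datasets + models
    metrics_tables = {}
    summaries = {}
    for domain in config.domains:
        try:
            ds = pair_waves(table, domain, dictionary, config.impute_policy)
            summaries.update(summarize_dataset(ds))
            logger.info(
                "stage=build-dataset domain=%s rows_in=%d examples=%d "
                "dropped_missing_label=%d", domain, ds.n_rows_in, len(ds),
                ds.n_dropped_missing_label)
        except Exception as exc:
            raise RuntimeError(f"stage 'build-dataset[{domain}]' failed: {exc}") from exc
        if not config.model_families:
            continue
        if len(ds) < config.k_folds:
            logger.warning("domain=%s has %d examples < k=%d; skipping models",
                           domain, len(ds), config.k_folds)
            continue
        try:
            report = compare_models(ds.X, ds.y, _specs_for(config, domain),
                                    k=config.k_folds, seed=config.seed)
            report.insert(0, "domain", domain)
            metrics_tables[domain] = report
            report.to_csv(out / f"metrics_{domain}.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'evaluate[{domain}]' failed: {exc}") from exc

    # stage: per-subject profiles (current wave + model prediction)
    profiles = {}
    try:
        last_wave = table.sort_values("wave_index").groupby("subject_id").tail(1)
        predictors = {}
        if config.model_families:
            for domain in config.domains:
                ds = pair_waves(table, domain, dictionary, config.impute_policy)
                if len(ds) >= 2:
                    spec = _specs_for(config, domain)[0]
                    predictors[domain] = train(make_model(spec), ds.X, ds.y)
        for rec in last_wave.to_dict("records"):
            current = compute_profile(rec)
            predicted_scores = {}
            for domain, model in predictors.items():
                try:
                    fv = build_features(rec, domain, dictionary)
                except Exception:
                    continue
                predicted_scores[domain] = predict_ic(model, fv.values)
            predicted = ICProfile(**predicted_scores)
            profiles[str(rec["subject_id"])] = export_profile(current, predicted)
        with open(out / "profiles.json", "w") as fh:
            json.dump({"seed": config.seed, "config_hash": config.config_hash(),
                       "profiles": profiles}, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"stage 'profiles' failed: {exc}") from exc

    import sklearn

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "dataset_summaries": summaries,
        "metrics_files": sorted(p.name for p in out.glob("metrics_*.csv")),
        "n_profiles": len(profiles),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "dataset_summary.json", "w") as fh:
        json.dump({"seed": config.seed, "config_hash": config.config_hash(),
                   "summaries": summaries}, fh, indent=2)
    return manifest
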