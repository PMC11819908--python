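"""Feature preprocessing: unit scaling, one-hot encoding, standardization.

Ordinal and continuous variables are scaled to [0, 1] using instrument-defined
bounds from the shipped data dictionary (not observed minima/maxima, so the
transform is dataset-independent). Marital status is one-hot encoded with a
full (non-dropped) indicator block. The cognitive and depression totals are
z-scored with published constants instead of unit-scaled; z-scores are passed
through unclipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .scoring import DOMAINS

__all__ = [
    "ConfigError",
    "RangeError",
    "EncodingError",
    "MissingFeatureError",
    "ImputationError",
    "StandardizationConstants",
    "FeatureVector",
    "DataDictionary",
    "load_dictionary",
    "scale_unit",
    "one_hot_marital",
    "standardize",
    "destandardize",
    "build_features",
    "impute_features",
    "IMPUTATION_POLICIES",
]

IMPUTATION_POLICIES = ("drop-incomplete", "column-mean", "column-median")


class ConfigError(ValueError):
    pass


class RangeError(ValueError):
    pass


class EncodingError(ValueError):
    pass


class MissingFeatureError(ValueError):
    pass


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class StandardizationConstants:
    instrument: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigError(f"{self.instrument}: sd must be positive, got {self.sd}")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named, model-ready values for one record and domain."""

    domain: str
    names: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)


class DataDictionary:
    """Schema of the wave table: variable types, bounds, categories, and the
    per-domain feature lists (shared block plus domain-specific extras)."""

    def __init__(self, spec: Mapping, standardization: Mapping) -> None:
        self.variables = dict(spec["variables"])
        self.shared_features = list(spec["shared_features"])
        self.domain_extras = {d: list(spec["domain_extras"].get(d, [])) for d in DOMAINS}
        self.standardization = {
            name: StandardizationConstants(name, c["mean"], c["sd"])
            for name, c in standardization.items()
        }
        for name in self.standardization:
            if name not in self.variables:
                raise ConfigError(f"standardized variable {name!r} not in dictionary")

    @property
    def marital_categories(self) -> list:
        return list(self.variables["marital_status"]["categories"])

    def source_columns(self, domain: str) -> list:
        """Raw wave-table columns feeding the domain's feature vector."""
        return self.shared_features + self.domain_extras[domain]

    def all_feature_columns(self) -> list:
        cols = list(self.shared_features)
        for domain in DOMAINS:
            for name in self.domain_extras[domain]:
                if name not in cols:
                    cols.append(name)
        return cols

    def feature_names(self, domain: str) -> list:
        """Expanded (post-one-hot) feature names, in canonical order."""
        names = []
        for var in self.source_columns(domain):
            if self.variables[var]["type"] == "categorical":
                names.extend(f"{var}={c}" for c in self.variables[var]["categories"])
            else:
                names.append(var)
        return names

    def input_size(self, domain: str) -> int:
        return len(self.feature_names(domain))


def load_dictionary(
    variables_path: Optional[str] = None, standardization_path: Optional[str] = None
) -> DataDictionary:
    """Load the shipped data dictionary, or user-supplied YAML overrides."""
    if variables_path is None:
        text = resources.files("icpredict.data").joinpath("variables.yaml").read_text()
    else:
        with open(variables_path) as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    if standardization_path is None:
        stext = resources.files("icpredict.data").joinpath("standardization.yaml").read_text()
    else:
        with open(standardization_path) as fh:
            stext = fh.read()
    return DataDictionary(spec, yaml.safe_load(stext))


def scale_unit(value: float, lo: float, hi: float) -> float:
    """Map ``value`` in [lo, hi] linearly onto [0, 1]."""
    if not lo < hi:
        raise ConfigError(f"invalid bounds: lo={lo} must be < hi={hi}")
    if not lo <= value <= hi:
        raise RangeError(f"value {value} outside [{lo}, {hi}]")
    return (value - lo) / (hi - lo)


def one_hot_marital(category, categories: Sequence) -> np.ndarray:
    """Full one-hot indicator vector over the configured category list."""
    try:
        idx = list(categories).index(category)
    except ValueError:
        raise EncodingError(
            f"unknown marital status {category!r}; expected one of {list(categories)}"
        ) from None
    vec = np.zeros(len(categories))
    vec[idx] = 1.0
    return vec


def standardize(raw: float, c: StandardizationConstants) -> float:
    return (raw - c.mean) / c.sd


def destandardize(z: float, c: StandardizationConstants) -> float:
    return z * c.sd + c.mean


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def build_features(
    record: Mapping, domain: str, dictionary: Optional[DataDictionary] = None
) -> FeatureVector:
    """Turn a (complete) wave record into the domain's model-ready vector.

    Applies unit scaling to ordinal/continuous items, one-hot encoding to
    marital status, and z-scoring to the standardized totals. Raises
    :class:`MissingFeatureError` naming the variable if a required feature
    is absent — imputation is the caller's job (see :func:`impute_features`).
    """
    if domain not in DOMAINS:
        raise ConfigError(f"unknown domain {domain!r}")
    dictionary = dictionary or load_dictionary()
    names: list = []
    values: list = []
    for var in dictionary.source_columns(domain):
        meta = dictionary.variables[var]
        raw = record.get(var)
        if _is_missing(raw):
            raise MissingFeatureError(f"missing feature {var!r} for domain {domain!r}")
        kind = meta["type"]
        if kind == "categorical":
            block = one_hot_marital(raw, meta["categories"])
            names.extend(f"{var}={c}" for c in meta["categories"])
            values.extend(block)
        elif kind == "standardized":
            names.append(var)
            values.append(standardize(float(raw), dictionary.standardization[var]))
        else:  # ordinal | continuous
            names.append(var)
            values.append(scale_unit(float(raw), meta["lo"], meta["hi"]))
    return FeatureVector(domain, tuple(names), np.asarray(values, dtype=float))


def impute_features(
    table: pd.DataFrame,
    policy: str = "column-mean",
    dictionary: Optional[DataDictionary] = None,
) -> pd.DataFrame:
    """Fill (or drop) missing values in feature columns; labels untouched.

    Only columns the data dictionary declares as features are modified;
    any other column — in particular precomputed IC label columns — is
    passed through unchanged. ``drop-incomplete`` removes rows with any
    missing numeric feature; the mean/median policies fill per column and
    fall back to the modal category for the categorical column.
    """
    if policy not in IMPUTATION_POLICIES:
        raise ConfigError(f"unknown policy {policy!r}; expected one of {IMPUTATION_POLICIES}")
    dictionary = dictionary or load_dictionary()
    feature_cols = [c for c in dictionary.all_feature_columns() if c in table.columns]
    out = table.copy()
    if policy == "drop-incomplete":
        return out.dropna(subset=feature_cols).reset_index(drop=True)
    for col in feature_cols:
        if not out[col].isna().any():
            continue
        series = out[col]
        if dictionary.variables[col]["type"] == "categorical":
            observed = series.dropna()
            if observed.empty:
                raise ImputationError(f"column {col!r} entirely missing")
            fill = observed.mode().iloc[0]
        else:
            observed = series.dropna().astype(float)
            if observed.empty:
                raise ImputationError(f"column {col!r} entirely missing")
            fill = observed.mean() if policy == "column-mean" else observed.median()
            if dictionary.variables[col]["type"] in ("ordinal", "standardized"):
                # integer-scored instruments stay on the integer grid
                fill = float(np.clip(round(fill),
                                     dictionary.variables[col]["lo"],
                                     dictionary.variables[col]["hi"]))
        out[col] = series.fillna(fill)
    return out


def build_feature_matrix(
    table: pd.DataFrame, domain: str, dictionary: Optional[DataDictionary] = None
) -> pd.DataFrame:
    """Vectorized :func:`build_features` over a complete wave table."""
    dictionary = dictionary or load_dictionary()
    rows = [build_features(rec, domain, dictionary) for rec in table.to_dict("records")]
    names = dictionary.feature_names(domain)
    return pd.DataFrame([fv.values for fv in rows], columns=names, index=table.index)
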