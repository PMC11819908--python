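"""Intrinsic-capacity (IC) domain scoring.

Five domains — locomotion, sensory, psychology, cognition, vitality — are
each scored on the unit interval from standard geriatric instruments:

* locomotion: Short Physical Performance Battery (SPPB) total over its
  maximum of 12 points;
* vitality: a clamped linear composite of the SF-12 energy item and grip
  strength in kilograms, ``min(0.13 * (6 - sf12_energy) + 0.09 * grip_kg, 1)``;
* psychology: a piecewise mapping of the PHQ-9 depression total using the
  standard severity cut-offs, falling linearly to 0 for severe scores;
* cognition: MoCA total over its maximum of 30 points;
* sensory: mean of four self-rated hearing/vision items (1-5 each), i.e.
  their sum over 20.

All scoring functions are pure, validate their inputs against the
instrument ranges, and raise :class:`DomainRangeError` on out-of-range or
non-integer values where the instrument is integer-scored.

Notes on fidelity
-----------------
Grip strength enters the vitality composite in raw kilograms: roughly 11 kg
alone saturates the score at 1. This is deliberate — the composite is used
as published, with no renormalization.

The SF-12 energy item is coded 1 = highest energy .. 6 = lowest, so the
``(6 - answer)`` term rewards energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

__all__ = [
    "DomainRangeError",
    "SPPBResult",
    "VitalityInputs",
    "DepressionScore",
    "CognitionScore",
    "SensoryRatings",
    "ICProfile",
    "DOMAINS",
    "SPPB_MAX",
    "MOCA_MAX",
    "score_locomotion",
    "score_vitality",
    "score_psychology",
    "score_cognition",
    "score_sensory",
    "compute_profile",
]

DOMAINS = ("locomotion", "sensory", "psychology", "cognition", "vitality")

#: Standard instrument maxima. Configurable through the scoring functions'
#: keyword arguments.
SPPB_MAX = 12
MOCA_MAX = 30


class DomainRangeError(ValueError):
    """A present instrument value is outside its valid range (or not an
    integer for an integer-scored instrument)."""


def _check_int(value, name: str, lo: int, hi: int) -> int:
    """Validate an integer-scored instrument value; accept integral floats."""
    if isinstance(value, bool):
        raise DomainRangeError(f"{name} must be an integer, got bool")
    if isinstance(value, float):
        if not value.is_integer():
            raise DomainRangeError(f"{name} must be integer-valued, got {value!r}")
        value = int(value)
    if not isinstance(value, int):
        raise DomainRangeError(f"{name} must be an integer, got {type(value).__name__}")
    if not lo <= value <= hi:
        raise DomainRangeError(f"{name}={value} outside valid range [{lo}, {hi}]")
    return value


@dataclass(frozen=True)
class SPPBResult:
    """SPPB component points: balance, gait speed, chair stands (0-4 each)."""

    balance_pts: int
    gait_pts: int
    chair_pts: int

    def __post_init__(self) -> None:
        for field in ("balance_pts", "gait_pts", "chair_pts"):
            _check_int(getattr(self, field), f"sppb.{field}", 0, 4)

    @property
    def total(self) -> int:
        return int(self.balance_pts) + int(self.gait_pts) + int(self.chair_pts)

    @classmethod
    def from_total(cls, total) -> "SPPBResult":
        """Build from a 0-12 total only (component split is arbitrary)."""
        total = _check_int(total, "sppb.total", 0, SPPB_MAX)
        parts = [min(total, 4), min(max(total - 4, 0), 4), min(max(total - 8, 0), 4)]
        return cls(*parts)


@dataclass(frozen=True)
class VitalityInputs:
    """SF-12 energy item answer (1-6, 1 = most energetic) and grip in kg."""

    sf12_energy: int
    grip_kg: float

    def __post_init__(self) -> None:
        _check_int(self.sf12_energy, "sf12_energy", 1, 6)
        if not math.isfinite(self.grip_kg) or self.grip_kg < 0:
            raise DomainRangeError(f"grip_kg={self.grip_kg!r} must be a non-negative real")


@dataclass(frozen=True)
class DepressionScore:
    """PHQ-9 total, 0-27 (higher = more depressive symptoms)."""

    phq_total: int

    def __post_init__(self) -> None:
        _check_int(self.phq_total, "phq_total", 0, 27)


@dataclass(frozen=True)
class CognitionScore:
    """MoCA total, 0-30 (higher = better cognition)."""

    moca_total: int

    def __post_init__(self) -> None:
        _check_int(self.moca_total, "moca_total", 0, MOCA_MAX)


@dataclass(frozen=True)
class SensoryRatings:
    """Self-rated hearing (left/right) and vision (far/near), 1-5 each."""

    h_left: int
    h_right: int
    v_far: int
    v_near: int

    def __post_init__(self) -> None:
        for field in ("h_left", "h_right", "v_far", "v_near"):
            _check_int(getattr(self, field), field, 1, 5)


@dataclass(frozen=True)
class ICProfile:
    """Five unit-interval domain scores; ``None`` marks an unavailable score
    (its instruments were missing — never imputed, never zero-filled)."""

    locomotion: Optional[float] = None
    sensory: Optional[float] = None
    psychology: Optional[float] = None
    cognition: Optional[float] = None
    vitality: Optional[float] = None

    def __post_init__(self) -> None:
        for domain in DOMAINS:
            score = getattr(self, domain)
            if score is not None and not 0.0 <= score <= 1.0:
                raise DomainRangeError(f"{domain} score {score!r} outside [0, 1]")

    def available(self) -> dict:
        return {d: getattr(self, d) is not None for d in DOMAINS}

    def to_dict(self) -> dict:
        """JSON-ready representation: scores plus availability mask."""
        return {
            "scores": {d: getattr(self, d) for d in DOMAINS},
            "available": self.available(),
        }


def score_locomotion(sppb: SPPBResult, *, sppb_max: int = SPPB_MAX) -> float:
    """Locomotion IC: SPPB total scaled by the instrument maximum."""
    total = _check_int(sppb.total, "sppb.total", 0, sppb_max)
    return total / sppb_max


def score_vitality(v: VitalityInputs) -> float:
    """Vitality IC: ``min(0.13 * (6 - sf12_energy) + 0.09 * grip_kg, 1)``."""
    return min(0.13 * (6 - v.sf12_energy) + 0.09 * v.grip_kg, 1.0)


def score_psychology(d: DepressionScore) -> float:
    """Psychological IC from the PHQ-9 total via severity cut-offs.

    1.00 for 0-4, 0.75 for 5-9, 0.50 for 10-14, 0.25 for 15-19, then
    ``(27 - phq) / 32`` above 19 so the score falls linearly to 0 at 27.
    """
    phq = d.phq_total
    if phq <= 4:
        return 1.0
    if phq <= 9:
        return 0.75
    if phq <= 14:
        return 0.5
    if phq <= 19:
        return 0.25
    return (27 - phq) / 32


def score_cognition(c: CognitionScore, *, moca_max: int = MOCA_MAX) -> float:
    """Cognition IC: MoCA total scaled by the instrument maximum."""
    total = _check_int(c.moca_total, "moca_total", 0, moca_max)
    return total / moca_max


def score_sensory(s: SensoryRatings) -> float:
    """Sensory IC: sum of the four 1-5 ratings over 20."""
    return (s.h_left + s.h_right + s.v_far + s.v_near) / 20


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _get(record: Mapping, key: str):
    value = record.get(key)
    return None if _is_missing(value) else value


def compute_profile(record: Mapping) -> ICProfile:
    """Score every domain whose instruments are present in ``record``.

    ``record`` is a flat mapping keyed by the canonical variable names
    (see the shipped data dictionary): ``sppb_balance``/``sppb_gait``/
    ``sppb_chair``, ``sf12_q10``, ``grip_kg``, ``phq9_total``,
    ``moca_total``, ``hearing_left``/``hearing_right``/``vision_far``/
    ``vision_near``. Missing instruments yield an unavailable (``None``)
    score — this function never raises on absent data, only on malformed
    present values.
    """
    locomotion = None
    sppb_parts = [_get(record, k) for k in ("sppb_balance", "sppb_gait", "sppb_chair")]
    if all(p is not None for p in sppb_parts):
        locomotion = score_locomotion(SPPBResult(*sppb_parts))

    sensory = None
    ratings = [
        _get(record, k)
        for k in ("hearing_left", "hearing_right", "vision_far", "vision_near")
    ]
    if all(r is not None for r in ratings):
        sensory = score_sensory(SensoryRatings(*ratings))

    psychology = None
    phq = _get(record, "phq9_total")
    if phq is not None:
        psychology = score_psychology(DepressionScore(phq))

    cognition = None
    moca = _get(record, "moca_total")
    if moca is not None:
        cognition = score_cognition(CognitionScore(moca))

    vitality = None
    energy, grip = _get(record, "sf12_q10"), _get(record, "grip_kg")
    if energy is not None and grip is not None:
        vitality = score_vitality(VitalityInputs(energy, float(grip)))

    return ICProfile(locomotion, sensory, psychology, cognition, vitality)
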