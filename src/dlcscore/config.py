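"""Threshold configuration shared by all scoring systems.

Every clinically meaningful cut-off lives here with the published values as
immutable defaults: age 50 years, BMI 30 kg/m^2, 90 minutes to identify the
cystic artery and duct, and the band-boundary binarization cut-offs (>=3
preoperative, >=3 standard intraoperative, >=4 modified intraoperative).
"""
from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path

import yaml

from .types import ValidationError

__all__ = ["ScoreThresholds", "DEFAULT_THRESHOLDS", "load_thresholds"]


@dataclass(frozen=True)
class ScoreThresholds:
    """Cut-offs used by the scorers and binarizers.

    Parameters
    ----------
    age_cutoff : float
        Age boundary in years; a point is awarded for age strictly above it
        by default (the score table reads "> 50").
    age_inclusive : bool
        If True, award the age point at ``age >= age_cutoff`` instead (some
        prose summaries of the score use "greater than or equal to 50").
    bmi_cutoff : float
        BMI boundary; a point for BMI strictly above it.
    time_cutoff_min : float
        Minutes to identify the cystic artery/duct; a point strictly above.
    preop_difficult_min : int
        Preoperative total at or above which the case is called difficult.
    standard_difficult_min : int
        Standard intraoperative total at or above which the operation is
        difficult (mild/moderate band boundary).
    modified_difficult_min : int
        Same for the modified intraoperative score.
    artery_only_points : int
        Points for an isolated cystic-artery injury. The modified score table
        lists only "duct only: 1" and "both: 2"; by symmetry a single injured
        structure scores 1, and scoring it emits a warning.
    """

    age_cutoff: float = 50.0
    age_inclusive: bool = False
    bmi_cutoff: float = 30.0
    time_cutoff_min: float = 90.0
    preop_difficult_min: int = 3
    standard_difficult_min: int = 3
    modified_difficult_min: int = 4
    artery_only_points: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.preop_difficult_min <= 11 + 1:
            raise ValidationError("preop_difficult_min outside the score range")
        if not 0 <= self.standard_difficult_min <= 10 + 1:
            raise ValidationError("standard_difficult_min outside the score range")
        if not 0 <= self.modified_difficult_min <= 16 + 1:
            raise ValidationError("modified_difficult_min outside the score range")
        if self.artery_only_points not in (0, 1, 2):
            raise ValidationError("artery_only_points must be 0, 1 or 2")

    def age_positive(self, age: float) -> bool:
        return age >= self.age_cutoff if self.age_inclusive else age > self.age_cutoff

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_THRESHOLDS = ScoreThresholds()


def load_thresholds(path: str | Path) -> ScoreThresholds:
    """Load threshold overrides from a YAML mapping.

    Unknown keys are rejected so typos cannot silently leave a default in
    place.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return DEFAULT_THRESHOLDS
    if not isinstance(raw, dict):
        raise ValidationError(f"threshold config must be a mapping, got {type(raw)}")
    known = set(DEFAULT_THRESHOLDS.to_dict())
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
    return replace(DEFAULT_THRESHOLDS, **raw)
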