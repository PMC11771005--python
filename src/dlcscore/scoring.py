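"""The three point-based difficulty scores and their binarizations.

Three systems are implemented:

* ``score_preop`` — the 11-point preoperative predictor score (age, sex,
  admission history for acute cholecystitis, BMI, palpable gallbladder,
  abdominal scar, impacted stone on imaging). Bands: 0-2 no risk, 3-7
  moderate risk, 8-11 high risk.
* ``score_sugrue`` — the standard 10-point Sugrue intraoperative grade
  (adhesions, distension/contraction features, BMI, previous-surgery
  adhesions, bile/pus outside the gallbladder, time to identify the cystic
  structures). Bands: <=2 mild, 3-4 moderate, 5-7 severe, 8-10 extreme.
* ``score_modified`` — the 16-point modified intraoperative grade, which
  drops the bile/pus item and adds bile/stone spillage, ductal/arterial
  injury, conversion to open, and ligature type. Bands: 0-3 mild, 4-7
  moderate, 8-11 severe, 12-16 extreme.

The three distension/contraction sub-items (distended or contracted
gallbladder, ungraspable with atraumatic forceps, stone >= 1 cm impacted in
Hartmann's pouch) are additive, one point each; the printed totals of 10 and
16 are attainable only under that reading.
"""
from __future__ import annotations

import warnings

from .config import DEFAULT_THRESHOLDS, ScoreThresholds
from .types import IntraopFindings, PreopProfile, ScoreResult, ValidationError

__all__ = [
    "score_preop",
    "score_sugrue",
    "score_modified",
    "binarize_preop",
    "binarize_intraop",
    "outcome_label",
    "band_for_total",
    "BANDS",
]

# (low, high, label) — contiguous, exhaustive over each system's range
BANDS = {
    "preop": ((0, 2, "no risk"), (3, 7, "moderate risk"), (8, 11, "high risk")),
    "standard": ((0, 2, "mild"), (3, 4, "moderate"), (5, 7, "severe"), (8, 10, "extreme")),
    "modified": ((0, 3, "mild"), (4, 7, "moderate"), (8, 11, "severe"), (12, 16, "extreme")),
}


def band_for_total(system: str, total: int) -> str:
    """Ordinal difficulty band for an integer total under ``system``."""
    try:
        bands = BANDS[system]
    except KeyError:
        raise ValidationError(f"unknown scoring system {system!r}") from None
    for low, high, label in bands:
        if low <= total <= high:
            return label
    raise ValidationError(f"{system} total {total} outside the score range")


def _result(system: str, breakdown: list[tuple[str, int]], difficult_min: int) -> ScoreResult:
    total = sum(points for _, points in breakdown)
    return ScoreResult(
        system=system,
        total=total,
        breakdown=tuple(breakdown),
        band=band_for_total(system, total),
        binary="difficult" if total >= difficult_min else "easy",
    )


def score_preop(
    profile: PreopProfile, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> ScoreResult:
    """Preoperative predictor score (maximum 11 points).

    Points: age above the cut-off 1; male 1; admission history for acute
    cholecystitis 4; BMI above 30 1; palpable gallbladder 1; infraumbilical
    scar 1 or supraumbilical scar 2; impacted stone on imaging 1.
    """
    b = [
        ("age", 1 if thresholds.age_positive(profile.age) else 0),
        ("sex", 1 if profile.sex == "male" else 0),
        ("admission_history", 4 if profile.admission_history_acute_cholecystitis else 0),
        ("bmi", 1 if profile.bmi > thresholds.bmi_cutoff else 0),
        ("palpable_gb", 1 if profile.palpable_gb else 0),
        (
            "abdominal_scar",
            {"none": 0, "infraumbilical": 1, "supraumbilical": 2}[profile.abdominal_scar],
        ),
        ("impacted_stone", 1 if profile.impacted_stone_imaging else 0),
    ]
    return _result("preop", b, thresholds.preop_difficult_min)


_ADHESION_POINTS = {"none": 0, "less_than_50pct": 1, "burying_gb": 3}


def _shared_intraop_items(
    findings: IntraopFindings, thresholds: ScoreThresholds
) -> list[tuple[str, int]]:
    """Items common to the standard and modified intraoperative scores."""
    return [
        ("adhesion", _ADHESION_POINTS[findings.adhesion_grade]),
        ("distended_or_contracted", 1 if findings.distended_or_contracted else 0),
        ("ungraspable", 1 if findings.ungraspable_with_forceps else 0),
        ("stone_impacted_hartmann", 1 if findings.stone_impacted_hartmann_ge_1cm else 0),
        ("bmi", 1 if findings.bmi > thresholds.bmi_cutoff else 0),
        (
            "prev_surgery_adhesions",
            1 if findings.adhesions_prev_surgery_limiting_access else 0,
        ),
        (
            "time_to_identify",
            1
            if findings.time_to_identify_cystic_structures_min > thresholds.time_cutoff_min
            else 0,
        ),
    ]


def score_sugrue(
    findings: IntraopFindings, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> ScoreResult:
    """Standard Sugrue intraoperative difficulty grade (maximum 10 points)."""
    b = _shared_intraop_items(findings, thresholds)
    # bile/pus outside the GB is scored only by the standard system
    b.insert(6, ("bile_pus_outside_gb", 1 if findings.bile_or_pus_outside_gb else 0))
    return _result("standard", b, thresholds.standard_difficult_min)


def _injury_points(injury: str, thresholds: ScoreThresholds) -> int:
    if injury == "none":
        return 0
    if injury == "duct_only":
        return 1
    if injury == "both":
        return 2
    # isolated arterial injury is unlisted in the published table; score it
    # like the other single-structure injury and warn
    warnings.warn(
        "injury 'artery_only' is not listed in the modified score table; "
        f"scoring it {thresholds.artery_only_points} point(s) by symmetry "
        "with 'duct_only'",
        stacklevel=3,
    )
    return thresholds.artery_only_points


def score_modified(
    findings: IntraopFindings, thresholds: ScoreThresholds = DEFAULT_THRESHOLDS
) -> ScoreResult:
    """Modified intraoperative difficulty grade (maximum 16 points).

    Extends the Sugrue items (without bile/pus outside the gallbladder) with
    bile/stone spillage 1; injury to duct 1 or both duct and artery 2;
    conversion to open 3; stitch ligature 1 (clip 0).
    """
    b = _shared_intraop_items(findings, thresholds)
    b += [
        ("bile_stone_spillage", 1 if findings.bile_stone_spillage else 0),
        ("injury", _injury_points(findings.injury, thresholds)),
        ("conversion_to_open", 3 if findings.conversion_to_open else 0),
        ("ligature", 1 if findings.ligature == "stitch" else 0),
    ]
    return _result("modified", b, thresholds.modified_difficult_min)


def binarize_preop(result: ScoreResult, difficult_min: int | None = None) -> str:
    """Collapse a preoperative result to easy/difficult.

    The default cut-off is the no-risk/moderate-risk band boundary: a total
    of 3 or more is difficult.
    """
    if result.system != "preop":
        raise ValidationError(
            f"binarize_preop expects a preop result, got {result.system!r}"
        )
    cut = DEFAULT_THRESHOLDS.preop_difficult_min if difficult_min is None else difficult_min
    return "difficult" if result.total >= cut else "easy"


def binarize_intraop(
    result: ScoreResult, system: str, difficult_min: int | None = None
) -> str:
    """Collapse an intraoperative result to easy/difficult.

    Defaults to the mild/moderate band boundary: standard >= 3, modified
    >= 4.
    """
    if system not in ("standard", "modified"):
        raise ValidationError(f"system must be standard/modified, got {system!r}")
    if result.system != system:
        raise ValidationError(
            f"result is from the {result.system!r} system, not {system!r}"
        )
    if difficult_min is None:
        difficult_min = (
            DEFAULT_THRESHOLDS.standard_difficult_min
            if system == "standard"
            else DEFAULT_THRESHOLDS.modified_difficult_min
        )
    return "difficult" if result.total >= difficult_min else "easy"


def outcome_label(
    findings: IntraopFindings,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    difficult_min: int | None = None,
) -> str:
    """Operative-outcome reference standard: difficult iff the standard
    Sugrue total reaches the mild/moderate boundary (>= 3 by default).

    The cut-off is configurable because no single published rule defines an
    operatively difficult cholecystectomy; the Sugrue band boundary is the
    choice consistent with the study's reported outcome counts.
    """
    cut = thresholds.standard_difficult_min if difficult_min is None else difficult_min
    return "difficult" if score_sugrue(findings, thresholds).total >= cut else "easy"
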