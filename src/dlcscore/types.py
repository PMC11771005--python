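"""Domain types: per-patient preoperative profiles, intraoperative findings,
and score results.

All categorical fields use lowercase string tokens so that records round-trip
through the CSV interchange format unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "ValidationError",
    "PreopProfile",
    "IntraopFindings",
    "ScoreResult",
    "SEX_LEVELS",
    "SCAR_LEVELS",
    "ADHESION_LEVELS",
    "INJURY_LEVELS",
    "LIGATURE_LEVELS",
]

SEX_LEVELS = ("female", "male")
SCAR_LEVELS = ("none", "infraumbilical", "supraumbilical")
ADHESION_LEVELS = ("none", "less_than_50pct", "burying_gb")
INJURY_LEVELS = ("none", "duct_only", "artery_only", "both")
LIGATURE_LEVELS = ("clip", "stitch")


class ValidationError(ValueError):
    """Raised when a record or configuration violates its invariants."""


def _require_level(name: str, value: str, levels: tuple[str, ...]) -> None:
    if value not in levels:
        raise ValidationError(
            f"{name} must be one of {levels}, got {value!r}"
        )


def _require_bool(name: str, value: object) -> None:
    if not isinstance(value, (bool,)):
        raise ValidationError(f"{name} must be a boolean, got {value!r}")


def _require_positive(name: str, value: object) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValidationError(f"{name} must be numeric, got {value!r}")
    if not value > 0:
        raise ValidationError(f"{name} must be positive, got {value!r}")


def _require_non_negative(name: str, value: object) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValidationError(f"{name} must be numeric, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class PreopProfile:
    """Preoperative risk variables for one patient.

    Parameters
    ----------
    age : int
        Age in years (positive).
    sex : {"female", "male"}
    admission_history_acute_cholecystitis : bool
        Prior hospital admission for an acute cholecystitis attack.
    bmi : float
        Body mass index in kg/m^2 (positive).
    palpable_gb : bool
        Gallbladder palpable on abdominal examination.
    abdominal_scar : {"none", "infraumbilical", "supraumbilical"}
        Location of any previous-surgery abdominal scar.
    impacted_stone_imaging : bool
        Impacted stone seen on preoperative sonography.
    """

    age: int
    sex: str
    admission_history_acute_cholecystitis: bool
    bmi: float
    palpable_gb: bool
    abdominal_scar: str
    impacted_stone_imaging: bool

    def __post_init__(self) -> None:
        _require_positive("age", self.age)
        _require_level("sex", self.sex, SEX_LEVELS)
        _require_bool(
            "admission_history_acute_cholecystitis",
            self.admission_history_acute_cholecystitis,
        )
        _require_positive("bmi", self.bmi)
        _require_bool("palpable_gb", self.palpable_gb)
        _require_level("abdominal_scar", self.abdominal_scar, SCAR_LEVELS)
        _require_bool("impacted_stone_imaging", self.impacted_stone_imaging)


@dataclass(frozen=True)
class IntraopFindings:
    """Scored intraoperative findings for one operation.

    ``bmi`` is shared with :class:`PreopProfile` when both record types exist
    for the same patient; the CSV reader enforces agreement at load time.
    ``time_to_complete_lc_min`` is recorded but scored by no system; it is an
    optional pass-through field.
    """

    adhesion_grade: str
    distended_or_contracted: bool
    ungraspable_with_forceps: bool
    stone_impacted_hartmann_ge_1cm: bool
    bmi: float
    adhesions_prev_surgery_limiting_access: bool
    bile_or_pus_outside_gb: bool
    time_to_identify_cystic_structures_min: float
    bile_stone_spillage: bool
    injury: str
    conversion_to_open: bool
    ligature: str
    time_to_complete_lc_min: float | None = None

    def __post_init__(self) -> None:
        _require_level("adhesion_grade", self.adhesion_grade, ADHESION_LEVELS)
        _require_bool("distended_or_contracted", self.distended_or_contracted)
        _require_bool("ungraspable_with_forceps", self.ungraspable_with_forceps)
        _require_bool(
            "stone_impacted_hartmann_ge_1cm", self.stone_impacted_hartmann_ge_1cm
        )
        _require_positive("bmi", self.bmi)
        _require_bool(
            "adhesions_prev_surgery_limiting_access",
            self.adhesions_prev_surgery_limiting_access,
        )
        _require_bool("bile_or_pus_outside_gb", self.bile_or_pus_outside_gb)
        _require_non_negative(
            "time_to_identify_cystic_structures_min",
            self.time_to_identify_cystic_structures_min,
        )
        _require_bool("bile_stone_spillage", self.bile_stone_spillage)
        _require_level("injury", self.injury, INJURY_LEVELS)
        _require_bool("conversion_to_open", self.conversion_to_open)
        _require_level("ligature", self.ligature, LIGATURE_LEVELS)
        if self.time_to_complete_lc_min is not None:
            _require_non_negative(
                "time_to_complete_lc_min", self.time_to_complete_lc_min
            )


# maximum attainable total per scoring system
SYSTEM_MAXIMA = {"preop": 11, "standard": 10, "modified": 16}


@dataclass(frozen=True)
class ScoreResult:
    """Result of applying one scoring system to one record.

    Attributes
    ----------
    system : {"preop", "standard", "modified"}
        Which scoring system produced the result.
    total : int
        Sum of the per-item points.
    breakdown : tuple of (item name, points)
        Ordered per-item contribution; sums exactly to ``total``.
    band : str
        Ordinal difficulty band derived from ``total``.
    binary : {"easy", "difficult"}
        Binarized class at the system's default cut-off.
    """

    system: str
    total: int
    breakdown: tuple[tuple[str, int], ...]
    band: str
    binary: str

    def __post_init__(self) -> None:
        if self.system not in SYSTEM_MAXIMA:
            raise ValidationError(f"unknown scoring system {self.system!r}")
        if self.total != sum(p for _, p in self.breakdown):
            raise ValidationError("total does not equal the sum of the breakdown")
        hi = SYSTEM_MAXIMA[self.system]
        if not 0 <= self.total <= hi:
            raise ValidationError(
                f"{self.system} total {self.total} outside [0, {hi}]"
            )
        if self.binary not in ("easy", "difficult"):
            raise ValidationError(f"binary must be easy/difficult, got {self.binary!r}")


PREOP_FIELDS = tuple(f.name for f in fields(PreopProfile))
INTRAOP_FIELDS = tuple(f.name for f in fields(IntraopFindings))
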