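"""Unit and property tests of the three scoring systems, their bands and
their binarizations."""
import dataclasses

import pytest
from hypothesis import given

from dlcscore import (
    DEFAULT_THRESHOLDS,
    IntraopFindings,
    PreopProfile,
    ScoreThresholds,
    ValidationError,
    band_for_total,
    binarize_intraop,
    binarize_preop,
    outcome_label,
    score_modified,
    score_preop,
    score_sugrue,
)
from dlcscore.scoring import BANDS

from conftest import intraop_findings, preop_profiles


class TestPreopScore:
    def test_all_worst_levels_reach_the_maximum(self, worst_preop):
        r = score_preop(worst_preop)
        assert r.total == 11
        assert r.band == "high risk"
        assert r.binary == "difficult"

    def test_female_otherwise_worst_scores_ten(self, worst_preop):
        # sex contributes 1 only for male patients
        r = score_preop(dataclasses.replace(worst_preop, sex="female"))
        assert r.total == 10

    def test_no_risk_factors_score_zero(self, benign_preop):
        r = score_preop(benign_preop)
        assert r.total == 0
        assert r.band == "no risk"
        assert r.binary == "easy"

    def test_moderate_risk_combination(self, benign_preop):
        # age over 50 (1) + infraumbilical scar (1) + impacted stone (1)
        p = dataclasses.replace(
            benign_preop,
            age=55,
            bmi=28.0,
            abdominal_scar="infraumbilical",
            impacted_stone_imaging=True,
        )
        r = score_preop(p)
        assert r.total == 3
        assert r.band == "moderate risk"
        assert dict(r.breakdown) == {
            "age": 1, "sex": 0, "admission_history": 0, "bmi": 0,
            "palpable_gb": 0, "abdominal_scar": 1, "impacted_stone": 1,
        }

    def test_age_boundary_is_strict_by_default(self, benign_preop):
        assert score_preop(dataclasses.replace(benign_preop, age=50)).total == 0
        assert score_preop(dataclasses.replace(benign_preop, age=51)).total == 1
        inclusive = ScoreThresholds(age_inclusive=True)
        assert score_preop(dataclasses.replace(benign_preop, age=50), inclusive).total == 1

    @pytest.mark.parametrize("field,value", [("age", 0), ("age", -3), ("bmi", 0.0)])
    def test_non_positive_vitals_rejected(self, field, value):
        with pytest.raises(ValidationError, match=field):
            PreopProfile(
                age=40 if field != "age" else value,
                sex="female",
                admission_history_acute_cholecystitis=False,
                bmi=25.0 if field != "bmi" else value,
                palpable_gb=False,
                abdominal_scar="none",
                impacted_stone_imaging=False,
            )

    def test_invalid_level_names_field(self):
        with pytest.raises(ValidationError, match="abdominal_scar"):
            PreopProfile(
                age=40, sex="female", admission_history_acute_cholecystitis=False,
                bmi=25.0, palpable_gb=False, abdominal_scar="umbilical",
                impacted_stone_imaging=False,
            )


class TestIntraopScores:
    def test_sugrue_all_worst_levels(self, worst_findings):
        r = score_sugrue(worst_findings)
        assert r.total == 10
        assert r.band == "extreme"

    def test_modified_all_worst_levels(self, worst_findings):
        r = score_modified(worst_findings)
        assert r.total == 16
        assert r.band == "extreme"

    def test_benign_operation_scores_zero(self, benign_findings):
        assert score_sugrue(benign_findings).total == 0
        assert score_sugrue(benign_findings).band == "mild"
        assert score_modified(benign_findings).total == 0
        assert score_modified(benign_findings).band == "mild"

    def test_burying_adhesion_alone_is_moderate_sugrue(self, benign_findings):
        r = score_sugrue(dataclasses.replace(benign_findings, adhesion_grade="burying_gb"))
        assert r.total == 3
        assert r.band == "moderate"

    def test_conversion_plus_stitch_is_moderate_modified(self, benign_findings):
        r = score_modified(
            dataclasses.replace(benign_findings, conversion_to_open=True, ligature="stitch")
        )
        assert r.total == 4
        assert r.band == "moderate"

    def test_time_boundary_is_strict(self, benign_findings):
        at = dataclasses.replace(benign_findings, time_to_identify_cystic_structures_min=90.0)
        above = dataclasses.replace(benign_findings, time_to_identify_cystic_structures_min=90.5)
        assert score_sugrue(at).total == 0
        assert score_sugrue(above).total == 1

    def test_bile_pus_only_scored_by_standard_system(self, benign_findings):
        f = dataclasses.replace(benign_findings, bile_or_pus_outside_gb=True)
        assert score_sugrue(f).total == 1
        assert score_modified(f).total == 0

    def test_injury_points(self, benign_findings):
        assert score_modified(dataclasses.replace(benign_findings, injury="duct_only")).total == 1
        assert score_modified(dataclasses.replace(benign_findings, injury="both")).total == 2

    def test_artery_only_injury_warns_and_scores_one(self, benign_findings):
        f = dataclasses.replace(benign_findings, injury="artery_only")
        with pytest.warns(UserWarning, match="artery_only"):
            assert score_modified(f).total == 1


class TestBinarization:
    @pytest.mark.parametrize("total,expected", [(2, "easy"), (3, "difficult"), (11, "difficult")])
    def test_preop_cutoff_at_band_boundary(self, benign_preop, worst_preop, total, expected):
        profiles = {
            2: dataclasses.replace(benign_preop, age=55, abdominal_scar="infraumbilical"),
            3: dataclasses.replace(
                benign_preop, age=55, abdominal_scar="infraumbilical",
                impacted_stone_imaging=True,
            ),
            11: worst_preop,
        }
        r = score_preop(profiles[total])
        assert r.total == total
        assert binarize_preop(r) == expected

    def test_preop_threshold_configurable(self, worst_preop):
        r = score_preop(worst_preop)
        assert binarize_preop(r, difficult_min=12) == "easy"

    def test_modified_boundary(self, benign_findings):
        three = dataclasses.replace(benign_findings, conversion_to_open=True)
        four = dataclasses.replace(three, ligature="stitch")
        assert binarize_intraop(score_modified(three), "modified") == "easy"
        assert binarize_intraop(score_modified(four), "modified") == "difficult"

    def test_standard_boundary(self, benign_findings):
        f = dataclasses.replace(benign_findings, adhesion_grade="burying_gb")
        r = score_sugrue(f)
        assert r.total == 3
        assert binarize_intraop(r, "standard") == "difficult"

    def test_system_mismatch_rejected(self, benign_findings):
        with pytest.raises(ValidationError, match="standard"):
            binarize_intraop(score_modified(benign_findings), "standard")
        with pytest.raises(ValidationError, match="preop"):
            binarize_preop(score_sugrue(benign_findings))


class TestOutcomeLabel:
    def test_boundaries(self, benign_findings, worst_findings):
        assert outcome_label(benign_findings) == "easy"
        assert outcome_label(worst_findings) == "difficult"
        at_three = dataclasses.replace(benign_findings, adhesion_grade="burying_gb")
        assert outcome_label(at_three) == "difficult"

    def test_threshold_configurable(self, benign_findings):
        at_three = dataclasses.replace(benign_findings, adhesion_grade="burying_gb")
        assert outcome_label(at_three, difficult_min=4) == "easy"


class TestBands:
    @pytest.mark.parametrize("system,maximum", [("preop", 11), ("standard", 10), ("modified", 16)])
    def test_bands_exhaustive_and_non_overlapping(self, system, maximum):
        bands = BANDS[system]
        covered = []
        for low, high, _ in bands:
            covered.extend(range(low, high + 1))
        assert covered == list(range(maximum + 1))
        for total in range(maximum + 1):
            assert sum(low <= total <= high for low, high, _ in bands) == 1
            band_for_total(system, total)  # no error

    def test_out_of_range_total_rejected(self):
        with pytest.raises(ValidationError):
            band_for_total("preop", 12)
        with pytest.raises(ValidationError):
            band_for_total("nonsense", 1)


def _band_rank(system, label):
    return [b[2] for b in BANDS[system]].index(label)


# single-item "worsening" moves per record type
_PREOP_MOVES = [
    lambda p: dataclasses.replace(p, age=max(p.age, 60)),
    lambda p: dataclasses.replace(p, sex="male"),
    lambda p: dataclasses.replace(p, admission_history_acute_cholecystitis=True),
    lambda p: dataclasses.replace(p, bmi=max(p.bmi, 35.0)),
    lambda p: dataclasses.replace(p, palpable_gb=True),
    lambda p: dataclasses.replace(p, abdominal_scar="supraumbilical"),
    lambda p: dataclasses.replace(p, impacted_stone_imaging=True),
]
_INTRAOP_MOVES = [
    lambda f: dataclasses.replace(f, adhesion_grade="burying_gb"),
    lambda f: dataclasses.replace(
        f, adhesion_grade="less_than_50pct" if f.adhesion_grade == "none" else f.adhesion_grade
    ),
    lambda f: dataclasses.replace(f, distended_or_contracted=True),
    lambda f: dataclasses.replace(f, ungraspable_with_forceps=True),
    lambda f: dataclasses.replace(f, stone_impacted_hartmann_ge_1cm=True),
    lambda f: dataclasses.replace(f, bmi=max(f.bmi, 35.0)),
    lambda f: dataclasses.replace(f, adhesions_prev_surgery_limiting_access=True),
    lambda f: dataclasses.replace(f, bile_or_pus_outside_gb=True),
    lambda f: dataclasses.replace(
        f, time_to_identify_cystic_structures_min=max(f.time_to_identify_cystic_structures_min, 120.0)
    ),
    lambda f: dataclasses.replace(f, bile_stone_spillage=True),
    lambda f: dataclasses.replace(f, injury="both"),
    lambda f: dataclasses.replace(f, conversion_to_open=True),
    lambda f: dataclasses.replace(f, ligature="stitch"),
]


class TestScoreProperties:
    @given(preop_profiles())
    def test_preop_total_bounded_and_breakdown_sums(self, profile):
        r = score_preop(profile)
        assert 0 <= r.total <= 11
        assert r.total == sum(p for _, p in r.breakdown)
        assert r.band == band_for_total("preop", r.total)

    @given(intraop_findings())
    def test_intraop_totals_bounded_and_breakdowns_sum(self, findings):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # artery_only draws a warning
            rs = score_sugrue(findings)
            rm = score_modified(findings)
        assert 0 <= rs.total <= 10
        assert 0 <= rm.total <= 16
        assert rs.total == sum(p for _, p in rs.breakdown)
        assert rm.total == sum(p for _, p in rm.breakdown)

    @given(preop_profiles())
    def test_preop_monotone_under_single_item_worsening(self, profile):
        base = score_preop(profile)
        for move in _PREOP_MOVES:
            worse = score_preop(move(profile))
            assert worse.total >= base.total
            assert _band_rank("preop", worse.band) >= _band_rank("preop", base.band)

    @given(intraop_findings())
    def test_intraop_monotone_under_single_item_worsening(self, findings):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for scorer, system in ((score_sugrue, "standard"), (score_modified, "modified")):
                base = scorer(findings)
                for move in _INTRAOP_MOVES:
                    worse = scorer(move(findings))
                    assert worse.total >= base.total
                    assert _band_rank(system, worse.band) >= _band_rank(system, base.band)

    @given(intraop_findings())
    def test_systems_agree_when_only_shared_items_active(self, findings):
        # without spillage, injury, conversion, stitch ligature or bile/pus
        # the modified grade reduces exactly to the standard one
        f = dataclasses.replace(
            findings,
            bile_stone_spillage=False,
            injury="none",
            conversion_to_open=False,
            ligature="clip",
            bile_or_pus_outside_gb=False,
        )
        assert score_modified(f).total == score_sugrue(f).total
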