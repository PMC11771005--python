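import dataclasses

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from dlcscore import IntraopFindings, PreopProfile

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@st.composite
def preop_profiles(draw):
    return PreopProfile(
        age=draw(st.integers(min_value=18, max_value=95)),
        sex=draw(st.sampled_from(["female", "male"])),
        admission_history_acute_cholecystitis=draw(st.booleans()),
        bmi=draw(st.floats(min_value=15.0, max_value=55.0, allow_nan=False)),
        palpable_gb=draw(st.booleans()),
        abdominal_scar=draw(
            st.sampled_from(["none", "infraumbilical", "supraumbilical"])
        ),
        impacted_stone_imaging=draw(st.booleans()),
    )


@st.composite
def intraop_findings(draw):
    return IntraopFindings(
        adhesion_grade=draw(st.sampled_from(["none", "less_than_50pct", "burying_gb"])),
        distended_or_contracted=draw(st.booleans()),
        ungraspable_with_forceps=draw(st.booleans()),
        stone_impacted_hartmann_ge_1cm=draw(st.booleans()),
        bmi=draw(st.floats(min_value=15.0, max_value=55.0, allow_nan=False)),
        adhesions_prev_surgery_limiting_access=draw(st.booleans()),
        bile_or_pus_outside_gb=draw(st.booleans()),
        time_to_identify_cystic_structures_min=draw(
            st.floats(min_value=0.0, max_value=240.0, allow_nan=False)
        ),
        bile_stone_spillage=draw(st.booleans()),
        injury=draw(st.sampled_from(["none", "duct_only", "artery_only", "both"])),
        conversion_to_open=draw(st.booleans()),
        ligature=draw(st.sampled_from(["clip", "stitch"])),
    )


@pytest.fixture
def worst_preop() -> PreopProfile:
    """Every item at its highest-point level (male sex included)."""
    return PreopProfile(
        age=55,
        sex="male",
        admission_history_acute_cholecystitis=True,
        bmi=32.0,
        palpable_gb=True,
        abdominal_scar="supraumbilical",
        impacted_stone_imaging=True,
    )


@pytest.fixture
def benign_preop() -> PreopProfile:
    return PreopProfile(
        age=40,
        sex="female",
        admission_history_acute_cholecystitis=False,
        bmi=25.0,
        palpable_gb=False,
        abdominal_scar="none",
        impacted_stone_imaging=False,
    )


@pytest.fixture
def worst_findings() -> IntraopFindings:
    """Maximizes every component of both intraoperative systems."""
    return IntraopFindings(
        adhesion_grade="burying_gb",
        distended_or_contracted=True,
        ungraspable_with_forceps=True,
        stone_impacted_hartmann_ge_1cm=True,
        bmi=32.0,
        adhesions_prev_surgery_limiting_access=True,
        bile_or_pus_outside_gb=True,
        time_to_identify_cystic_structures_min=120.0,
        bile_stone_spillage=True,
        injury="both",
        conversion_to_open=True,
        ligature="stitch",
    )


@pytest.fixture
def benign_findings() -> IntraopFindings:
    return IntraopFindings(
        adhesion_grade="none",
        distended_or_contracted=False,
        ungraspable_with_forceps=False,
        stone_impacted_hartmann_ge_1cm=False,
        bmi=25.0,
        adhesions_prev_surgery_limiting_access=False,
        bile_or_pus_outside_gb=False,
        time_to_identify_cystic_structures_min=60.0,
        bile_stone_spillage=False,
        injury="none",
        conversion_to_open=False,
        ligature="clip",
    )


def replace(record, **kwargs):
    return dataclasses.replace(record, **kwargs)
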