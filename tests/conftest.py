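import pytest

from cvdrisk.cohort import DrinkFrequency, ParticipantRecord, Sex
from cvdrisk.index import default_score_model


def make_record(**overrides) -> ParticipantRecord:
    """A healthy 45-year-old baseline record; override fields per test."""
    base = dict(
        id=1,
        sex=Sex.FEMALE,
        age_years=45,
        sbp_mmHg=118.0,
        dbp_mmHg=72.0,
        height_m=1.65,
        weight_kg=60.0,
        fpg_mmol_L=5.0,
        pg2h_mmol_L=None,
        tc_mmol_L=4.5,
        tg_mmol_L=1.2,
        hdl_mmol_L=1.5,
        smoker_6mo=False,
        drink_frequency=DrinkFrequency.NEVER,
        exercise_sessions_per_week=4,
        exercise_minutes_per_session=45.0,
        heavy_physical_labor=False,
        dx_hypertension=False,
        on_antihypertensives=False,
        on_lipid_drugs=False,
        on_glucose_drugs_or_insulin=False,
        family_history_cvd=False,
        cardiopathy=False,
        cvd_case=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def score_model():
    return default_score_model()
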