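"""Domain types and deterministic diagnostic coding of raw survey records.

Raw survey records (demographics, physical exam, laboratory values and
medical history) are coded into binary risk-factor profiles using fixed
diagnostic thresholds.  All classifiers are pure functions; coding the same
cohort twice yields identical profiles.

Units are fixed: blood pressure in mmHg, glucose and lipids in mmol/L,
height in metres, weight in kg.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Optional

import pandas as pd

__all__ = [
    "Sex",
    "DrinkFrequency",
    "ExerciseStatus",
    "InvalidRecordError",
    "ParticipantRecord",
    "RiskFactorProfile",
    "MODEL_FACTORS",
    "classify_hypertension",
    "classify_diabetes",
    "classify_dyslipidemia",
    "classify_obesity",
    "classify_exercise",
    "classify_drinking",
    "derive_profile",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_profiles_csv",
    "write_profiles_csv",
    "profiles_to_frame",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class DrinkFrequency(str, enum.Enum):
    NEVER = "never"
    OCCASIONAL = "occasional"
    FREQUENT = "frequent"


class ExerciseStatus(str, enum.Enum):
    SUFFICIENT = "sufficient"
    LACK = "lack"


class InvalidRecordError(ValueError):
    """Raised when a record violates a physiological or structural invariant."""


#: The six binary factors entering the regression and score model, in the
#: order used throughout the package.
MODEL_FACTORS = (
    "age_ge_60",
    "lack_of_exercise",
    "smoking",
    "hypertension",
    "diabetes",
    "family_history_cvd",
)


@dataclass(frozen=True)
class ParticipantRecord:
    """One survey respondent's raw fields.

    ``pg2h_mmol_L`` (2-h postprandial glucose) may be absent (``None``);
    it is then treated as not measured.
    """

    id: int
    sex: Sex
    age_years: int
    sbp_mmHg: float
    dbp_mmHg: float
    height_m: float
    weight_kg: float
    fpg_mmol_L: float
    tc_mmol_L: float
    tg_mmol_L: float
    hdl_mmol_L: float
    smoker_6mo: bool
    drink_frequency: DrinkFrequency
    exercise_sessions_per_week: int
    exercise_minutes_per_session: float
    heavy_physical_labor: bool
    dx_hypertension: bool
    on_antihypertensives: bool
    on_lipid_drugs: bool
    on_glucose_drugs_or_insulin: bool
    family_history_cvd: bool
    cardiopathy: bool
    cvd_case: bool
    pg2h_mmol_L: Optional[float] = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise InvalidRecordError(f"record id must be positive, got {self.id}")
        if self.age_years < 40:
            raise InvalidRecordError(
                f"record {self.id}: age_years must be >= 40 (inclusion criterion), "
                f"got {self.age_years}"
            )
        positives = {
            "sbp_mmHg": self.sbp_mmHg,
            "dbp_mmHg": self.dbp_mmHg,
            "height_m": self.height_m,
            "weight_kg": self.weight_kg,
            "fpg_mmol_L": self.fpg_mmol_L,
            "tc_mmol_L": self.tc_mmol_L,
            "tg_mmol_L": self.tg_mmol_L,
            "hdl_mmol_L": self.hdl_mmol_L,
        }
        if self.pg2h_mmol_L is not None:
            positives["pg2h_mmol_L"] = self.pg2h_mmol_L
        for name, value in positives.items():
            if not value > 0:
                raise InvalidRecordError(
                    f"record {self.id}: {name} must be strictly positive, got {value}"
                )
        if self.exercise_sessions_per_week < 0:
            raise InvalidRecordError(
                f"record {self.id}: exercise_sessions_per_week must be >= 0"
            )
        if self.exercise_minutes_per_session < 0:
            raise InvalidRecordError(
                f"record {self.id}: exercise_minutes_per_session must be >= 0"
            )


@dataclass(frozen=True)
class RiskFactorProfile:
    """Coded binary risk factors plus descriptive covariates and the outcome.

    The six model factors are ``age_ge_60``, ``lack_of_exercise``,
    ``smoking``, ``hypertension``, ``diabetes`` and ``family_history_cvd``;
    the remaining booleans are descriptive only.
    """

    id: int
    age_ge_60: bool
    lack_of_exercise: bool
    hypertension: bool
    diabetes: bool
    smoking: bool
    family_history_cvd: bool
    sex: Sex
    alcohol: bool
    obesity: bool
    dyslipidemia: bool
    cardiopathy: bool
    cvd_case: bool

    def factor_values(self) -> tuple[int, ...]:
        """The six model-factor indicators as 0/1 in canonical order."""
        return tuple(int(getattr(self, f)) for f in MODEL_FACTORS)


def classify_hypertension(dx: bool, on_meds: bool, sbp: float, dbp: float) -> bool:
    """Code hypertension from diagnosis/medication history and measured pressure.

    A prior clinical diagnosis combined with current antihypertensive use
    counts as hypertensive regardless of the measured pressure; everyone
    else is coded from the measurement (SBP >= 140 mmHg and/or
    DBP >= 90 mmHg).
    """
    if not sbp > 0 or not dbp > 0:
        raise InvalidRecordError(
            f"blood pressures must be strictly positive, got sbp={sbp}, dbp={dbp}"
        )
    if dx and on_meds:
        return True
    return sbp >= 140 or dbp >= 90


def classify_diabetes(fpg: float, pg2h: Optional[float], on_meds: bool) -> bool:
    """Code diabetes: FPG >= 7.0, 2-h postprandial >= 11.1, or on treatment.

    A missing 2-h value means "not measured": the criterion is a
    disjunction, so absence of one disjunct cannot force positivity.
    """
    if not fpg > 0:
        raise InvalidRecordError(f"fpg must be strictly positive, got {fpg}")
    if pg2h is not None and not pg2h > 0:
        raise InvalidRecordError(f"pg2h must be strictly positive when present, got {pg2h}")
    return on_meds or fpg >= 7.0 or (pg2h is not None and pg2h >= 11.1)


def classify_dyslipidemia(tc: float, tg: float, hdl: float, on_lipid_drugs: bool) -> bool:
    """Code dyslipidemia: TC >= 6.22, TG >= 2.26, HDL < 1.04 (mmol/L), or on drugs."""
    for name, value in (("tc", tc), ("tg", tg), ("hdl", hdl)):
        if not value > 0:
            raise InvalidRecordError(f"{name} must be strictly positive, got {value}")
    return on_lipid_drugs or tc >= 6.22 or tg >= 2.26 or hdl < 1.04


def classify_obesity(height: float, weight: float) -> bool:
    """Code obesity as BMI >= 28 kg/m^2 (inclusive)."""
    if not height > 0 or not weight > 0:
        raise InvalidRecordError(
            f"height and weight must be strictly positive, got {height}, {weight}"
        )
    return weight / height**2 >= 28.0


def classify_exercise(
    sessions_per_week: int, minutes: float, heavy_labor: bool
) -> ExerciseStatus:
    """Sufficient iff >= 3 sessions/week of >= 30 min each, or heavy physical labor."""
    if (sessions_per_week >= 3 and minutes >= 30) or heavy_labor:
        return ExerciseStatus.SUFFICIENT
    return ExerciseStatus.LACK


def classify_drinking(
    drinks_daily_over_year: bool, liquor_times_per_week: int, ml_each: float
) -> DrinkFrequency:
    """Three-level drinking frequency.

    Frequent: liquor >= 3 times/week and >= 100 mL each time.  Never: no
    drinking at all.  Anything else is occasional.
    """
    if liquor_times_per_week >= 3 and ml_each >= 100:
        return DrinkFrequency.FREQUENT
    if not drinks_daily_over_year and liquor_times_per_week == 0:
        return DrinkFrequency.NEVER
    return DrinkFrequency.OCCASIONAL


def derive_profile(record: ParticipantRecord) -> RiskFactorProfile:
    """Apply every classifier to a raw record; deterministic and idempotent."""
    try:
        return RiskFactorProfile(
            id=record.id,
            age_ge_60=record.age_years >= 60,
            lack_of_exercise=(
                classify_exercise(
                    record.exercise_sessions_per_week,
                    record.exercise_minutes_per_session,
                    record.heavy_physical_labor,
                )
                is ExerciseStatus.LACK
            ),
            hypertension=classify_hypertension(
                record.dx_hypertension,
                record.on_antihypertensives,
                record.sbp_mmHg,
                record.dbp_mmHg,
            ),
            diabetes=classify_diabetes(
                record.fpg_mmol_L, record.pg2h_mmol_L, record.on_glucose_drugs_or_insulin
            ),
            smoking=record.smoker_6mo,
            family_history_cvd=record.family_history_cvd,
            sex=record.sex,
            alcohol=record.drink_frequency is not DrinkFrequency.NEVER,
            obesity=classify_obesity(record.height_m, record.weight_kg),
            dyslipidemia=classify_dyslipidemia(
                record.tc_mmol_L, record.tg_mmol_L, record.hdl_mmol_L, record.on_lipid_drugs
            ),
            cardiopathy=record.cardiopathy,
            cvd_case=record.cvd_case,
        )
    except InvalidRecordError as exc:
        raise InvalidRecordError(f"record {record.id}: {exc}") from exc


# ---------------------------------------------------------------------------
# CSV interfaces.  Booleans serialize as 0/1; missing pg2h as an empty cell.

_RECORD_BOOL_FIELDS = frozenset(
    f.name for f in fields(ParticipantRecord) if f.type == "bool"
)
_PROFILE_BOOL_FIELDS = frozenset(
    f.name for f in fields(RiskFactorProfile) if f.type == "bool"
)


def write_cohort_csv(records: list[ParticipantRecord], path) -> None:
    rows = []
    for r in records:
        row = {}
        for f in fields(ParticipantRecord):
            v = getattr(r, f.name)
            if isinstance(v, enum.Enum):
                v = v.value
            elif isinstance(v, bool):
                v = int(v)
            row[f.name] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields(ParticipantRecord):
            v = row[f.name]
            if f.name == "pg2h_mmol_L":
                kwargs[f.name] = None if pd.isna(v) else float(v)
            elif f.name == "sex":
                kwargs[f.name] = Sex(v)
            elif f.name == "drink_frequency":
                kwargs[f.name] = DrinkFrequency(v)
            elif f.name in _RECORD_BOOL_FIELDS:
                kwargs[f.name] = bool(int(v))
            elif f.name in ("id", "age_years", "exercise_sessions_per_week"):
                kwargs[f.name] = int(v)
            else:
                kwargs[f.name] = float(v)
        records.append(ParticipantRecord(**kwargs))
    return records


def profiles_to_frame(profiles: list[RiskFactorProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame with 0/1 ints and string sex."""
    rows = []
    for p in profiles:
        row = {}
        for f in fields(RiskFactorProfile):
            v = getattr(p, f.name)
            if isinstance(v, enum.Enum):
                v = v.value
            elif isinstance(v, bool):
                v = int(v)
            row[f.name] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=[f.name for f in fields(RiskFactorProfile)])


def write_profiles_csv(profiles: list[RiskFactorProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles_csv(path) -> list[RiskFactorProfile]:
    df = pd.read_csv(path)
    profiles = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields(RiskFactorProfile):
            v = row[f.name]
            if f.name == "sex":
                kwargs[f.name] = Sex(v)
            elif f.name == "id":
                kwargs[f.name] = int(v)
            else:
                kwargs[f.name] = bool(int(v))
        profiles.append(RiskFactorProfile(**kwargs))
    return profiles
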