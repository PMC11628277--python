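"""Patient-level scoring and risk-group assignment.

A patient's total score is the sum, over the eight model factors, of the
points of the single stratum their record falls in.  Totals are cut into
four risk groups (low / intermediate / high / very high) at configurable
cutpoints, by default 6, 11.25 and 17.5 points, with each boundary
belonging to the lower group (a score must exceed a cutpoint to move up).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .score import FACTOR_FIELDS, ScoreError, ScoreTable

#: BMI plausibility window (kg/m2); values outside are rejected as input errors
BMI_WINDOW = (10.0, 70.0)

#: default risk-group cutpoints on the score line
DEFAULT_CUTPOINTS = (6.0, 11.25, 17.5)

#: administrative follow-up horizon of the 6-month relapse endpoint
FOLLOWUP_HORIZON_DAYS = 183.0


class CohortError(ValueError):
    """Invalid patient record or scoring request."""


class RiskGroup(str, enum.Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def rank(self) -> int:
        return list(RiskGroup).index(self)


@dataclass(frozen=True)
class PatientRecord:
    """Predictors (and optionally the 6-month relapse outcome) of one patient.

    ``higher_relief`` flags achievement of PASI 90 during treatment;
    ``faster_relief`` flags PASI 75 within 8 weeks.  Relapse means loss of
    PASI 75 or resumption of systemic therapy within the 183-day horizon;
    ``followup_days`` is the relapse time for relapsers and the censoring
    time otherwise.
    """

    patient_id: str
    bmi: float
    smoker: bool
    disease_course_gt2y: bool
    psa: bool
    higher_relief: bool
    faster_relief: bool
    prior_biologics: bool
    treatment_months: float
    relapsed: bool | None = None
    followup_days: float | None = None

    def __post_init__(self) -> None:
        if not BMI_WINDOW[0] < self.bmi < BMI_WINDOW[1]:
            raise CohortError(
                f"patient {self.patient_id}: BMI {self.bmi} outside the "
                f"plausibility window {BMI_WINDOW}")
        if self.treatment_months <= 0:
            raise CohortError(
                f"patient {self.patient_id}: treatment_months must be positive")
        if self.relapsed is not None and self.followup_days is None:
            raise CohortError(
                f"patient {self.patient_id}: outcome present without a "
                "follow-up time")
        if self.followup_days is not None and not (
                0 <= self.followup_days <= FOLLOWUP_HORIZON_DAYS):
            raise CohortError(
                f"patient {self.patient_id}: followup_days must lie in "
                f"[0, {FOLLOWUP_HORIZON_DAYS}] for the 6-month design")


@dataclass(frozen=True)
class ScoredPatient:
    patient_id: str
    total_score: float
    per_factor_points: Mapping[str, float]
    risk_group: RiskGroup
    relapsed: bool | None = None
    followup_days: float | None = None


def assign_risk_group(
        total_score: float,
        cutpoints: Sequence[float] = DEFAULT_CUTPOINTS) -> RiskGroup:
    """Map a total score to its risk group.

    Groups are [0, c1], (c1, c2], (c2, c3], (c3, inf): a boundary score
    stays in the lower group, matching the cutoff semantics under which a
    score must exceed the operating threshold to be called high risk.
    """
    c1, c2, c3 = cutpoints
    if not c1 < c2 < c3:
        raise CohortError(f"cutpoints must be strictly increasing, got "
                          f"{tuple(cutpoints)}")
    if total_score < 0:
        raise CohortError("total score cannot be negative")
    if total_score <= c1:
        return RiskGroup.LOW
    if total_score <= c2:
        return RiskGroup.INTERMEDIATE
    if total_score <= c3:
        return RiskGroup.HIGH
    return RiskGroup.VERY_HIGH


def score_patient(patient: PatientRecord, table: ScoreTable,
                  cutpoints: Sequence[float] = DEFAULT_CUTPOINTS) -> ScoredPatient:
    """Score one patient: each factor contributes exactly one stratum."""
    per_factor: dict[str, float] = {}
    for factor in table.factor_ids:
        field_name = FACTOR_FIELDS.get(factor)
        if field_name is None:
            raise CohortError(f"factor {factor!r} has no patient field mapping")
        value = getattr(patient, field_name, None)
        if value is None:
            raise CohortError(
                f"patient {patient.patient_id}: missing predictor "
                f"{field_name!r}")
        matches = [s for s in table.strata(factor) if s.predicate.matches(value)]
        if len(matches) != 1:
            raise ScoreError(
                f"factor {factor!r}: value {value!r} matched "
                f"{len(matches)} strata (table is not a partition)")
        per_factor[factor] = matches[0].points
    total = float(sum(per_factor.values()))
    return ScoredPatient(
        patient_id=patient.patient_id,
        total_score=total,
        per_factor_points=per_factor,
        risk_group=assign_risk_group(total, cutpoints),
        relapsed=patient.relapsed,
        followup_days=patient.followup_days,
    )


def score_cohort(patients: Iterable[PatientRecord], table: ScoreTable,
                 cutpoints: Sequence[float] = DEFAULT_CUTPOINTS) -> pd.DataFrame:
    """Score a cohort; one row per patient, factor points in columns."""
    rows = []
    for p in patients:
        sp = score_patient(p, table, cutpoints)
        row = {"patient_id": sp.patient_id, "total_score": sp.total_score,
               "risk_group": sp.risk_group.value}
        row.update({f"points_{k}": v for k, v in sp.per_factor_points.items()})
        row["relapsed"] = sp.relapsed
        row["followup_days"] = sp.followup_days
        rows.append(row)
    if not rows:
        raise CohortError("empty cohort")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- I/O

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}

_BOOL_FIELDS = ("smoker", "disease_course_gt2y", "psa", "higher_relief",
                "faster_relief", "prior_biologics")


def _parse_bool(value, column: str):
    if pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise CohortError(f"cannot parse boolean {value!r} in column {column!r}")


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read patients from a header-named CSV; booleans accept 0/1/yes/no."""
    df = pd.read_csv(path)
    required = {"patient_id", "bmi", "treatment_months", *_BOOL_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"missing columns in {path}: {sorted(missing)}")
    records = []
    for row in df.to_dict(orient="records"):
        kwargs = {
            "patient_id": str(row["patient_id"]),
            "bmi": float(row["bmi"]),
            "treatment_months": float(row["treatment_months"]),
        }
        for b in _BOOL_FIELDS:
            val = _parse_bool(row[b], b)
            if val is None:
                raise CohortError(f"patient {kwargs['patient_id']}: missing "
                                  f"predictor {b!r}")
            kwargs[b] = val
        if "relapsed" in df.columns:
            kwargs["relapsed"] = _parse_bool(row["relapsed"], "relapsed")
        if "followup_days" in df.columns and pd.notna(row["followup_days"]):
            kwargs["followup_days"] = float(row["followup_days"])
        records.append(PatientRecord(**kwargs))
    return records


def cohort_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in patients])


def write_cohort_csv(patients: Iterable[PatientRecord], path) -> None:
    cohort_to_frame(patients).to_csv(path, index=False)
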