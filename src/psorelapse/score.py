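"""Additive point-score construction from pooled relative risks.

Each risk factor's weight is its log relative risk (beta = ln RR) scaled
by 10 and rounded to the score lattice; continuous factors (BMI,
treatment course) are stratified, with stratum points proportional to the
unit offset of the stratum from its reference.  The canonical published
scoring table ships as packaged data and is authoritative for scoring
patients; tables derived from pooled RRs are used to verify it within a
rounding tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping, Sequence

from .meta import PooledEffect

Rounding = Literal["nearest_integer", "nearest_half", "none"]

#: the eight factors of the final relapse model
MODEL_FACTORS = (
    "bmi", "smoking", "disease_course", "psa", "higher_relief",
    "faster_relief", "prior_biologics", "treatment_course",
)

#: which PatientRecord field each factor reads
FACTOR_FIELDS = {
    "bmi": "bmi",
    "smoking": "smoker",
    "disease_course": "disease_course_gt2y",
    "psa": "psa",
    "higher_relief": "higher_relief",
    "faster_relief": "faster_relief",
    "prior_biologics": "prior_biologics",
    "treatment_course": "treatment_months",
}

#: unit offsets of the scored BMI strata from the reference stratum,
#: used to turn the per-unit BMI RR into stratum points
DEFAULT_BMI_OFFSETS = {"24 ~ 27.99": 5.0, ">=28": 10.0}


class ScoreError(ValueError):
    """Invalid scoring table or scoring request."""


@dataclass(frozen=True)
class PooledSummary:
    """A pooled RR with its 95% CI, as published, without study-level detail.

    Stands in for a full pooled record when only the pooled estimate is
    reported; sufficient input for table construction, which reads just
    ``factor_id`` and ``rr``.
    """

    factor_id: str
    rr: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ScoreError("CI must bracket a positive RR")


def published_pooled_effects() -> list[PooledSummary]:
    """The pooled RRs of the eight final model factors, as packaged data."""
    src = resources.files("psorelapse.data").joinpath("published_pooled_rr.json")
    return [PooledSummary(**r)
            for r in json.loads(src.read_text(encoding="utf-8"))]


def published_meta_factors() -> dict:
    """Factor ids found significant in meta-analysis plus collinear groups."""
    src = resources.files("psorelapse.data").joinpath("meta_factors.json")
    return json.loads(src.read_text(encoding="utf-8"))


@dataclass(frozen=True)
class Predicate:
    """Machine-readable stratum membership condition on one record field.

    ``kind`` is ``"flag"`` (boolean equality with ``value``) or
    ``"interval"`` (half-open/closed numeric interval ``low``..``high``;
    ``None`` means unbounded).
    """

    kind: Literal["flag", "interval"]
    value: bool | None = None
    low: float | None = None
    high: float | None = None
    low_closed: bool = True
    high_closed: bool = False

    def matches(self, x) -> bool:
        if self.kind == "flag":
            return bool(x) == self.value
        if self.low is not None:
            if x < self.low or (x == self.low and not self.low_closed):
                return False
        if self.high is not None:
            if x > self.high or (x == self.high and not self.high_closed):
                return False
        return True

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "flag":
            d["value"] = self.value
        else:
            d.update(low=self.low, high=self.high,
                     low_closed=self.low_closed, high_closed=self.high_closed)
        return d


@dataclass(frozen=True)
class ScoreItem:
    """One stratum of one factor: label, membership predicate and points.

    ``raw_value`` carries the unrounded |10 beta| magnitude for derived
    tables; it is ``None`` on the canonical table.
    """

    factor_id: str
    stratum_label: str
    predicate: Predicate
    points: float
    raw_value: float | None = None

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ScoreError("points must be nonnegative")
        if round(self.points * 2) != self.points * 2:
            raise ScoreError(
                f"points must fall on the half-point lattice, got {self.points}")


@dataclass(frozen=True)
class ScoreTable:
    items: tuple[ScoreItem, ...]
    version_tag: str = "unversioned"
    provenance: Literal["canonical", "derived"] = "derived"

    def __post_init__(self) -> None:
        if not self.items:
            raise ScoreError("empty score table")

    @property
    def factor_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for it in self.items:
            if it.factor_id not in seen:
                seen.append(it.factor_id)
        return tuple(seen)

    def strata(self, factor_id: str) -> tuple[ScoreItem, ...]:
        out = tuple(i for i in self.items if i.factor_id == factor_id)
        if not out:
            raise ScoreError(f"unknown factor {factor_id!r}")
        return out

    def max_total(self) -> float:
        return sum(max(i.points for i in self.strata(f))
                   for f in self.factor_ids)

    def min_total(self) -> float:
        return sum(min(i.points for i in self.strata(f))
                   for f in self.factor_ids)

    def to_dict(self) -> dict:
        return {
            "version_tag": self.version_tag,
            "provenance": self.provenance,
            "items": [
                {"factor_id": i.factor_id, "stratum_label": i.stratum_label,
                 "predicate": i.predicate.to_dict(), "points": i.points,
                 **({"raw_value": i.raw_value} if i.raw_value is not None else {})}
                for i in self.items
            ],
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreTable":
        items = tuple(
            ScoreItem(
                factor_id=i["factor_id"],
                stratum_label=i["stratum_label"],
                predicate=Predicate(**i["predicate"]),
                points=float(i["points"]),
                raw_value=i.get("raw_value"),
            )
            for i in d["items"]
        )
        return cls(items=items, version_tag=d.get("version_tag", "unversioned"),
                   provenance=d.get("provenance", "derived"))

    @classmethod
    def load(cls, path) -> "ScoreTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def canonical_table(invert_remission_factors: bool = False) -> ScoreTable:
    """The published scoring table, as packaged data.

    With ``invert_remission_factors=True`` the points of the two lesion
    remission factors (achieving PASI 90; PASI 75 within 8 weeks) are
    moved from the "Yes" to the "No" strata, the encoding consistent with
    their protective pooled RRs; the default keeps the table exactly as
    printed.
    """
    src = resources.files("psorelapse.data").joinpath(
        "canonical_score_table.json")
    table = ScoreTable.from_dict(json.loads(src.read_text(encoding="utf-8")))
    if not invert_remission_factors:
        return table
    items = []
    for it in table.items:
        if it.factor_id in ("higher_relief", "faster_relief"):
            partner = next(o.points for o in table.strata(it.factor_id)
                           if o is not it)
            items.append(ScoreItem(it.factor_id, it.stratum_label,
                                   it.predicate, partner))
        else:
            items.append(it)
    return ScoreTable(items=tuple(items),
                      version_tag=table.version_tag + "+inverted-remission",
                      provenance="canonical")


# ------------------------------------------------------- construction

def beta_from_rr(rr: float) -> float:
    """beta = ln RR, the log-linear weight of a factor."""
    if rr <= 0:
        raise ScoreError(f"RR must be strictly positive, got {rr!r}")
    return math.log(rr)


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5)


def round_points(value: float, rounding: Rounding) -> float:
    """Round a nonnegative |10 beta| magnitude to the score lattice."""
    if value < 0:
        raise ScoreError("point magnitude must be nonnegative")
    if rounding == "nearest_integer":
        return float(_round_half_away(value))
    if rounding == "nearest_half":
        return _round_half_away(value * 2.0) / 2.0
    if rounding == "none":
        return value
    raise ScoreError(f"unknown rounding policy {rounding!r}")


def points_from_beta(beta: float, rounding: Rounding = "nearest_integer") -> float:
    """Points carried by a binary factor: |10 beta| rounded per policy.

    A protective factor (beta < 0) carries the same magnitude of points,
    attached by the table builder to its risk-direction stratum.
    """
    return round_points(abs(10.0 * beta), rounding)


def screen_collinear(factor_ids: Sequence[str],
                     collinear_groups: Sequence[Sequence[str]]) -> list[str]:
    """Drop all but the preferred member of each collinear factor group.

    ``collinear_groups`` lists groups with the preferred (kept) factor
    first, mirroring the model-development choice of BMI over weight and
    the binary over the continuous disease-duration coding.
    """
    drop = {f for group in collinear_groups for f in group[1:]}
    return [f for f in factor_ids if f not in drop]


_BINARY_FACTORS = ("smoking", "disease_course", "psa", "higher_relief",
                   "faster_relief", "prior_biologics")

_BINARY_LABELS = {  # (reference stratum, scored stratum) when RR > 1
    "smoking": ("No", "Yes"),
    "disease_course": ("<=2", ">2"),
    "psa": ("No", "Yes"),
    "higher_relief": ("No", "Yes"),
    "faster_relief": ("No", "Yes"),
    "prior_biologics": ("No", "Yes"),
}


def build_derived_table(pooled: Sequence[PooledEffect | PooledSummary],
                        bmi_strata_offsets: Mapping[str, float] | None = None,
                        rounding: Rounding = "nearest_integer") -> ScoreTable:
    """Derive a scoring table from pooled RRs for the eight model factors.

    Binary factors carry |10 ln RR| rounded per ``rounding`` on their
    risk-direction stratum (the exposed stratum when RR > 1, the
    unexposed one when RR < 1).  BMI, whose RR is per unit, carries
    |10 ln RR| * offset per scored stratum; treatment course carries its
    points on the short-course (<= 10.75 months) stratum.  The two
    half-step factors (BMI, treatment course) always round to the
    nearest half point, the lattice the published table uses for them.
    """
    offsets = dict(DEFAULT_BMI_OFFSETS if bmi_strata_offsets is None
                   else bmi_strata_offsets)
    by_id = {p.factor_id: p for p in pooled}
    missing = [f for f in MODEL_FACTORS if f not in by_id]
    if missing:
        raise ScoreError(f"missing pooled factors: {missing}")

    items: list[ScoreItem] = []

    # BMI: three strata, per-unit RR scaled by each stratum's offset
    beta_bmi = beta_from_rr(by_id["bmi"].rr)
    items.append(ScoreItem("bmi", "<24",
                           Predicate("interval", high=24.0), 0.0, 0.0))
    for label, pred in (
            ("24 ~ 27.99", Predicate("interval", low=24.0, high=28.0,
                                     low_closed=True, high_closed=False)),
            (">=28", Predicate("interval", low=28.0, low_closed=True))):
        raw = abs(10.0 * beta_bmi * offsets[label])
        items.append(ScoreItem("bmi", label, pred,
                               round_points(raw, "nearest_half"), raw))

    for factor in _BINARY_FACTORS:
        eff = by_id[factor]
        beta = beta_from_rr(eff.rr)
        ref_label, scored_label = _BINARY_LABELS[factor]
        if beta < 0:
            # protective exposure: risk direction is the unexposed stratum
            ref_label, scored_label = scored_label, ref_label
        raw = abs(10.0 * beta)
        pts = round_points(raw, rounding)
        ref_val = ref_label in ("Yes", ">2")
        items.append(ScoreItem(factor, ref_label,
                               Predicate("flag", value=ref_val), 0.0, 0.0))
        items.append(ScoreItem(factor, scored_label,
                               Predicate("flag", value=not ref_val), pts, raw))

    # treatment course: shorter course is the risk stratum
    raw = abs(10.0 * beta_from_rr(by_id["treatment_course"].rr))
    items.append(ScoreItem(
        "treatment_course", "<=10.75",
        Predicate("interval", high=10.75, high_closed=True),
        round_points(raw, "nearest_half"), raw))
    items.append(ScoreItem(
        "treatment_course", ">10.75",
        Predicate("interval", low=10.75, low_closed=False), 0.0, 0.0))

    return ScoreTable(items=tuple(items), version_tag="derived-from-pooled",
                      provenance="derived")


# ------------------------------------------------------- verification

@dataclass(frozen=True)
class StratumCheck:
    factor_id: str
    canonical_label: str
    canonical_points: float
    derived_label: str
    derived_value: float
    discrepancy: float


@dataclass(frozen=True)
class VerificationReport:
    checks: tuple[StratumCheck, ...]
    tol: float

    @property
    def passed(self) -> bool:
        return all(c.discrepancy < self.tol for c in self.checks)

    @property
    def failures(self) -> tuple[StratumCheck, ...]:
        return tuple(c for c in self.checks if c.discrepancy >= self.tol)

    @property
    def max_discrepancy(self) -> float:
        return max(c.discrepancy for c in self.checks)


def verify_against_canonical(derived: ScoreTable, canonical: ScoreTable,
                             tol: float = 0.5) -> VerificationReport:
    """Compare a derived table's unrounded |10 beta| values to canonical points.

    Factors are matched by id and, within each factor, strata are matched
    by descending points, so the comparison is insensitive to which label
    ("Yes"/"No") a protective factor's points sit on.  Passes when every
    absolute discrepancy is below ``tol``.
    """
    if set(derived.factor_ids) != set(canonical.factor_ids):
        raise ScoreError(
            f"factor sets differ: derived {sorted(derived.factor_ids)} vs "
            f"canonical {sorted(canonical.factor_ids)}")
    checks: list[StratumCheck] = []
    for factor in canonical.factor_ids:
        can = sorted(canonical.strata(factor), key=lambda i: -i.points)
        der = sorted(derived.strata(factor), key=lambda i: -i.points)
        if len(can) != len(der):
            raise ScoreError(f"stratum count mismatch for {factor!r}: "
                             f"{len(der)} derived vs {len(can)} canonical")
        for c, d in zip(can, der):
            value = d.raw_value if d.raw_value is not None else d.points
            checks.append(StratumCheck(
                factor_id=factor,
                canonical_label=c.stratum_label,
                canonical_points=c.points,
                derived_label=d.stratum_label,
                derived_value=value,
                discrepancy=abs(value - c.points),
            ))
    return VerificationReport(checks=tuple(checks), tol=tol)
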