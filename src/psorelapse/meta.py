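"""Effect-size conversion and heterogeneity-gated meta-analytic pooling.

Per-study odds ratios, relative risks and hazard ratios for each relapse
risk factor are brought onto a common RR scale and pooled per factor by
inverse-variance weighting on the log scale.  Between-study heterogeneity
is quantified with Cochran's Q and I-squared; when heterogeneity is
material (Q p-value < 0.10 or I-squared > 50%) pooling switches from a
fixed-effect to a DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile used throughout for Wald intervals
Z95 = 1.959964

#: heterogeneity gate: random effects when q_pvalue < this ...
Q_PVALUE_GATE = 0.10
#: ... or when I-squared (percent) exceeds this
I2_GATE = 50.0

#: default control-group 6-month relapse proportion used for OR -> RR
#: conversion when a study does not report its own baseline risk
DEFAULT_BASELINE_RISK = 0.447

EffectType = Literal["OR", "RR", "HR"]
ModelType = Literal["fixed", "random"]


class MetaError(ValueError):
    """Invalid input to a pooling operation."""


@dataclass(frozen=True)
class StudyEffect:
    """One extracted per-study effect estimate for one risk factor.

    ``estimate``, ``ci_low`` and ``ci_high`` live on the ratio scale and
    must be strictly positive with ``ci_low < estimate < ci_high``.
    ``baseline_risk`` is the control-group event proportion, consumed by
    the OR -> RR conversion; ``adjustment_rank`` and ``followup_days``
    drive deduplication when a study reports several estimates for the
    same factor (most-adjusted, then longest follow-up wins).
    """

    study_id: str
    factor_id: str
    effect_type: EffectType
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    baseline_risk: float | None = None
    adjustment_rank: int = 0
    followup_days: float | None = None
    converted_from: EffectType | None = None

    def __post_init__(self) -> None:
        if self.effect_type not in ("OR", "RR", "HR"):
            raise MetaError(f"unknown effect type {self.effect_type!r}")
        for name in ("estimate", "ci_low", "ci_high"):
            if not getattr(self, name) > 0:
                raise MetaError(f"{name} must be strictly positive, got "
                                f"{getattr(self, name)!r}")
        if not (self.ci_low < self.estimate < self.ci_high):
            raise MetaError(
                f"CI must bracket the estimate: {self.ci_low} < "
                f"{self.estimate} < {self.ci_high} fails")
        if self.n <= 0:
            raise MetaError("sample size must be a positive integer")
        if self.baseline_risk is not None and not 0 < self.baseline_risk < 1:
            raise MetaError("baseline_risk must lie in (0, 1)")

    @property
    def log_estimate(self) -> float:
        return math.log(self.estimate)

    @property
    def log_se(self) -> float:
        return log_se_from_ci(self.ci_low, self.ci_high)


@dataclass(frozen=True)
class PooledEffect:
    """Pooled relative risk for one factor with heterogeneity diagnostics."""

    factor_id: str
    rr: float
    ci_low: float
    ci_high: float
    q_stat: float
    q_pvalue: float
    i_squared: float
    tau_squared: float
    model: ModelType
    k_studies: int
    forced: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low < self.rr < self.ci_high):
            raise MetaError("pooled CI must bracket the pooled RR")
        if not 0 <= self.i_squared <= 100:
            raise MetaError("I-squared must lie in [0, 100]")
        if self.tau_squared < 0 or self.q_stat < 0:
            raise MetaError("Q and tau-squared must be nonnegative")

    @property
    def beta(self) -> float:
        """Log relative risk, the scale on which points are derived."""
        return math.log(self.rr)


def log_se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error of the log effect from a 95% Wald CI on the ratio scale.

    Inverts ``exp(logEst +/- z * se)``: ``se = (ln hi - ln lo) / (2 z)``.
    """
    if not (ci_low > 0 and ci_high > 0):
        raise MetaError("CI bounds must be strictly positive")
    if ci_low > ci_high:
        raise MetaError("ci_low must not exceed ci_high")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)


def or_to_rr(odds_ratio: float, p0: float) -> float:
    """Convert an odds ratio to a relative risk at control-group risk ``p0``.

    Uses RR = OR / ((1 - p0) + p0 * OR), exact under the standard 2x2
    identity relating odds and risks.
    """
    if not 0 < p0 < 1:
        raise MetaError(f"baseline risk must lie in (0, 1), got {p0!r}")
    if odds_ratio <= 0:
        raise MetaError("odds ratio must be strictly positive")
    return odds_ratio / ((1.0 - p0) + p0 * odds_ratio)


def convert_to_rr(effect: StudyEffect,
                  default_p0: float = DEFAULT_BASELINE_RISK) -> StudyEffect:
    """Return ``effect`` expressed as a relative risk.

    RR input passes through unchanged.  HR is treated as RR at the fixed
    6-month horizon.  OR is converted with :func:`or_to_rr` applied to the
    estimate and both CI bounds, using the study's own control-group risk
    when available and ``default_p0`` otherwise.  Conversions are recorded
    in ``converted_from`` and logged.
    """
    if effect.effect_type == "RR":
        return effect
    if effect.effect_type == "HR":
        logger.info("treating HR as RR for %s/%s at the 6-month horizon",
                    effect.study_id, effect.factor_id)
        return replace(effect, effect_type="RR", converted_from="HR")
    p0 = effect.baseline_risk if effect.baseline_risk is not None else default_p0
    converted = replace(
        effect,
        effect_type="RR",
        estimate=or_to_rr(effect.estimate, p0),
        ci_low=or_to_rr(effect.ci_low, p0),
        ci_high=or_to_rr(effect.ci_high, p0),
        converted_from="OR",
    )
    logger.info("converted OR=%.4g to RR=%.4g for %s/%s (p0=%.3f)",
                effect.estimate, converted.estimate, effect.study_id,
                effect.factor_id, p0)
    return converted


def deduplicate(effects: Iterable[StudyEffect]) -> list[StudyEffect]:
    """Keep one estimate per (study, factor) pair.

    When a study contributes several estimates for the same factor the
    most-adjusted one (highest ``adjustment_rank``) is kept; ties fall to
    the longest follow-up, then to lexicographic study id for stability.
    """
    def sort_key(e: StudyEffect):
        fu = e.followup_days if e.followup_days is not None else -math.inf
        return (-e.adjustment_rank, -fu, e.study_id)

    best: dict[tuple[str, str], StudyEffect] = {}
    for e in sorted(effects, key=sort_key):
        best.setdefault((e.study_id, e.factor_id), e)
    return sorted(best.values(), key=lambda e: (e.factor_id, e.study_id))


def _dl_components(y: np.ndarray, v: np.ndarray) -> dict[str, float]:
    """Fixed-effect fit, Cochran's Q, I-squared and DL tau-squared."""
    w = 1.0 / v
    sw = w.sum()
    y_fixed = float((w * y).sum() / sw)
    q = float((w * (y - y_fixed) ** 2).sum())
    k = len(y)
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    c = sw - (w ** 2).sum() / sw
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    return {"y_fixed": y_fixed, "se_fixed": math.sqrt(1.0 / sw),
            "q": q, "i2": i2, "tau2": tau2, "k": k}


def pool(effects: Sequence[StudyEffect],
         force_model: ModelType | None = None) -> PooledEffect:
    """Pool RR-scale study effects for one factor.

    Inverse-variance weighting on the log-RR scale.  The fixed-effect fit
    supplies Cochran's Q (k-1 df) and I-squared; the DerSimonian-Laird
    moment estimator supplies tau-squared for the random-effects weights
    1/(v_i + tau2).  The model is chosen by the heterogeneity gate
    (q_pvalue < 0.10 or I2 > 50 -> random) unless ``force_model`` is set.
    """
    effects = list(effects)
    if len(effects) < 2:
        raise MetaError(
            "pooling needs at least two studies; pass a single-study "
            "effect through unpooled instead")
    factor_ids = {e.factor_id for e in effects}
    if len(factor_ids) != 1:
        raise MetaError(f"mixed factors in one pool: {sorted(factor_ids)}")
    not_rr = [e for e in effects if e.effect_type != "RR"]
    if not_rr:
        raise MetaError(
            "all effects must be RR-type before pooling; convert first "
            f"(offending studies: {[e.study_id for e in not_rr]})")

    y = np.array([e.log_estimate for e in effects])
    v = np.array([e.log_se ** 2 for e in effects])
    if np.any(v <= 0):
        raise MetaError("every study needs a nonzero CI width")

    comp = _dl_components(y, v)
    k = comp["k"]
    q_pvalue = float(stats.chi2.sf(comp["q"], df=k - 1))

    gate_random = q_pvalue < Q_PVALUE_GATE or comp["i2"] > I2_GATE
    model: ModelType = force_model if force_model is not None else (
        "random" if gate_random else "fixed")

    if model == "random":
        w_star = 1.0 / (v + comp["tau2"])
        y_hat = float((w_star * y).sum() / w_star.sum())
        se_hat = math.sqrt(1.0 / w_star.sum())
    else:
        y_hat, se_hat = comp["y_fixed"], comp["se_fixed"]

    logger.info("factor %s: Q=%.3f (p=%.3g), I2=%.1f%%, tau2=%.4g -> %s "
                "model%s", effects[0].factor_id, comp["q"], q_pvalue,
                comp["i2"], comp["tau2"], model,
                " (forced)" if force_model is not None else "")

    return PooledEffect(
        factor_id=effects[0].factor_id,
        rr=math.exp(y_hat),
        ci_low=math.exp(y_hat - Z95 * se_hat),
        ci_high=math.exp(y_hat + Z95 * se_hat),
        q_stat=comp["q"],
        q_pvalue=q_pvalue,
        i_squared=comp["i2"],
        tau_squared=comp["tau2"],
        model=model,
        k_studies=k,
        forced=force_model is not None,
    )


def sensitivity_switch(effects: Sequence[StudyEffect],
                       forced_model: ModelType) -> PooledEffect:
    """Re-pool under the opposite (or an explicit) model for robustness."""
    if forced_model not in ("fixed", "random"):
        raise MetaError(f"unknown model {forced_model!r}")
    return pool(effects, force_model=forced_model)


def pool_all(effects: Iterable[StudyEffect],
             default_p0: float = DEFAULT_BASELINE_RISK,
             force_model: ModelType | None = None) -> list[PooledEffect]:
    """Convert, deduplicate and pool every factor present in ``effects``."""
    converted = [convert_to_rr(e, default_p0=default_p0)
                 for e in deduplicate(effects)]
    by_factor: dict[str, list[StudyEffect]] = {}
    for e in converted:
        by_factor.setdefault(e.factor_id, []).append(e)
    return [pool(v, force_model=force_model)
            for _, v in sorted(by_factor.items())]


# ---------------------------------------------------------------- I/O

def read_study_effects(path) -> list[StudyEffect]:
    """Read per-study effects from a header-named CSV file."""
    df = pd.read_csv(path)
    required = {"study_id", "factor_id", "effect_type", "estimate",
                "ci_low", "ci_high", "n"}
    missing = required - set(df.columns)
    if missing:
        raise MetaError(f"missing columns in {path}: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        kwargs = dict(
            study_id=str(row.study_id),
            factor_id=str(row.factor_id),
            effect_type=str(row.effect_type).upper(),
            estimate=float(row.estimate),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
            n=int(row.n),
        )
        for opt in ("baseline_risk", "adjustment_rank", "followup_days"):
            if opt in df.columns:
                val = getattr(row, opt)
                if pd.notna(val):
                    kwargs[opt] = int(val) if opt == "adjustment_rank" else float(val)
        out.append(StudyEffect(**kwargs))
    return out


def pooled_to_frame(pooled: Sequence[PooledEffect]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in pooled])


def write_pooled(pooled: Sequence[PooledEffect], path) -> None:
    """Write pooled effects as JSON (list of records)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([asdict(p) for p in pooled], fh, indent=2)


def read_pooled(path) -> list[PooledEffect]:
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    return [PooledEffect(**r) for r in records]
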