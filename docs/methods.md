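# Methods

## Problem setting

Roughly a quarter to 60% of psoriasis patients who discontinue biologic
therapy after reaching remission relapse within six months (relapse
being loss of PASI 75 or resumption of systemic therapy). The package
implements an additive point score over eight clinical factors — BMI,
smoking, disease course > 2 years, psoriatic arthritis, extent and speed
of lesion remission, prior biologic exposure, and treatment-course
length — and the statistics used to validate such a score externally.

## Meta-analytic pooling

Study effects arrive as OR, RR or HR with 95% CIs. All are carried to
the RR scale before pooling:

- RR passes through; HR is treated as RR, defensible at a short fixed
  horizon where the cumulative-incidence and hazard scales nearly agree.
- OR is converted with RR = OR / ((1 − p₀) + p₀·OR), where p₀ is the
  control-group risk. When a study does not report p₀ the default 0.447
  (the 6-month relapse proportion of the reference validation
  population) is used. Every conversion is logged.

The log-scale standard error is recovered from the CI as
(ln hi − ln lo)/(2·1.959964). Pooling is inverse-variance on log RR.
From the fixed-effect fit, Cochran's Q = Σwᵢ(yᵢ − ŷ)² with k−1 degrees
of freedom, I² = max(0, (Q − (k−1))/Q)·100, and the DerSimonian–Laird
moment estimate τ² = max(0, (Q − (k−1))/C), C = Σwᵢ − Σwᵢ²/Σwᵢ.
Random-effects weights are 1/(vᵢ + τ²). The model is chosen by the
heterogeneity gate — random when the Q p-value < 0.10 or I² > 50% —
and can be forced either way for sensitivity analysis. DL was chosen
over REML because the gate-style workflow is the classical DL setting
and the estimator is closed-form and exactly testable by hand. When one
study reports several estimates for a factor, the most-adjusted one is
kept, ties broken by longest follow-up.

The implementation is cross-checked in the tests against an independent
step-by-step hand evaluation of the DL formulas (frozen to six decimals)
and against `statsmodels.stats.meta_analysis.combine_effects`; note
statsmodels reports the untruncated moment τ², which we truncate at 0.

## Score construction

Each factor's weight is β = ln RR of its pooled effect, scaled by 10.
Binary factors carry |10β| points on their risk-direction stratum (the
exposed stratum when RR > 1, the unexposed one when RR < 1). BMI enters
per unit, so its strata earn |10β·Δ| with Δ the offset of the stratum
midpoint region from reference — Δ = 5 for 24–27.99 kg/m² and Δ = 10
for ≥ 28 kg/m², calibrated so a per-unit RR of 1.03 yields the published
1.5 and 3 points. A treatment course ≤ 10.75 months carries the
short-course penalty; longer treatment is reference.

No single rounding rule reproduces the published table (10·ln 1.71 =
5.37 prints as 5, integer rounding, while 10·|ln 0.70| = 3.57 prints as
3.5, half-point rounding), so rounding is a named policy: binary factors
default to nearest-integer, while the two half-step factors (BMI strata,
treatment course) always round to the nearest half point. The canonical
published table ships as packaged JSON and is authoritative for scoring
patients; a table derived from pooled RRs is used only to verify the
canonical one, comparing unrounded |10β| magnitudes against canonical
points with tolerance 0.5 (the observed maximum gap is 0.365, on the
disease-course factor).

One genuine ambiguity in the source table is preserved rather than
resolved: the two remission factors have protective pooled RRs (0.60,
0.73) yet the printed table awards their points to the "Yes" strata.
The canonical file keeps the table exactly as printed — the printed
maximum of 23.5 is only consistent with that reading — and a
`invert_remission_factors` flag (off by default) moves those points to
the "No" strata for users who read the labels as a typesetting
inversion. Derived tables always place points on the risk-direction
stratum, so verification matches strata by points rank, not by label.

## Patient scoring and risk groups

A patient's total is the sum of exactly one stratum per factor; with the
canonical table every reachable total lies on {0, 0.5, …, 23.5}. Risk
groups cut the score line at 6, 11.25 and 17.5 into [0, 6], (6, 11.25],
(11.25, 17.5], (17.5, ∞). Boundaries belong to the lower group, which
matches the semantics of an operating cutoff of 11.25 ("score > 11.25
predicts relapse"; 11.25 is the midpoint of the half-step lattice values
11 and 11.5). BMI exactly 28 kg/m² falls in the top stratum; values in
(27.99, 28) fall in the middle one, treating the printed 27.99 bound as
"< 28". BMI outside (10, 70) kg/m² is rejected as implausible.
Outcome fields may be absent for prediction-only scoring; the validation
stage requires them.

## Validation statistics

- **ROC/AUC**: trapezoidal integration over all distinct-score
  thresholds, which equals pairwise concordance with ties counted ½ (the
  tests assert exact agreement with a brute-force O(n²) oracle up to
  n = 200). The 95% CI uses DeLong's variance of placement values; the
  implementation was checked once against an independent reference
  (R's pROC `ci.auc(method="delong")`) and the agreed values are frozen
  in the tests.
- **Operating cutoff**: Youden's J = sensitivity + specificity − 1
  maximised over midpoints between consecutive distinct observed scores;
  ties break toward higher specificity, then the lower cutoff.
- **Decision-curve analysis**: net benefit TP/n − (FP/n)·t/(1−t) on a
  0.001-step grid over 0.254–0.597, the reported range of 6-month
  relapse rates, with treat-all and treat-none references. The unitless
  score is mapped to a relapse probability by a single-predictor
  logistic fit (near-MLE; a negligible ridge penalty keeps the fit
  stable under perfect separation), which is monotone by construction.
- **Risk-group survival**: Kaplan–Meier product-limit curves per group
  (cumulative risk = 1 − S(t); with no censoring this is exactly the
  empirical incidence), and hazard ratios from a Cox proportional-
  hazards model on group indicators with low risk as reference, Efron
  tie handling, two-sided Wald p-values, no multiplicity adjustment for
  the three contrasts. Empty groups are dropped with a warning; a
  reference group with zero events leaves the HRs undefined and flagged.

Follow-up is administratively truncated at 183 days, the 6-month
horizon of the endpoint.

## Synthetic cohort generator

The generator emulates the validation population's baseline structure:
BMI strata 41.1 / 40.9 / 18% (uniform within 18.5–24, 24–28, 28–35
kg/m²), smoking 42.8%, disease course > 2 years 89.9%, PsA 9.4%, prior
biologics 17.3%, PASI 75 within 8 weeks 73.3%, PASI 90 84.4%, and a
log-normal treatment course with median 10 months and σ = 0.30 on the
log scale (chosen so the quartiles land near the reported 8 and 12).
Predictors are independent by default — the real inter-factor
correlations are unreported, making independence the only defensible
default — with an optional one-factor Gaussian copula (`latent_rho`)
that induces exchangeable correlation without changing the marginals.

Relapse times are exponential with rate λᵢ = λ₀·exp(γ·(scoreᵢ − s̄)).
The constant hazard is a transparency choice; no relapse-time
distribution is reported for the real cohort. λ₀ is calibrated by
bisection (log-scale, 200 iterations) so the cohort-average 183-day
relapse probability equals the 0.447 target; targets of exactly 0 or 1
are rejected as unreachable. The default slope γ = 0.30 per point was
set so the concordance of score against outcome is ≈ 0.80 at n = 5000,
the discrimination regime of interest for this score; γ = 0 yields
AUC ≈ 0.5 as a no-signal control.

What passing tests on these cohorts do **not** show: the generator has
no predictor correlations, no time-varying hazards, no per-drug effect
differences, and no claim to match the real cohort's score
distribution. Synthetic recovery results are property-level checks of
the pipeline (calibration hits its target, discrimination is recovered,
risk-group rates and hazard ratios are ordered), not reproductions of
any cohort-specific estimate.

## Numerical choices and problem sizes

- 95% intervals use z = 1.959964 throughout; Q p-values come from the
  χ²(k−1) survival function.
- Point magnitudes round half away from zero (so 2.5 → 3), on the
  integer or half-point lattice per policy.
- Degenerate inputs: a degenerate CI gives SE 0 and is rejected at
  pooling; constant scores give AUC ½ with no informative cutoff;
  single-class outcomes are errors.
- All randomness flows from one `numpy.random.default_rng(seed)` per
  generated cohort; two runs with the same configuration are
  byte-identical, and the pipeline writes a manifest of config plus
  SHA-256 checksums of every output.
- The test suite and the acceptance script use n = 5000 synthetic
  cohorts for recovery checks (large enough that binomial noise on a
  proportion is ± 0.014 at 2σ) and n ≤ 200 for the exact O(n²)
  concordance oracle; the suite runs in a few seconds.

## Known limitations

- The OR→RR conversion assumes the published control-group risk applies
  when a study omits its own; the per-study conversion strategy of the
  original evidence synthesis is not public.
- Treating HR as RR ignores censoring before 6 months.
- The canonical table's remission-factor direction ambiguity (above) is
  documented, not resolved.
- Score→probability calibration for DCA is a modelling stand-in; any
  monotone mapping changes net-benefit values, though not the ROC.
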