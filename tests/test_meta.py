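import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psorelapse.meta import (
    MetaError,
    StudyEffect,
    convert_to_rr,
    deduplicate,
    log_se_from_ci,
    pool,
    pool_all,
    read_study_effects,
    sensitivity_switch,
)

# step-by-step hand computation of the DerSimonian-Laird formulas on a
# three-study fixture (log effects ln 1.2, ln 2.0, ln 1.6 with variances
# 0.04, 0.09, 0.0625), frozen before the implementation was written
DL_FIXTURE = dict(
    y=[math.log(1.2), math.log(2.0), math.log(1.6)],
    v=[0.04, 0.09, 0.0625],
    q=2.1960883267490785,
    q_pvalue=0.3335227622357704,
    i2=8.928981788239486,
    tau2=0.0059717808600855725,
    rr_fixed=1.4616536389422046,
    rr_random=1.4709813997520977,
    ci_fixed=(1.1141148558651353, 1.9176042299283418),
)


class TestConvertToRR:
    def test_rr_passes_through_unchanged(self, make_study):
        eff = make_study(math.log(1.5), 0.02)
        assert convert_to_rr(eff) is eff

    def test_hr_treated_as_rr_with_provenance(self, make_study):
        eff = make_study(math.log(1.5), 0.02, effect_type="HR")
        out = convert_to_rr(eff)
        assert out.effect_type == "RR"
        assert out.converted_from == "HR"
        assert out.estimate == eff.estimate

    @pytest.mark.parametrize("p0", [0.1, 0.447, 0.9])
    def test_null_odds_ratio_is_conversion_invariant(self, p0):
        eff = StudyEffect("s", "psa", "OR", 1.0, 0.8, 1.25, 50,
                          baseline_risk=p0)
        assert convert_to_rr(eff).estimate == pytest.approx(1.0)

    def test_or_two_at_half_baseline_risk_gives_four_thirds(self):
        eff = StudyEffect("s", "psa", "OR", 2.0, 1.5, 2.7, 50,
                          baseline_risk=0.5)
        out = convert_to_rr(eff)
        assert out.estimate == pytest.approx(2.0 / 1.5, abs=1e-4)
        assert out.converted_from == "OR"
        # both CI bounds transformed by the same formula
        assert out.ci_low == pytest.approx(1.5 / (0.5 + 0.75), abs=1e-12)

    def test_default_baseline_risk_applies_when_study_reports_none(self):
        eff = StudyEffect("s", "psa", "OR", 2.0, 1.5, 2.7, 50)
        out = convert_to_rr(eff, default_p0=0.447)
        assert out.estimate == pytest.approx(2.0 / (0.553 + 0.447 * 2.0))

    def test_invalid_baseline_risk_rejected(self):
        with pytest.raises(MetaError):
            StudyEffect("s", "psa", "OR", 2.0, 1.5, 2.7, 50, baseline_risk=1.2)


class TestLogSeFromCi:
    def test_degenerate_interval_gives_zero(self):
        assert log_se_from_ci(1.0, 1.0) == 0.0

    def test_published_duration_interval(self):
        # 95% CI 1.23-2.36 on the ratio scale
        # (ln 2.36 - ln 1.23) / (2 * 1.959964) = 0.651648 / 3.919928
        assert log_se_from_ci(1.23, 2.36) == pytest.approx(0.166240, abs=1e-5)

    def test_symmetric_e_interval_closed_form(self):
        assert log_se_from_ci(math.exp(-1), math.exp(1)) == pytest.approx(
            1 / 1.959964, abs=1e-12)

    @pytest.mark.parametrize("lo,hi", [(0.0, 1.0), (-1.0, 2.0)])
    def test_nonpositive_bounds_rejected(self, lo, hi):
        with pytest.raises(MetaError):
            log_se_from_ci(lo, hi)


class TestPool:
    def test_identical_studies_have_zero_heterogeneity(self, make_study):
        y, v = math.log(2.0), 0.02
        eff = [make_study(y, v, study_id=f"s{i}") for i in range(2)]
        out = pool(eff)
        assert out.rr == pytest.approx(2.0)
        assert out.q_stat == pytest.approx(0.0, abs=1e-12)
        assert out.i_squared == 0.0
        assert out.model == "fixed"

    def test_equal_variances_reduce_to_log_mean(self, make_study):
        ys = [0.1, 0.5, 0.9, 0.3]
        eff = [make_study(y, 0.25, study_id=f"s{i}") for i, y in enumerate(ys)]
        out = pool(eff)
        assert math.log(out.rr) == pytest.approx(np.mean(ys), abs=1e-10)

    def test_matches_hand_computed_dl_fixture(self, make_study):
        eff = [make_study(y, v, study_id=f"s{i}")
               for i, (y, v) in enumerate(zip(DL_FIXTURE["y"], DL_FIXTURE["v"]))]
        out = pool(eff)
        assert out.q_stat == pytest.approx(DL_FIXTURE["q"], abs=1e-6)
        assert out.q_pvalue == pytest.approx(DL_FIXTURE["q_pvalue"], abs=1e-6)
        assert out.i_squared == pytest.approx(DL_FIXTURE["i2"], abs=1e-6)
        assert out.tau_squared == pytest.approx(DL_FIXTURE["tau2"], abs=1e-6)
        assert out.model == "fixed"  # p = 0.33, I2 = 8.9%: gate stays fixed
        assert out.rr == pytest.approx(DL_FIXTURE["rr_fixed"], abs=1e-6)
        assert out.ci_low == pytest.approx(DL_FIXTURE["ci_fixed"][0], abs=1e-6)
        assert out.ci_high == pytest.approx(DL_FIXTURE["ci_fixed"][1], abs=1e-6)

    def test_random_effects_fixture_value_under_forced_model(self, make_study):
        eff = [make_study(y, v, study_id=f"s{i}")
               for i, (y, v) in enumerate(zip(DL_FIXTURE["y"], DL_FIXTURE["v"]))]
        out = sensitivity_switch(eff, "random")
        assert out.rr == pytest.approx(DL_FIXTURE["rr_random"], abs=1e-6)
        assert out.forced

    def test_null_effect_conservation(self, make_study):
        eff = [make_study(0.0, v, study_id=f"s{i}")
               for i, v in enumerate([0.01, 0.04, 0.09])]
        out = pool(eff)
        assert out.rr == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_statsmodels_on_random_sets(self, make_study, seed):
        """Independent cross-check against statsmodels' DL implementation."""
        from statsmodels.stats.meta_analysis import combine_effects
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        y = rng.normal(0.3, 0.4, size=k)
        v = rng.uniform(0.01, 0.2, size=k)
        eff = [make_study(yi, vi, study_id=f"s{i}")
               for i, (yi, vi) in enumerate(zip(y, v))]
        ours = pool(eff)
        ref = combine_effects(y, v, method_re="dl")
        assert ours.q_stat == pytest.approx(float(ref.q), abs=1e-8)
        # statsmodels reports the raw moment estimate; DL truncates at zero
        assert ours.tau_squared == pytest.approx(max(0.0, float(ref.tau2)),
                                                 abs=1e-8)
        if ours.tau_squared > 0 and ours.model == "random":
            expected = ref.mean_effect_re
        else:
            expected = ref.mean_effect_fe
        assert math.log(ours.rr) == pytest.approx(float(expected), abs=1e-8)

    @given(st.lists(st.tuples(st.floats(-1.0, 1.0), st.floats(0.01, 0.5)),
                    min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pooled_estimate_is_convex_combination(self, studies):
        effs = [StudyEffect(f"s{i}", "f", "RR", math.exp(y),
                            math.exp(y - 1.959964 * math.sqrt(v)),
                            math.exp(y + 1.959964 * math.sqrt(v)), 50)
                for i, (y, v) in enumerate(studies)]
        out = pool(effs, force_model="fixed")
        logs = [y for y, _ in studies]
        assert min(logs) - 1e-9 <= math.log(out.rr) <= max(logs) + 1e-9

    def test_random_ci_at_least_as_wide_as_fixed(self, make_study):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = rng.integers(2, 6)
            eff = [make_study(rng.normal(0, 0.8), rng.uniform(0.01, 0.3),
                              study_id=f"s{i}") for i in range(k)]
            fx = sensitivity_switch(eff, "fixed")
            rd = sensitivity_switch(eff, "random")
            w_f = math.log(fx.ci_high) - math.log(fx.ci_low)
            w_r = math.log(rd.ci_high) - math.log(rd.ci_low)
            assert w_r >= w_f - 1e-12

    def test_heterogeneity_gate_selects_random(self, make_study):
        # widely spread precise studies: Q blows up, gate must flip
        eff = [make_study(y, 0.005, study_id=f"s{i}")
               for i, y in enumerate([-0.5, 0.2, 0.9])]
        out = pool(eff)
        assert out.q_pvalue < 0.10 or out.i_squared > 50
        assert out.model == "random"

    def test_single_study_rejected(self, make_study):
        with pytest.raises(MetaError, match="at least two"):
            pool([make_study(0.2, 0.04)])

    def test_mixed_factors_rejected(self, make_study):
        with pytest.raises(MetaError, match="mixed"):
            pool([make_study(0.2, 0.04, factor="a"),
                  make_study(0.3, 0.04, factor="b", study_id="s2")])

    def test_unconverted_effects_rejected(self, make_study):
        with pytest.raises(MetaError, match="RR-type"):
            pool([make_study(0.2, 0.04, effect_type="OR"),
                  make_study(0.3, 0.04, study_id="s2")])


class TestDeduplicate:
    def test_most_adjusted_then_longest_followup_wins(self, make_study):
        crude = make_study(0.1, 0.04, adjustment_rank=0, followup_days=180)
        adj = make_study(0.2, 0.04, adjustment_rank=2, followup_days=90)
        adj_long = make_study(0.3, 0.04, adjustment_rank=2, followup_days=365)
        kept = deduplicate([crude, adj, adj_long])
        assert len(kept) == 1
        assert kept[0].estimate == adj_long.estimate

    def test_distinct_studies_all_kept(self, make_study):
        effs = [make_study(0.1, 0.04, study_id=f"s{i}") for i in range(3)]
        assert len(deduplicate(effs)) == 3


class TestIO:
    def test_csv_roundtrip_and_pooling(self, tmp_path, make_study):
        import pandas as pd
        rows = []
        for i, (y, v) in enumerate(zip(DL_FIXTURE["y"], DL_FIXTURE["v"])):
            e = make_study(y, v, study_id=f"s{i}")
            rows.append(dict(study_id=e.study_id, factor_id=e.factor_id,
                             effect_type=e.effect_type, estimate=e.estimate,
                             ci_low=e.ci_low, ci_high=e.ci_high, n=e.n))
        path = tmp_path / "effects.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        pooled = pool_all(read_study_effects(path))
        assert len(pooled) == 1
        assert pooled[0].rr == pytest.approx(DL_FIXTURE["rr_fixed"], abs=1e-9)

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study_id,estimate\ns1,1.2\n")
        with pytest.raises(MetaError, match="missing columns"):
            read_study_effects(path)
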