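import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from garsmeta import (ContingencyTable, MetaAnalysis, bonferroni, leave_one_out,
                      pool_fixed_iv, pool_mantel_haenszel, pool_random_dl,
                      z_test)
from conftest import make_est


class TestFixedIV:
    def test_single_study_identity(self):
        e = make_est(0.3, 0.12)
        r = pool_fixed_iv([e])
        assert r.pooled_log_or == pytest.approx(e.log_or)
        assert r.pooled_se == pytest.approx(e.se)
        assert r.k == 1

    def test_equal_se_midpoint_on_log_scale(self):
        r = pool_fixed_iv([make_est(0.0, 0.2), make_est(math.log(4), 0.2)])
        assert r.or_value == pytest.approx(2.0)

    def test_three_identical_studies_shrink_se_by_sqrt3(self):
        s = 0.25
        r = pool_fixed_iv([make_est(0.5, s)] * 3)
        assert r.pooled_se == pytest.approx(s / math.sqrt(3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_fixed_iv([])

    def test_matches_statsmodels(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        ests = [make_est(x, s) for x, s in
                [(0.1, 0.2), (0.4, 0.15), (-0.2, 0.3), (0.25, 0.1)]]
        r = pool_fixed_iv(ests)
        cf = sm_meta.combine_effects(np.array([e.log_or for e in ests]),
                                     np.array([e.se**2 for e in ests]))
        frame = cf.summary_frame()
        assert r.pooled_log_or == pytest.approx(frame.loc["fixed effect", "eff"])


class TestMantelHaenszel:
    def test_single_table_equals_crude_or(self):
        t = ContingencyTable(20, 80, 10, 90)
        assert pool_mantel_haenszel([t]).or_value == pytest.approx(2.25)

    def test_replication_invariance(self):
        t = ContingencyTable(15, 85, 10, 90)
        one = pool_mantel_haenszel([t])
        two = pool_mantel_haenszel([t, t])
        assert two.or_value == pytest.approx(one.or_value)

    def test_homogeneous_strata_exact(self):
        tables = [ContingencyTable(20, 80, 10, 90),
                  ContingencyTable(40, 160, 20, 180)]
        assert pool_mantel_haenszel(tables).or_value == pytest.approx(2.25)

    def test_handles_zero_cells_without_correction(self):
        tables = [ContingencyTable(5, 0, 5, 5), ContingencyTable(10, 5, 5, 10)]
        r = pool_mantel_haenszel(tables)
        assert r.or_value > 0

    def test_no_discordant_information_rejected(self):
        with pytest.raises(ValueError, match="discordant"):
            pool_mantel_haenszel([ContingencyTable(5, 0, 0, 5)])

    def test_agrees_with_iv_on_large_homogeneous_collections(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tables = []
            for _ in range(8):
                n1, n2 = rng.integers(200, 800, 2)
                p0 = rng.uniform(0.2, 0.5)
                p1 = 1.8 * p0 / (1 - p0 + 1.8 * p0)
                a = max(20, rng.binomial(n1, p1))
                c = max(20, rng.binomial(n2, p0))
                tables.append(ContingencyTable(int(a), int(n1 - a), int(c), int(n2 - c)))
            model = MetaAnalysis(tables=tables)
            mh = pool_mantel_haenszel(tables)
            iv = pool_fixed_iv(model.estimates)
            assert mh.pooled_log_or == pytest.approx(iv.pooled_log_or, rel=0.01)


class TestRandomDL:
    def test_identical_estimates_truncate_tau2_and_match_fixed(self):
        ests = [make_est(0.4, 0.2)] * 5
        dl = pool_random_dl(ests)
        iv = pool_fixed_iv(ests)
        assert dl.tau2 == 0.0
        assert dl.pooled_log_or == iv.pooled_log_or
        assert dl.pooled_se == iv.pooled_se

    def test_q_below_df_truncates_to_zero(self):
        ests = [make_est(0.40, 0.3), make_est(0.42, 0.3), make_est(0.41, 0.3)]
        assert pool_random_dl(ests).tau2 == 0.0

    def test_hand_evaluated_moment_estimator(self):
        # Q = 50, sum(w) = 200, sum(w^2)/sum(w) = 100 -> tau2 = 49/100
        dl = pool_random_dl([make_est(0.0, 0.1), make_est(1.0, 0.1)])
        assert dl.tau2 == pytest.approx(0.49)
        assert dl.pooled_log_or == pytest.approx(0.5)

    def test_k1_falls_back_to_fixed_with_note(self):
        r = pool_random_dl([make_est(0.2, 0.1)])
        assert r.model == "random_dl"
        assert "fallback" in r.note

    def test_matches_statsmodels_dl(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        ests = [make_est(x, s) for x, s in
                [(0.1, 0.2), (0.8, 0.15), (-0.3, 0.3), (0.45, 0.1), (0.2, 0.25)]]
        r = pool_random_dl(ests)
        cf = sm_meta.combine_effects(np.array([e.log_or for e in ests]),
                                     np.array([e.se**2 for e in ests]),
                                     method_re="dl")
        assert r.tau2 == pytest.approx(cf.tau2)
        frame = cf.summary_frame()
        assert r.pooled_log_or == pytest.approx(frame.loc["random effect", "eff"])

    @given(st.lists(st.tuples(st.floats(-1.5, 1.5), st.floats(0.05, 0.8)),
                    min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_random_ci_at_least_as_wide_as_fixed(self, raw):
        ests = [make_est(x, s) for x, s in raw]
        dl, iv = pool_random_dl(ests), pool_fixed_iv(ests)
        width_dl = math.log(dl.ci_high) - math.log(dl.ci_low)
        width_iv = math.log(iv.ci_high) - math.log(iv.ci_low)
        assert width_dl >= width_iv - 1e-12
        if dl.tau2 == 0.0:
            assert dl.pooled_log_or == iv.pooled_log_or
            assert dl.pooled_se == iv.pooled_se

    def test_order_invariance_and_weight_normalization(self):
        ests = [make_est(x, s) for x, s in [(0.1, 0.2), (0.6, 0.1), (-0.2, 0.4)]]
        a = pool_random_dl(ests)
        b = pool_random_dl(ests[::-1])
        assert a.pooled_log_or == pytest.approx(b.pooled_log_or)
        assert sum(a.per_study_weights) == pytest.approx(1.0)


class TestZTestAndBonferroni:
    def test_null_log_or(self):
        r = z_test(0.0, 0.5)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_quantile_identity(self):
        assert z_test(1.959964 * 0.3, 0.3).p_value == pytest.approx(0.05, abs=1e-6)

    def test_sign_flip_preserves_p(self):
        assert z_test(0.4, 0.1).p_value == z_test(-0.4, 0.1).p_value

    def test_bonferroni_product_cap_and_identity(self):
        assert bonferroni([0.004], 10) == [pytest.approx(0.04)]
        assert bonferroni([0.2], 10) == [1.0]
        assert bonferroni([0.03], 1) == [0.03]

    def test_bonferroni_m_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


class TestLeaveOneOut:
    def test_cardinality_and_labels(self):
        ests = [make_est(0.1 * i, 0.2, label=f"s{i}") for i in range(3)]
        res = leave_one_out(ests)
        assert len(res) == 3
        assert [r.omitted for r in res] == ["s0", "s1", "s2"]
        assert all(r.k == 2 for r in res)

    def test_exchangeable_estimates_give_identical_results(self):
        res = leave_one_out([make_est(0.3, 0.2)] * 4)
        assert len({round(r.pooled_log_or, 12) for r in res}) == 1

    def test_omitting_outlier_restores_null(self):
        ests = [make_est(0.0, 0.1)] * 3 + [make_est(math.log(9), 0.1)]
        res = leave_one_out(ests)
        full = pool_fixed_iv(ests)
        assert full.pooled_log_or == pytest.approx(math.log(9) / 4)
        assert res[-1].pooled_log_or == pytest.approx(0.0)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            leave_one_out([make_est(0.1, 0.1)])


class TestMetaAnalysisModel:
    def test_fit_auto_selects_random_under_heterogeneity(self):
        ests = [make_est(0.0, 0.1), make_est(1.2, 0.1), make_est(-0.5, 0.1)]
        res = MetaAnalysis(ests).fit()
        assert res.pooled.model == "random_dl"
        assert res.pooled.tau2 > 0

    def test_fit_auto_selects_mh_for_homogeneous_tables(self):
        tables = [ContingencyTable(30, 70, 20, 80)] * 4
        res = MetaAnalysis(tables=tables).fit()
        assert res.pooled.model == "fixed_mh"

    def test_summary_mentions_model_and_k(self):
        res = MetaAnalysis([make_est(0.2, 0.1), make_est(0.3, 0.1)]).fit("fixed_iv")
        text = res.summary()
        assert "fixed_iv" in text and "pooled OR" in text

    def test_from_dataframe(self):
        import pandas as pd
        df = pd.DataFrame({"study_id": ["a", "b"],
                           "case_risk": [20, 30], "case_other": [80, 70],
                           "control_risk": [10, 15], "control_other": [90, 85]})
        m = MetaAnalysis.from_dataframe(df)
        assert m.k == 2 and m.labels == ["a", "b"]
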