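import math
from itertools import combinations

import numpy as np
import pytest

from garsmeta import (MetaAnalysis, SimulationConfig, begg_test, cochran_q,
                      egger_test, generate_studies, pool_fixed_iv,
                      power_approximation, trim_and_fill)
from conftest import make_est


class TestCochranQ:
    def test_identical_estimates(self):
        r = cochran_q([make_est(0.3, 0.2)] * 4)
        assert r.q == pytest.approx(0.0)
        assert r.i2 == 0.0
        assert r.df == 3

    def test_two_study_closed_form(self):
        # equal weights w: Q = w (theta1 - theta2)^2 / 2
        se, t1, t2 = 0.2, 0.1, 0.9
        r = cochran_q([make_est(t1, se), make_est(t2, se)])
        assert r.q == pytest.approx((1 / se**2) * (t1 - t2) ** 2 / 2)

    def test_i2_formula_at_q5_df1(self):
        # engineer Q = 5 with two equal-weight studies: i2 = 1 - 1/5
        se = 0.1
        delta = math.sqrt(2 * 5 * se**2)
        r = cochran_q([make_est(0.0, se), make_est(delta, se)])
        assert r.q == pytest.approx(5.0)
        assert r.i2 == pytest.approx(0.8)

    def test_i2_clamped_at_zero_when_q_below_df(self):
        r = cochran_q([make_est(0.30, 0.3), make_est(0.31, 0.3), make_est(0.32, 0.3)])
        assert r.q < r.df
        assert r.i2 == 0.0

    def test_i2_increases_with_q_at_fixed_df(self):
        i2s = []
        for delta in (0.2, 0.5, 0.9):
            r = cochran_q([make_est(0.0, 0.1), make_est(delta, 0.1)])
            i2s.append(r.i2)
        assert i2s == sorted(i2s)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            cochran_q([make_est(0.1, 0.1)])


class TestPowerApproximation:
    def test_size_under_null(self):
        assert power_approximation(0.0, 0.2, alpha=0.05) == pytest.approx(0.05)

    def test_large_effect_limit(self):
        assert power_approximation(5.0, 0.1) == pytest.approx(1.0, abs=1e-9)

    def test_lambda_at_critical_value(self):
        from scipy.stats import norm
        se = 1.0
        delta = norm.ppf(0.975)
        expect = 0.5 + norm.cdf(-2 * norm.ppf(0.975))
        assert power_approximation(delta, se) == pytest.approx(expect, abs=1e-9)

    def test_monotone_in_effect_and_se(self):
        p1 = power_approximation(0.2, 0.1)
        p2 = power_approximation(0.4, 0.1)
        p3 = power_approximation(0.4, 0.2)
        assert p2 > p1
        assert p2 > p3


class TestEgger:
    def test_common_effect_gives_zero_intercept(self):
        # identical log-ORs with varying se lie on a line through the origin
        ests = [make_est(0.5, s) for s in (0.1, 0.2, 0.3, 0.4)]
        r = egger_test(ests)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)
        assert r.slope == pytest.approx(0.5)

    def test_constructed_intercept_recovered(self):
        # standardized effect = 1 + 0.5 * precision, inverted into log-ORs
        precisions = [1.0, 2.0, 4.0]
        ests = [make_est((1 + 0.5 * x) / x, 1 / x) for x in precisions]
        r = egger_test(ests)
        assert r.intercept == pytest.approx(1.0)
        assert r.slope == pytest.approx(0.5)
        assert r.df == 1

    def test_order_invariance(self):
        ests = [make_est(x, s) for x, s in [(0.2, 0.1), (0.7, 0.3), (0.4, 0.2),
                                            (0.1, 0.15)]]
        fwd, rev = egger_test(ests), egger_test(ests[::-1])
        assert fwd.intercept == pytest.approx(rev.intercept)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_requires_three_studies_and_se_variation(self):
        with pytest.raises(ValueError):
            egger_test([make_est(0.1, 0.1), make_est(0.2, 0.2)])
        with pytest.raises(ValueError):
            egger_test([make_est(0.1, 0.2)] * 4)

    def test_type_i_error_calibrated_under_null(self):
        # no true effect, no suppression: rejection near the nominal level
        rej = 0
        reps = 400
        for r in range(reps):
            cfg = SimulationConfig(true_or=1.0, tau2=0.0, k=20, seed=410_000 + r)
            m = MetaAnalysis.from_studies(generate_studies(cfg))
            if egger_test(m.estimates).p_value < 0.05:
                rej += 1
        assert rej / reps == pytest.approx(0.05, abs=0.03)


class TestBegg:
    def test_monotone_deviation_variance_relation_gives_tau_one(self):
        # log-ORs rise so steeply with se that standardized deviations
        # increase monotonically with variance
        ses = [0.1, 0.2, 0.3, 0.4, 0.5]
        ests = [make_est(2.0 * s**2 / max(ses) ** 2 * 3, s) for s in ses]
        r = begg_test(ests)
        assert r.tau == pytest.approx(1.0)

    def test_tau_matches_brute_force_pair_count(self):
        ests = [make_est(x, s) for x, s in
                [(0.3, 0.1), (0.1, 0.22), (0.55, 0.31), (-0.2, 0.17), (0.4, 0.45)]]
        r = begg_test(ests)
        # independent oracle: re-derive standardized deviations and count
        # concordant/discordant pairs for tau (no ties in this fixture)
        theta = np.array([e.log_or for e in ests])
        v = np.array([e.se**2 for e in ests])
        w = 1 / v
        pooled = (w * theta).sum() / w.sum()
        t_star = (theta - pooled) / np.sqrt(v - 1 / w.sum())
        conc = disc = 0
        for i, j in combinations(range(len(ests)), 2):
            s = (t_star[i] - t_star[j]) * (v[i] - v[j])
            conc += s > 0
            disc += s < 0
        n_pairs = len(ests) * (len(ests) - 1) / 2
        assert r.tau == pytest.approx((conc - disc) / n_pairs)

    def test_antisymmetric_under_effect_mirroring(self):
        # negating every log-OR mirrors the funnel, flipping the sign of
        # every standardized deviation and hence of the rank correlation
        ses = [0.1, 0.2, 0.3, 0.4]
        devs = [0.05, 0.2, 0.5, 0.9]
        fwd = begg_test([make_est(d, s) for d, s in zip(devs, ses)])
        rev = begg_test([make_est(-d, s) for d, s in zip(devs, ses)])
        assert fwd.tau == pytest.approx(-rev.tau)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_requires_three_studies(self):
        with pytest.raises(ValueError):
            begg_test([make_est(0.1, 0.1), make_est(0.2, 0.2)])


class TestTrimAndFill:
    def symmetric_funnel(self):
        devs = [-1.2, -0.9, -0.6, -0.45, -0.3, -0.15, 0,
                0.15, 0.3, 0.45, 0.6, 0.9, 1.2]
        return [make_est(0.5 + d, 0.2 + 0.1 * abs(d)) for d in devs]

    def test_symmetric_funnel_unchanged(self):
        ests = self.symmetric_funnel()
        tf = trim_and_fill(ests, side="auto")
        assert tf.k0 == 0
        assert tf.filled_estimates == ()
        assert tf.adjusted.pooled_log_or == pytest.approx(
            pool_fixed_iv(ests).pooled_log_or)

    def test_recovers_three_suppressed_studies(self):
        # funnel whose three most negative studies were removed: a tight
        # high-precision core plus an intact right tail of small studies
        devs = [-.03, -.02, -.01, 0, .01, .02, .5, .6, .7, .8]
        ses = [.05] * 6 + [.4] * 4
        obs = [make_est(0.5 + d, s) for d, s in zip(devs, ses)]
        tf = trim_and_fill(obs, side="auto")
        assert tf.k0 == 3
        assert tf.side == "left"
        assert tf.converged
        assert len(tf.filled_estimates) == 3
        # imputed studies mirror the trimmed ones below the adjusted center
        assert all(f.log_or < tf.adjusted.pooled_log_or
                   for f in tf.filled_estimates)

    def test_adjusted_moves_toward_truth_under_suppression(self):
        # one-sided suppression: non-significant studies of a true OR=1.3
        # effect mostly vanish; the adjusted OR should land between the
        # biased observed OR and the truth in the large majority of runs
        between = n = 0
        for r in range(120):
            cfg = SimulationConfig(true_or=1.3, tau2=0.0, k=40,
                                   case_n_range=(100, 500),
                                   control_n_range=(100, 500),
                                   suppression_p_threshold=0.05,
                                   suppression_prob=0.9, seed=420_000 + r)
            studies = generate_studies(cfg)
            if len(studies) < 3:
                continue
            n += 1
            m = MetaAnalysis.from_studies(studies)
            obs = pool_fixed_iv(m.estimates)
            tf = trim_and_fill(m.estimates, side="auto")
            lo, hi = sorted([obs.pooled_log_or, math.log(1.3)])
            between += lo - 1e-12 <= tf.adjusted.pooled_log_or <= hi + 1e-12
        assert between / n >= 0.8

    def test_requires_three_studies(self):
        with pytest.raises(ValueError):
            trim_and_fill([make_est(0.1, 0.1), make_est(0.2, 0.2)])


def test_funnel_plot_writes_image(tmp_path):
    ests = [make_est(0.1 * i, 0.1 + 0.05 * i) for i in range(6)]
    out = tmp_path / "funnel.png"
    from garsmeta import funnel_plot
    funnel_plot(ests, path=out)
    assert out.stat().st_size > 0
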