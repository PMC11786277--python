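"""Traveled-distance statistic, ANCOVA, and Pillai's-trace MANOVA."""

import numpy as np
import pytest

from vantage.metrics import (
    DegenerateInputError, ancova_oneway, manova_pillai, movement_summary,
    posthoc_contrasts, total_traveled_distance,
)

from conftest import make_session


class TestTraveledDistance:
    def test_three_four_five(self):
        s = make_session([0, 100], [[0, 0, 0], [3, 4, 0]])
        raw, score = total_traveled_distance(s)
        assert raw == pytest.approx(5.0)
        assert score == pytest.approx(np.log(5.0))

    def test_unit_step_additivity(self):
        k = 37
        cam = np.zeros((k + 1, 3))
        cam[:, 0] = np.arange(k + 1)
        s = make_session(np.arange(k + 1) * 100, cam)
        raw, _ = total_traveled_distance(s)
        assert raw == pytest.approx(float(k))

    def test_random_walk_matches_cumulative_norm_oracle(self, rng):
        steps = rng.normal(size=(500, 3))
        cam = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        s = make_session(np.arange(501) * 50, cam)
        raw, _ = total_traveled_distance(s)
        oracle = sum(float(np.sqrt(v @ v)) for v in steps)
        assert raw == pytest.approx(oracle, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        cam = np.cumsum(rng.normal(size=(100, 3)), axis=0)
        s1 = make_session(np.arange(100) * 50, cam)
        theta = 0.7
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        s2 = make_session(np.arange(100) * 50, cam @ R.T + [10, -3, 2])
        assert total_traveled_distance(s1)[0] == pytest.approx(
            total_traveled_distance(s2)[0], rel=1e-12)

    def test_zero_travel_degenerate(self):
        s = make_session([0, 100], [[1, 1, 1], [1, 1, 1]])
        with pytest.raises(DegenerateInputError):
            total_traveled_distance(s)

    def test_movement_summary_uses_both_phases(self, random_session):
        s = random_session(n=100, seed=11)
        m = movement_summary(s)
        assert np.isfinite(m.d_total) and np.isfinite(m.d_cov)
        assert m.d_total != m.d_cov


class TestAncova:
    def test_study_degrees_of_freedom(self, rng):
        # 261 eligible participants in three groups with one covariate
        n = 261
        g = np.repeat([0, 1, 2], [84, 97, 80])
        y = rng.normal(5.8, 0.5, n)
        x = rng.normal(5.5, 0.5, n)
        res = ancova_oneway(y, g, x)
        assert (res.group.df1, res.group.df2) == (2, 257)
        assert (res.covariate.df1, res.covariate.df2) == (1, 257)

    def test_pairwise_degrees_of_freedom(self, rng):
        g = np.repeat([1, 2], [97, 80])
        y = rng.normal(size=177)
        x = rng.normal(size=177)
        res = ancova_oneway(y, g, x)
        assert (res.group.df1, res.group.df2) == (1, 174)

    def test_matches_statsmodels_oracle(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        for _ in range(5):
            n = int(rng.integers(25, 50))
            df = pd.DataFrame({
                "y": rng.normal(size=n),
                "g": rng.integers(0, 3, n).astype(str),
                "x": rng.normal(size=n),
            })
            res = ancova_oneway(df["y"], df["g"], df["x"])
            fit = ols("y ~ C(g) + x", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=3)
            assert res.group.f_value == pytest.approx(table.loc["C(g)", "F"],
                                                      abs=1e-8)
            assert res.covariate.f_value == pytest.approx(table.loc["x", "F"],
                                                          abs=1e-8)

    def test_null_rejection_rate_calibrated(self):
        # no group effect: rejections at alpha=.05 should be ~5%
        rng = np.random.default_rng(2024)
        n, reps = 300, 2000
        g = np.repeat([0, 1, 2], 100)
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)   # covariate real, groups null
            if ancova_oneway(y, g, x).group.p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.01)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            ancova_oneway(rng.normal(size=30), np.repeat([0, 1, 2], 10),
                          np.ones(30))


class TestManovaPillai:
    def test_study_degrees_of_freedom(self, rng):
        Y = rng.normal(size=(317, 9))
        g = np.repeat([0, 1, 2], [108, 110, 99])
        res = manova_pillai(Y, g)
        assert (res.df1, res.df2) == (18, 614)

    def test_pairwise_degrees_of_freedom(self, rng):
        Y = rng.normal(size=(218, 9))
        g = np.repeat([0, 1], [108, 110])
        res = manova_pillai(Y, g)
        assert (res.df1, res.df2) == (9, 208)

    def test_univariate_case_equals_anova(self, rng):
        from scipy import stats
        y = rng.normal(size=90) + np.repeat([0, 0.5, 0.2], 30)
        g = np.repeat([0, 1, 2], 30)
        res = manova_pillai(y[:, None], g)
        f, p = stats.f_oneway(y[g == 0], y[g == 1], y[g == 2])
        assert res.f_value == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)
        # T = F df1 / (F df1 + df2) in the univariate case
        T = f * res.df1 / (f * res.df1 + res.df2)
        assert res.statistic == pytest.approx(T, rel=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        for _ in range(3):
            n, p = 60, 4
            Y = rng.normal(size=(n, p))
            g = rng.integers(0, 3, n)
            Y[g == 1] += 0.4
            res = manova_pillai(Y, g)
            mv = MANOVA(Y, np.column_stack([np.ones(n), g == 1, g == 2]))
            tab = mv.mv_test(hypotheses=[("g", np.array([[0, 1, 0],
                                                         [0, 0, 1]]), None)])
            stats_df = tab.results["g"]["stat"]
            assert res.statistic == pytest.approx(
                float(stats_df.loc["Pillai's trace", "Value"]), abs=1e-8)
            assert res.f_value == pytest.approx(
                float(stats_df.loc["Pillai's trace", "F Value"]), abs=1e-6)

    def test_affine_rescaling_invariance(self, rng):
        Y = rng.normal(size=(80, 5))
        g = rng.integers(0, 3, 80)
        Y[g == 2, 0] += 0.5
        base = manova_pillai(Y, g).statistic
        Y2 = Y * rng.uniform(0.5, 4.0, 5) + rng.normal(0, 10, 5)
        assert manova_pillai(Y2, g).statistic == pytest.approx(base, rel=1e-8)


class TestPosthoc:
    def test_bonferroni_loses_significance(self, rng):
        # a raw p just under .05 is corrected above it with m = 3 tests
        results = None
        for seed in range(200):
            r = np.random.default_rng(seed)
            Y = r.normal(size=(120, 3))
            g = np.repeat([0, 1, 2], 40)
            Y[g == 1] += 0.25
            out = posthoc_contrasts(Y, g, [(0, 1), (0, 2), (1, 2)])
            if 0.02 < out[0].p_value < 0.05 / 1.5:
                results = out
                break
        assert results is not None
        assert results[0].p_adjusted == pytest.approx(3 * results[0].p_value)
        assert results[0].p_adjusted > results[0].p_value

    def test_identical_groups_near_null(self, rng):
        Y = np.tile(rng.normal(size=(40, 4)), (2, 1))
        g = np.repeat([0, 1], 40)
        res = posthoc_contrasts(Y, g, [(0, 1)])[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_correction_monotone(self, rng):
        Y = rng.normal(size=(90, 2))
        g = np.repeat([0, 1, 2], 30)
        for res in posthoc_contrasts(Y, g, [(0, 1), (0, 2), (1, 2)]):
            assert res.p_adjusted >= res.p_value
            assert res.p_adjusted <= 1.0

    def test_missing_pair_rejected(self, rng):
        Y = rng.normal(size=(20, 2))
        g = np.repeat([0, 1], 10)
        with pytest.raises(ValueError):
            posthoc_contrasts(Y, g, [(0, 5)])


class TestEffectSizeCI:
    def test_eta_ci_brackets_point_estimate(self, rng):
        y = rng.normal(size=120) + np.repeat([0, 0.6, 0.1], 40)
        res = manova_pillai(y[:, None], np.repeat([0, 1, 2], 40))
        lo, hi = res.eta_ci
        assert 0.0 <= lo <= res.partial_eta_sq <= hi <= 1.0

    def test_null_data_ci_touches_zero(self, rng):
        y = rng.normal(size=150)
        res = manova_pillai(y[:, None], np.repeat([0, 1, 2], 50))
        assert res.eta_ci[0] == pytest.approx(0.0, abs=1e-9)
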