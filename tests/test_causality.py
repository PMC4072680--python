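import numpy as np
import pytest
from scipy import stats

import gcfmri as g
from gcfmri import InvalidInputError

from conftest import ar1, coupled_pair, series


def two_regression_gc(xv: np.ndarray, yv: np.ndarray, p: int) -> float:
    """Independent brute-force GC: two explicit OLS fits via normal equations."""
    xv = xv - xv.mean()
    yv = yv - yv.mean()
    n = len(yv)
    rows = n - p
    Ly = np.column_stack([yv[p - k: n - k] for k in range(1, p + 1)])
    Lx = np.column_stack([xv[p - k: n - k] for k in range(1, p + 1)])
    t = yv[p:]
    b = np.linalg.solve(Ly.T @ Ly, Ly.T @ t)
    ssr_r = np.sum((t - Ly @ b) ** 2)
    D = np.hstack([Ly, Lx])
    b = np.linalg.solve(D.T @ D, D.T @ t)
    ssr_f = np.sum((t - D @ b) ** 2)
    return np.log(ssr_r / ssr_f)


class TestGrangerCausality:
    def test_independent_null_is_small(self):
        rng = np.random.default_rng(11)
        x = series(ar1(5000, 0.5, rng), roi="x")
        y = series(ar1(5000, 0.5, rng), roi="y")
        res = g.granger_causality(x, y, 1)
        assert res.g_value < 0.005
        assert res.parametric_p > 0.05

    def test_identical_series_gives_zero(self, rng):
        # an exact copy carries no extra predictive information: the
        # collinear design resolves by minimum norm and g collapses to 0
        v = ar1(1000, 0.5, rng)
        res = g.granger_causality(series(v.copy(), roi="x"),
                                  series(v, roi="y"), 2)
        assert res.g_value == pytest.approx(0.0, abs=1e-8)
        # a 1e-12 jitter only adds floating-point-level "information"
        x = series(v + 1e-12 * rng.standard_normal(1000), roi="x")
        res = g.granger_causality(x, series(v, roi="y"), 2)
        assert res.g_value < 0.01

    def test_coupled_system_matches_long_run_oracle(self):
        # y(t) = 0.5 y(t-1) + 0.4 x(t-1) + e: the full model recovers unit
        # innovation variance; the restricted residual variance comes from
        # an independent long-run fit of the univariate AR(1) of y.
        rng = np.random.default_rng(21)
        xv, yv = coupled_pair(20_000, rng)
        res = g.granger_causality(series(xv, roi="x"), series(yv, roi="y"), 1)
        yc = yv - yv.mean()
        num = yc[:-1] @ yc[1:] / (yc[:-1] @ yc[:-1])
        resid = yc[1:] - num * yc[:-1]
        expected = np.log(resid.var() / 1.0)
        assert res.g_value == pytest.approx(expected, rel=0.10)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_matches_two_regression_oracle(self, p):
        rng = np.random.default_rng(p)
        for _ in range(5):
            xv, yv = coupled_pair(300, rng, c=0.3)
            res = g.granger_causality(series(xv, roi="x"), series(yv, roi="y"), p)
            assert res.g_value == pytest.approx(two_regression_gc(xv, yv, p),
                                                abs=1e-8)

    def test_positivity_on_null_pairs(self):
        for i in range(50):
            rng = np.random.default_rng(500 + i)
            x = series(rng.standard_normal(120), roi="x")
            y = series(rng.standard_normal(120), roi="y")
            assert g.granger_causality(x, y, 2).g_value >= 0.0

    def test_scale_invariance(self, rng):
        xv, yv = coupled_pair(600, rng)
        a = g.granger_causality(series(xv, roi="x"), series(yv, roi="y"), 2)
        b = g.granger_causality(series(3.7 * xv, roi="x"),
                                series(0.002 * yv, roi="y"), 2)
        assert a.g_value == pytest.approx(b.g_value, abs=1e-10)

    def test_mismatched_inputs_rejected(self, rng):
        x = series(rng.standard_normal(100), roi="x")
        with pytest.raises(InvalidInputError):
            g.granger_causality(x, series(rng.standard_normal(90), roi="y"), 1)
        with pytest.raises(InvalidInputError):
            g.granger_causality(x, series(rng.standard_normal(100), dt=0.2,
                                          roi="y"), 1)
        with pytest.raises(InvalidInputError):
            g.granger_causality(x, series(np.zeros(100), roi="y"), 1)

    def test_g_equals_log_ratio_of_stored_resvars(self, rng):
        xv, yv = coupled_pair(500, rng)
        res = g.granger_causality(series(xv, roi="x"), series(yv, roi="y"), 2)
        assert res.g_value == pytest.approx(
            np.log(res.restricted_resvar / res.full_resvar), abs=1e-10)


class TestParametricInference:
    def test_zero_g_statistic_is_one(self):
        # ((n-p)/p)(1 - (n-2p)/(n-p)) reduces to 1 for any n, p
        p_val = g.parametric_p_value(0.0, 1000, 1)
        assert p_val == pytest.approx(stats.f.sf(1.0, 1, 998), abs=1e-12)
        assert p_val == pytest.approx(0.3175, abs=5e-4)

    @pytest.mark.parametrize("gv,n,p", [(0.0, 1000, 1), (0.01, 1000, 2),
                                        (0.1, 500, 3), (0.05, 2400, 11)])
    def test_matches_f_cdf_oracle(self, gv, n, p):
        stat = ((n - p) / p) * (np.exp(gv) - (n - 2 * p) / (n - p))
        assert g.parametric_p_value(gv, n, p) == pytest.approx(
            1.0 - stats.f.cdf(stat, p, n - 2 * p), abs=1e-10)

    def test_monotone_decreasing_in_g(self):
        grid = np.linspace(0, 0.5, 30)
        ps = [g.parametric_p_value(gv, 1000, 2) for gv in grid]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_far_tail(self):
        # statistic ~ 50 at p=1, n=1000
        gv = np.log(50 / 999 + 998 / 999)
        assert g.parametric_p_value(gv + 0.05, 1000, 1) < 1e-10

    def test_requires_enough_samples(self):
        with pytest.raises(InvalidInputError):
            g.parametric_p_value(0.1, 20, 10)


class TestInfluenceDifference:
    def test_antisymmetric(self, rng):
        xv, yv = coupled_pair(800, rng)
        x, y = series(xv, roi="x"), series(yv, roi="y")
        a = g.influence_difference(x, y, 2)
        b = g.influence_difference(y, x, 2)
        assert a.delta_g == -b.delta_g

    def test_identical_series_near_zero(self, rng):
        v = ar1(800, 0.5, rng)
        x = series(v + 1e-10 * rng.standard_normal(800), roi="x")
        y = series(v, roi="y")
        res = g.influence_difference(x, y, 1)
        assert abs(res.delta_g) < 1e-6

    def test_unidirectional_pair_recovers_direction(self):
        hits = 0
        for i in range(100):
            rng = np.random.default_rng(3000 + i)
            xv, yv = coupled_pair(2400, rng, c=0.4)
            res = g.influence_difference(series(xv, dt=0.1, roi="x"),
                                         series(yv, dt=0.1, roi="y"), 1)
            hits += res.delta_g > 0 and res.dominant_direction == ("x", "y")
        assert hits >= 95


class TestConditionalGC:
    def test_empty_conditioning_equals_bivariate(self, rng):
        xv, yv = coupled_pair(600, rng)
        x, y = series(xv, roi="x"), series(yv, roi="y")
        biv = g.granger_causality(x, y, 2)
        cond = g.conditional_gc(x, y, [], 2)
        assert cond.g_value == pytest.approx(biv.g_value, abs=1e-12)
        assert cond.conditional_on == ()

    def test_chain_mediation_suppressed(self):
        # x -> z -> y: bivariate x->y sees the mediated flow, conditioning
        # on z removes it
        rng = np.random.default_rng(8)
        n = 20_000
        x = np.zeros(n); z = np.zeros(n); y = np.zeros(n)
        ex, ez, ey = (rng.standard_normal(n) for _ in range(3))
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + ex[t]
            z[t] = 0.8 * x[t - 1] + ez[t]
            y[t] = 0.8 * z[t - 1] + ey[t]
        xs, zs, ys = (series(v, roi=r) for v, r in ((x, "x"), (z, "z"), (y, "y")))
        biv = g.granger_causality(xs, ys, 2).g_value
        cond = g.conditional_gc(xs, ys, [zs], 2).g_value
        assert biv > 0.01
        assert cond < 0.005
        assert cond < biv

    def test_direct_edge_robust_to_irrelevant_conditioning(self):
        rng = np.random.default_rng(9)
        xv, yv = coupled_pair(20_000, rng)
        zs = series(ar1(20_000, 0.5, rng), roi="z")
        x, y = series(xv, roi="x"), series(yv, roi="y")
        biv = g.granger_causality(x, y, 1).g_value
        cond = g.conditional_gc(x, y, [zs], 1).g_value
        assert cond == pytest.approx(biv, rel=0.20)

    def test_conditional_on_labels(self, rng):
        xv, yv = coupled_pair(500, rng)
        zs = series(ar1(500, 0.3, rng), roi="PPC")
        res = g.conditional_gc(series(xv, roi="V"), series(yv, roi="M"), [zs], 1)
        assert res.conditional_on == ("PPC",)


class TestResultsExport:
    def test_tidy_csv(self, tmp_path, rng):
        xv, yv = coupled_pair(400, rng)
        res = g.granger_causality(series(xv, roi="V"), series(yv, roi="M"), 2)
        path = tmp_path / "res.csv"
        g.results_to_csv([res], path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back["source"]) == ["V"]
        assert back.loc[0, "g"] == pytest.approx(res.g_value)


class TestGrangerCausalityAnalyzer:
    def test_fit_matrix_shape_and_labels(self, rng):
        xv, yv = coupled_pair(1500, rng)
        zv = ar1(1500, 0.4, rng)
        X = np.column_stack([xv, yv, zv])
        est = g.GrangerCausalityAnalyzer(max_order=3)
        est.fit(X, labels=["V", "M", "S"])
        assert est.gc_matrix_.shape == (3, 3)
        assert np.isnan(est.gc_matrix_[0, 0])
        # column causes row: x (col 0) -> y (row 1) should dominate reverse
        assert est.gc_matrix_[1, 0] > est.gc_matrix_[0, 1]
        assert len(est.results_) == 6

    def test_conditional_flag(self, rng):
        X = rng.standard_normal((800, 3))
        est = g.GrangerCausalityAnalyzer(order=1, conditional=True).fit(X)
        assert set(est.results_["conditional_on"]) == {"2", "1", "0"}

    def test_params_round_trip(self):
        est = g.GrangerCausalityAnalyzer(order=2, conditional=True)
        assert g.GrangerCausalityAnalyzer(**est.get_params()).get_params() == \
            est.get_params()
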