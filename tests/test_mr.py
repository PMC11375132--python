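import numpy as np
import pytest
from scipy import stats

from cmrkit.mr import (MRError, MRInput, cml, cochran_q, ivw_random, raps,
                       steiger_filter, wald_ratio, weighted_median,
                       weighted_mode)


def mk(beta_x, beta_y, se_x=None, se_y=None, **kw):
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    if se_x is None:
        se_x = np.full_like(beta_x, 0.01)
    if se_y is None:
        se_y = np.full_like(beta_y, 1.0)
    return MRInput(beta_x, se_x, beta_y, se_y, **kw)


class TestIVW:
    def test_homogeneous_ratios(self):
        res = ivw_random(mk([1, 1], [0.5, 0.5]))
        assert res.theta == pytest.approx(0.5)
        assert res.diagnostics["Q"] == pytest.approx(0.0)
        assert res.diagnostics["inflation"] == 1.0

    def test_weighted_ls_closed_form(self):
        # bx=(1,2), by=(1,1), sy=1: theta = (1*1 + 2*1)/(1 + 4) = 3/5
        res = ivw_random(mk([1, 2], [1, 1]))
        assert res.theta == pytest.approx(3 / 5, abs=1e-12)

    def test_outcome_scale_equivariance(self):
        a = ivw_random(mk([1, 2, 3], [0.5, 1.2, 1.4]))
        b = ivw_random(mk([1, 2, 3], [0.5, 1.2, 1.4],
                          se_y=np.full(3, 2.0)))
        assert b.theta == pytest.approx(a.theta)
        assert b.diagnostics["se_fixed"] == pytest.approx(2 * a.diagnostics["se_fixed"])

    def test_needs_two_ivs(self):
        with pytest.raises(MRError):
            ivw_random(mk([1], [1]))
        assert wald_ratio(mk([2], [1])).theta == pytest.approx(0.5)


class TestCochranQ:
    def test_zero_for_homogeneous(self):
        Q, df, p = cochran_q(mk([1, 1, 1], [0.3, 0.3, 0.3]))
        assert Q == pytest.approx(0.0) and df == 2

    def test_two_term_algebra(self):
        bx = np.array([1.0, 2.0])
        by = np.array([0.6, 0.4])
        sy = np.array([1.0, 0.5])
        w = bx**2 / sy**2
        th = by / bx
        expected = w[0] * w[1] * (th[0] - th[1]) ** 2 / (w[0] + w[1])
        Q, df, _ = cochran_q(mk(bx, by, se_y=sy))
        assert Q == pytest.approx(expected, rel=1e-12)

    def test_null_distribution_chi2(self):
        # strong IVs, no pleiotropy: Q ~ chi2(m-1)
        rng = np.random.default_rng(5)
        m, reps, theta = 8, 2000, 0.3
        qs = []
        for _ in range(reps):
            gamma = rng.uniform(0.1, 0.2, m)
            bx = gamma + rng.normal(0, 1e-4, m)   # negligible exposure noise
            by = theta * gamma + rng.normal(0, 0.01, m)
            qs.append(cochran_q(mk(bx, by, se_x=np.full(m, 1e-4),
                                   se_y=np.full(m, 0.01)))[0])
        d = stats.kstest(qs, stats.chi2(m - 1).cdf)
        assert d.statistic < 0.05


class TestWeightedMedian:
    def test_equal_ratios(self):
        res = weighted_median(mk([1, 1, 1], [0.7, 0.7, 0.7]), seed=1)
        assert res.theta == pytest.approx(0.7)

    def test_interpolation_formula(self):
        # ratios (0, 0.5, 10), equal weights -> midpoint interpolation = 0.5
        res = weighted_median(mk([1, 1, 1], [0.0, 0.5, 10.0]), seed=1)
        assert res.theta == pytest.approx(0.5)

    def test_breakdown_majority_weight(self):
        inp = mk([10, 1, 1], [5.0, 3.0, 9.0])  # first IV has weight 100/102
        res = weighted_median(inp, seed=1)
        assert res.theta == pytest.approx(0.5, abs=0.05)

    def test_order_invariance_and_seed_reproducibility(self):
        bx, by = [1, 2, 3, 4], [0.5, 1.1, 1.4, 2.2]
        a = weighted_median(mk(bx, by), seed=7)
        b = weighted_median(mk(bx[::-1], by[::-1]), seed=7)
        assert a.theta == pytest.approx(b.theta)
        assert a.se == pytest.approx(b.se)

    def test_zero_beta_x_dropped(self):
        res = weighted_median(mk([0, 1, 1, 1], [1, 0.5, 0.5, 0.5]), seed=1)
        assert res.n_iv == 3 and res.theta == pytest.approx(0.5)


class TestWeightedMode:
    def test_equal_ratios(self):
        res = weighted_mode(mk([1, 1, 1], [0.7, 0.7, 0.7]), seed=1)
        assert res.theta == pytest.approx(0.7)

    def test_cluster_beats_outliers(self):
        bx = np.ones(10)
        by = np.array([0.48, 0.5, 0.49, 0.51, 0.52, 0.5, 0.47, 5.0, 5.1, 4.9])
        res = weighted_mode(mk(bx, by, se_y=np.full(10, 0.05)), seed=3)
        assert 0.4 < res.theta < 0.6

    def test_kde_argmax_matches_grid_oracle(self):
        from cmrkit.mr import _kde_argmax, _mode_bandwidth, _weighted_median
        rng = np.random.default_rng(11)
        ratios = np.concatenate([rng.normal(0.5, 0.02, 7), [5.0, 5.1, 4.9]])
        w = np.ones(10) / 10
        h = _mode_bandwidth(ratios, w, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200001)
        dens = np.zeros_like(grid)
        for r_j, w_j in zip(ratios, w):  # brute-force KDE
            dens += w_j * np.exp(-0.5 * ((grid - r_j) / h) ** 2)
        oracle = grid[np.argmax(dens)]
        assert _kde_argmax(ratios, w, h) == pytest.approx(oracle, abs=2e-3)

    def test_zero_weight_outliers_equivalent_to_removal(self):
        bx = np.ones(6)
        by = np.array([0.5, 0.52, 0.48, 0.5, 8.0, 9.0])
        # infinite ratio se -> exactly zero weight
        sy = np.array([0.05] * 4 + [np.inf, np.inf])
        full = weighted_mode(mk(bx, by, se_y=sy), seed=5, n_boot=50)
        clean = weighted_mode(mk(bx[:4], by[:4], se_y=sy[:4]), seed=5, n_boot=50)
        assert full.theta == pytest.approx(clean.theta, abs=1e-12)


class TestRAPS:
    def test_noiseless_proportional_limit(self):
        bx = np.array([0.1, 0.15, 0.2, 0.12, 0.18])
        res = raps(MRInput(bx, np.full(5, 1e-6), 0.4 * bx, np.full(5, 1e-6)))
        assert res.theta == pytest.approx(0.4, abs=1e-4)
        assert res.diagnostics["tau2"] == pytest.approx(0.0, abs=1e-8)

    def test_tau2_recovery(self):
        rng = np.random.default_rng(17)
        m, reps, theta, tau = 100, 200, 0.2, 0.02
        tau2_hats = []
        for _ in range(reps):
            gamma = rng.uniform(0.05, 0.2, m)
            sx = np.full(m, 0.005)
            sy = np.full(m, 0.01)
            bx = gamma + rng.normal(0, sx)
            by = theta * gamma + rng.normal(0, tau, m) + rng.normal(0, sy)
            tau2_hats.append(raps(MRInput(bx, sx, by, sy)).diagnostics["tau2"])
        mc_se = np.std(tau2_hats) / np.sqrt(reps)
        assert abs(np.mean(tau2_hats) - tau**2) < 3 * mc_se

    def test_huber_loss_runs(self):
        rng = np.random.default_rng(3)
        gamma = rng.uniform(0.1, 0.2, 30)
        bx = gamma + rng.normal(0, 0.01, 30)
        by = 0.3 * gamma + rng.normal(0, 0.02, 30)
        res = raps(MRInput(bx, np.full(30, 0.01), by, np.full(30, 0.02)),
                   loss="huber")
        assert res.theta == pytest.approx(0.3, abs=0.05)


class TestCML:
    def test_noiseless_proportional_exact(self):
        bx = np.array([0.1, 0.15, 0.2, 0.12])
        inp = MRInput(bx, np.full(4, 0.01), 0.25 * bx, np.full(4, 0.01))
        res = cml(inp, n=10000, K_range=[0], seed=1)
        assert res.theta == pytest.approx(0.25, abs=1e-10)

    def test_single_outlier_identified(self):
        rng = np.random.default_rng(23)
        hits = 0
        for rep in range(20):
            gamma = rng.uniform(0.1, 0.2, 10)
            bx = gamma + rng.normal(0, 0.005, 10)
            by = 0.2 * gamma + rng.normal(0, 0.01, 10)
            by[4] += 0.3  # gross outlier
            inp = MRInput(bx, np.full(10, 0.005), by, np.full(10, 0.01))
            res = cml(inp, n=50000, seed=rep)
            hits += (res.diagnostics["invalid_ids_bic"] == ["iv4"])
        assert hits >= 19

    def test_bic_selects_true_invalid_count(self):
        rng = np.random.default_rng(29)
        hits = 0
        reps = 50
        for rep in range(reps):
            m = 20
            gamma = rng.uniform(0.1, 0.2, m)
            bx = gamma + rng.normal(0, 0.005, m)
            by = 0.1 * gamma + rng.normal(0, 0.01, m)
            by[:5] += rng.uniform(0.1, 0.2, 5) * rng.choice([-1, 1], 5)
            inp = MRInput(bx, np.full(m, 0.005), by, np.full(m, 0.01))
            res = cml(inp, n=50000, n_starts=3, seed=rep)
            hits += (res.diagnostics["K_best"] == 5)
        assert hits / reps > 0.9


class TestSteiger:
    def test_rules(self):
        inp = mk([0.1, 0.02, 0.05], [0.02, 0.1, 0.05],
                 se_x=np.full(3, 0.01), se_y=np.full(3, 0.01))
        inp.n_x = np.full(3, 1e4)
        inp.n_y = np.full(3, 1e4)
        filtered, report = steiger_filter(inp)
        # iv0: z_x=10 > z_y=2 -> kept; iv1: reversed -> removed; iv2: tie -> kept
        assert filtered.ids == ["iv0", "iv2"]
        assert report["removed"].tolist() == [False, True, False]


@pytest.mark.parametrize("method,kwargs", [
    (ivw_random, {}),
    (raps, {}),
    (weighted_median, {"seed": 3}),
    (weighted_mode, {"seed": 3}),
    (lambda i, **k: cml(i, n=10000, **k), {"seed": 3}),
])
def test_sign_equivariance(method, kwargs):
    rng = np.random.default_rng(31)
    gamma = rng.uniform(0.1, 0.2, 12)
    bx = gamma + rng.normal(0, 0.01, 12)
    by = 0.3 * gamma + rng.normal(0, 0.01, 12)
    inp = MRInput(bx, np.full(12, 0.01), by, np.full(12, 0.01))
    neg = MRInput(bx, np.full(12, 0.01), -by, np.full(12, 0.01))
    assert method(neg, **kwargs).theta == pytest.approx(-method(inp, **kwargs).theta,
                                                        abs=1e-6)


@pytest.mark.parametrize("method,kwargs", [
    (ivw_random, {}),
    (weighted_median, {"seed": 3}),
    (weighted_mode, {"seed": 3}),
    (lambda i, **k: cml(i, n=10000, **k), {"seed": 3}),
])
def test_exposure_scale_equivariance(method, kwargs):
    rng = np.random.default_rng(37)
    gamma = rng.uniform(0.1, 0.2, 12)
    bx = gamma + rng.normal(0, 0.01, 12)
    by = 0.3 * gamma + rng.normal(0, 0.01, 12)
    c = 4.0
    inp = MRInput(bx, np.full(12, 0.01), by, np.full(12, 0.01))
    scaled = MRInput(c * bx, np.full(12, c * 0.01), by, np.full(12, 0.01))
    assert method(scaled, **kwargs).theta == pytest.approx(
        method(inp, **kwargs).theta / c, rel=1e-4)


def test_estimators_consistent_without_pleiotropy():
    """All five estimators recover theta with strong valid instruments."""
    rng = np.random.default_rng(41)
    theta, m, reps = 0.25, 50, 60
    est = {k: [] for k in ("ivw", "raps", "median", "mode", "cml")}
    for rep in range(reps):
        gamma = rng.uniform(0.1, 0.2, m)
        sx = np.full(m, 0.005)
        sy = np.full(m, 0.01)
        inp = MRInput(gamma + rng.normal(0, sx), sx,
                      theta * gamma + rng.normal(0, sy), sy)
        est["ivw"].append(ivw_random(inp).theta)
        est["raps"].append(raps(inp).theta)
        est["median"].append(weighted_median(inp, n_boot=20, seed=rep).theta)
        est["mode"].append(weighted_mode(inp, n_boot=20, seed=rep).theta)
        est["cml"].append(cml(inp, n=50000, K_range=range(0, 6),
                              n_starts=3, seed=rep).theta)
    for k, v in est.items():
        mc_se = np.std(v) / np.sqrt(reps)
        assert abs(np.mean(v) - theta) < 3 * mc_se + 1e-4, k
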