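"""Robust two-sample MR estimators on per-instrument effect pairs.

Each instrument j contributes an exposure association (beta_xj, se_xj) and
an outcome association (beta_yj, se_yj); under the linear structural model
beta_yj = theta * beta_xj + alpha_j, the estimators below recover the causal
effect theta under different assumptions on the pleiotropic effects alpha_j:

* :func:`ivw_random` — multiplicative random-effects inverse-variance
  weighting (balanced pleiotropy / InSIDE).
* :func:`raps` — robust adjusted profile score with overdispersion
  (accounts for measurement error in beta_x; balanced pleiotropy).
* :func:`weighted_median` — majority-valid assumption.
* :func:`weighted_mode` — plurality-valid assumption (mode of ratios).
* :func:`cml` — constrained maximum likelihood with BIC model averaging
  over the number of invalid instruments (plurality-valid).

plus Cochran's Q heterogeneity and Steiger directionality filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)


class MRError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MRInput:
    """Per-instrument harmonized effect pairs."""

    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    ids: list[str] | None = None
    n_x: np.ndarray | None = None
    n_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, float) for a in
                (self.beta_x, self.se_x, self.beta_y, self.se_y)]
        self.beta_x, self.se_x, self.beta_y, self.se_y = arrs
        m = len(self.beta_x)
        if not all(len(a) == m for a in arrs) or m < 1:
            raise MRError("effect vectors must share a common length >= 1")
        if (self.se_x <= 0).any() or (self.se_y <= 0).any():
            raise MRError("all standard errors must be positive")
        if self.ids is None:
            self.ids = [f"iv{j}" for j in range(m)]

    def __len__(self) -> int:
        return len(self.beta_x)

    def subset(self, mask: np.ndarray) -> "MRInput":
        """Select instruments by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MRInput(self.beta_x[idx], self.se_x[idx],
                       self.beta_y[idx], self.se_y[idx],
                       [self.ids[j] for j in idx],
                       None if self.n_x is None else np.asarray(self.n_x)[idx],
                       None if self.n_y is None else np.asarray(self.n_y)[idx])

    def drop_zero_beta_x(self) -> "MRInput":
        bad = self.beta_x == 0
        if bad.any():
            logger.warning("dropped %d instrument(s) with beta_x = 0", int(bad.sum()))
            return self.subset(~bad)
        return self

    def canonical_order(self) -> "MRInput":
        """Deterministic IV ordering, so seeded resampling is independent of
        the caller's input order."""
        order = np.lexsort((self.se_y, self.beta_y, self.se_x, self.beta_x))
        return MRInput(self.beta_x[order], self.se_x[order],
                       self.beta_y[order], self.se_y[order],
                       [self.ids[j] for j in order],
                       None if self.n_x is None else np.asarray(self.n_x)[order],
                       None if self.n_y is None else np.asarray(self.n_y)[order])


@dataclass
class MRResult:
    method: str
    theta: float
    se: float
    pval: float
    n_iv: int
    diagnostics: dict = field(default_factory=dict)


def _normal_p(theta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(theta) / se)) if se > 0 else 0.0


# ---------------------------------------------------------------------------
# IVW and heterogeneity


def wald_ratio(input: MRInput, j: int = 0) -> MRResult:
    """Single-instrument ratio estimate (diagnostic; first-order se)."""
    th = input.beta_y[j] / input.beta_x[j]
    se = input.se_y[j] / abs(input.beta_x[j])
    return MRResult("wald_ratio", float(th), float(se), _normal_p(th, se), 1)


def ivw_random(input: MRInput) -> MRResult:
    """Multiplicative random-effects IVW.

    theta = sum(bx*by/sy^2)/sum(bx^2/sy^2); the fixed-effect se is inflated
    by sqrt(max(1, Q/(m-1))) — under-dispersion is not allowed.
    """
    if len(input) < 2:
        raise MRError("IVW needs at least 2 instruments")
    w = input.beta_x**2 / input.se_y**2
    theta = float(np.sum(input.beta_x * input.beta_y / input.se_y**2) / np.sum(w))
    ratios = input.beta_y / np.where(input.beta_x == 0, np.nan, input.beta_x)
    q_terms = w * (ratios - theta) ** 2
    Q = float(np.nansum(q_terms))
    m = len(input)
    inflation = max(1.0, Q / (m - 1))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    se = se_fixed * np.sqrt(inflation)
    return MRResult("ivw", theta, se, _normal_p(theta, se), m,
                    {"Q": Q, "df": m - 1, "inflation": inflation,
                     "se_fixed": se_fixed})


def cochran_q(input: MRInput) -> tuple[float, int, float]:
    """Cochran's Q over ratio estimates with first-order weights bx^2/sy^2."""
    if len(input) < 2:
        raise MRError("Q needs at least 2 instruments")
    res = ivw_random(input)
    Q, df = res.diagnostics["Q"], res.diagnostics["df"]
    return Q, df, float(stats.chi2.sf(Q, df))


# ---------------------------------------------------------------------------
# RAPS


def _huber_psi(t: np.ndarray, k: float = 1.345) -> np.ndarray:
    return np.clip(t, -k, k)


def _huber_delta(k: float = 1.345) -> float:
    # E[psi(Z) Z] for Z ~ N(0,1): integrates to 2k phi(k) + (1-2Phi(-k)) ... computed exactly
    from scipy.integrate import quad
    val, _ = quad(lambda z: np.clip(z, -k, k) * z * stats.norm.pdf(z), -np.inf, np.inf)
    return val


def raps(input: MRInput, loss: str = "l2", overdispersion: bool = True,
         max_iter: int = 200) -> MRResult:
    """Robust adjusted profile score estimator.

    Model: beta_x_hat ~ N(gamma, se_x^2), beta_y_hat ~ N(theta*gamma + alpha,
    se_y^2), alpha ~ N(0, tau2).  Solves the adjusted profile score
    equations in (theta, tau2) with standardized residuals
    t_j = (by - theta*bx)/sqrt(sy^2 + theta^2 sx^2 + tau2); sandwich se;
    tau2 floored at zero.
    """
    if len(input) < 3:
        raise MRError("RAPS needs at least 3 instruments")
    bx, sx, by, sy = input.beta_x, input.se_x, input.beta_y, input.se_y
    if loss == "l2":
        psi, delta = (lambda t: t), 1.0
    elif loss == "huber":
        psi, delta = _huber_psi, _huber_delta()
    else:
        raise ValueError(f"unknown loss {loss!r}")

    def scores(theta: float, tau2: float) -> np.ndarray:
        V = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(V)
        u = (bx * sy**2 + theta * by * sx**2 + theta * tau2 * bx) / V**1.5
        s1 = psi(t) * u
        s2 = (psi(t) * t - delta) / V
        return np.column_stack([s1, s2])

    def solve_theta(tau2: float, theta0: float) -> float:
        f = lambda th: scores(th, tau2)[:, 0].sum()
        # bracket around theta0, expanding geometrically
        step = 0.5 * max(abs(theta0), 0.5)
        lo, hi = theta0 - step, theta0 + step
        for _ in range(60):
            if f(lo) * f(hi) <= 0:
                break
            step *= 2.0
            lo, hi = theta0 - step, theta0 + step
        else:
            raise ConvergenceError("RAPS: could not bracket the theta score root")
        return float(optimize.brentq(f, lo, hi, xtol=1e-12))

    def solve_tau2(theta: float) -> float:
        # the tau2 score is decreasing in tau2; boundary at 0
        g = lambda t2: scores(theta, t2)[:, 1].sum()
        if g(0.0) <= 0:
            return 0.0
        hi = np.max(sy**2 + theta**2 * sx**2)
        for _ in range(100):
            if g(hi) < 0:
                break
            hi *= 4.0
        else:
            raise ConvergenceError("RAPS: could not bracket the tau2 root")
        return float(optimize.brentq(g, 0.0, hi, xtol=1e-14))

    theta_hat = ivw_random(input).theta if len(input) >= 2 else 0.0
    tau2_hat = 0.0
    for it in range(max_iter):
        theta_new = solve_theta(tau2_hat, theta_hat)
        tau2_new = solve_tau2(theta_new) if overdispersion else 0.0
        done = (abs(theta_new - theta_hat) < 1e-10 * max(1, abs(theta_hat))
                and abs(tau2_new - tau2_hat) < 1e-12 + 1e-8 * tau2_hat)
        theta_hat, tau2_hat = theta_new, tau2_new
        if done:
            break
    else:
        raise ConvergenceError(
            f"RAPS did not converge in {max_iter} iterations "
            f"(theta={theta_hat:.4g}, tau2={tau2_hat:.4g})")

    # sandwich variance in theta: A^-1 B A^-T / 1 with per-IV scores
    S = scores(theta_hat, tau2_hat)
    eps = 1e-5 * max(1.0, abs(theta_hat))

    def theta_score(th):
        return scores(th, tau2_hat)[:, 0].sum()

    A = (theta_score(theta_hat + eps) - theta_score(theta_hat - eps)) / (2 * eps)
    B = float(np.sum(S[:, 0] ** 2))
    if A == 0:
        raise ConvergenceError("RAPS: flat score at the solution")
    se = float(np.sqrt(B) / abs(A))
    return MRResult("raps", theta_hat, se, _normal_p(theta_hat, se), len(input),
                    {"tau2": tau2_hat, "loss": loss,
                     "overdispersion": overdispersion})


# ---------------------------------------------------------------------------
# weighted median


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2.0     # midpoints of cumulative weights
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def weighted_median(input: MRInput, n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    """Weighted-median estimator; valid when >50% of weight is on valid IVs.

    Weights are first-order inverse ratio variances bx^2/sy^2; the se comes
    from a seeded parametric bootstrap (resampling beta_x, beta_y from
    normals at their reported standard errors).
    """
    if seed is None:
        raise MRError("weighted_median requires an explicit seed")
    input = input.drop_zero_beta_x().canonical_order()
    if len(input) < 3:
        raise MRError("weighted median needs at least 3 instruments")
    ratios = input.beta_y / input.beta_x
    w = input.beta_x**2 / input.se_y**2
    theta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(input.beta_x, input.se_x)
        by = rng.normal(input.beta_y, input.se_y)
        ok = bx != 0
        boots[b] = _weighted_median(by[ok] / bx[ok], bx[ok]**2 / input.se_y[ok]**2)
    se = float(boots.std(ddof=1))
    return MRResult("weighted_median", theta, se, _normal_p(theta, se),
                    len(input), {"n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# weighted mode


def _mode_bandwidth(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Modified Silverman rule on the weighted MAD of the ratios."""
    med = _weighted_median(ratios, weights)
    mad = 1.4826 * _weighted_median(np.abs(ratios - med), weights)
    if mad == 0:
        mu = np.average(ratios, weights=weights)
        sd = np.sqrt(np.average((ratios - mu) ** 2, weights=weights))
        mad = sd
    return phi * 0.9 * mad * len(ratios) ** (-1 / 5)


def _kde_argmax(ratios: np.ndarray, weights: np.ndarray, h: float,
                n_grid: int = 4096) -> float:
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def weighted_mode(input: MRInput, phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MRResult:
    """Weighted-mode estimator; valid when the largest group of IVs sharing
    a ratio is valid (plurality).  Delta-method ratio ses give the weights;
    the estimate is the argmax of a weighted Gaussian KDE of the ratios.
    """
    if seed is None:
        raise MRError("weighted_mode requires an explicit seed")
    input = input.drop_zero_beta_x().canonical_order()
    s_all = np.sqrt(input.se_y**2 / input.beta_x**2
                    + input.beta_y**2 * input.se_x**2 / input.beta_x**4)
    if np.isinf(s_all).any():          # zero-weight IVs contribute nothing
        input = input.subset(np.isfinite(s_all))
    if len(input) < 3:
        raise MRError("weighted mode needs at least 3 instruments")
    bx, sx, by, sy = input.beta_x, input.se_x, input.beta_y, input.se_y
    ratios = by / bx
    s = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    w = 1.0 / s**2
    w = w / w.sum()

    def estimate(r, wt):
        if np.ptp(r) == 0:
            return float(r[0])
        h = _mode_bandwidth(r, wt, phi)
        if h <= 0 or not np.isfinite(h):
            return float(_weighted_median(r, wt))
        return _kde_argmax(r, wt, h)

    theta = estimate(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        rb = byb[ok] / bxb[ok]
        sb = np.sqrt(sy[ok]**2 / bxb[ok]**2 + byb[ok]**2 * sx[ok]**2 / bxb[ok]**4)
        wb = 1.0 / sb**2
        boots[b] = estimate(rb, wb / wb.sum())
    se = float(boots.std(ddof=1))
    return MRResult("weighted_mode", theta, se, _normal_p(theta, se),
                    len(input), {"phi": phi, "n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# constrained maximum likelihood (cML) with BIC model averaging


def _cml_fixed_K(bx, sx, by, sy, K: int, theta_init: float,
                 max_iter: int = 200, tol: float = 1e-10):
    """Coordinate-descent cML for a fixed number K of invalid instruments.

    Closed-form updates: valid gamma_j pools both traits; invalid IVs take
    gamma_j = bx_j with a free alpha_j; the invalid set is the K largest
    squared standardized outcome residuals.  Returns (theta, negloglik,
    invalid_index_set, converged).
    """
    m = len(bx)
    theta = theta_init
    invalid = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        gamma_valid = (bx / sx**2 + theta * by / sy**2) / (1 / sx**2 + theta**2 / sy**2)
        resid2 = (by - theta * gamma_valid) ** 2 / sy**2
        new_invalid = np.zeros(m, dtype=bool)
        if K > 0:
            new_invalid[np.argsort(-resid2, kind="mergesort")[:K]] = True
        gamma = np.where(new_invalid, bx, gamma_valid)
        alpha = np.where(new_invalid, by - theta * gamma, 0.0)
        denom = np.sum(gamma**2 / sy**2)
        if denom == 0:
            return theta, np.inf, new_invalid, False
        theta_new = float(np.sum(gamma * (by - alpha) / sy**2) / denom)
        done = abs(theta_new - theta) < tol and (new_invalid == invalid).all()
        theta, invalid = theta_new, new_invalid
        if done:
            gamma_valid = (bx / sx**2 + theta * by / sy**2) / (1 / sx**2 + theta**2 / sy**2)
            gamma = np.where(invalid, bx, gamma_valid)
            alpha = np.where(invalid, by - theta * gamma, 0.0)
            nll = float(np.sum((bx - gamma) ** 2 / (2 * sx**2)
                               + (by - theta * gamma - alpha) ** 2 / (2 * sy**2)))
            return theta, nll, invalid, True
    return theta, np.inf, invalid, False


def _cml_profile_nll(theta, bx, sx, by, sy, valid_mask):
    r = (by - theta * bx)[valid_mask]
    V = (sy**2 + theta**2 * sx**2)[valid_mask]
    return float(np.sum(r**2 / (2 * V)))


def cml(input: MRInput, n: float, K_range=None, n_starts: int = 10,
        seed: int | None = None) -> MRResult:
    """cML with BIC model averaging over the number of invalid instruments.

    For each K in ``K_range`` (default 0..m-2) the constrained likelihood is
    minimized from ``n_starts`` random initializations of theta plus the IVW
    start; BIC(K) = 2*minL + K*log(n); the model average uses weights
    proportional to exp(-dBIC/2), with variance combining within-model
    Fisher variance and between-model dispersion.
    """
    if seed is None:
        raise MRError("cml requires an explicit seed")
    if len(input) < 3:
        raise MRError("cML needs at least 3 instruments")
    bx, sx, by, sy = input.beta_x, input.se_x, input.beta_y, input.se_y
    m = len(input)
    if K_range is None:
        K_range = range(0, m - 1)
    K_range = [int(K) for K in K_range]
    if any(K < 0 or K > m - 2 for K in K_range):
        raise MRError("K_range must lie within {0, ..., m-2}")

    rng = np.random.default_rng(seed)
    theta_ivw = ivw_random(input).theta if m >= 2 else 0.0
    spread = 3.0 * max(abs(theta_ivw), np.median(np.abs(by / np.where(bx == 0, np.nan, bx))[np.isfinite(by / np.where(bx == 0, np.nan, bx))]) if m else 1.0, 0.1)
    starts = [theta_ivw] + list(rng.uniform(-spread, spread, n_starts))

    results = {}
    for K in K_range:
        best = None
        for th0 in starts:
            th, nll, inv, ok = _cml_fixed_K(bx, sx, by, sy, K, th0)
            if ok and (best is None or nll < best[1]):
                best = (th, nll, inv)
        if best is None:
            logger.warning("cML: no convergent start for K=%d; excluded", K)
            continue
        th, nll, inv = best
        # observed information of the profile likelihood (valid IVs only)
        eps = 1e-4 * max(1.0, abs(th))
        d2 = (_cml_profile_nll(th + eps, bx, sx, by, sy, ~inv)
              - 2 * _cml_profile_nll(th, bx, sx, by, sy, ~inv)
              + _cml_profile_nll(th - eps, bx, sx, by, sy, ~inv)) / eps**2
        se_K = float(np.sqrt(1.0 / d2)) if d2 > 0 else np.inf
        results[K] = (th, nll, inv, se_K, 2 * nll + K * np.log(n))
    if not results:
        raise ConvergenceError("cML failed to converge for every K")

    bics = np.array([results[K][4] for K in results])
    thetas = np.array([results[K][0] for K in results])
    ses = np.array([results[K][3] for K in results])
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    theta_ma = float(np.sum(w * thetas))
    var_ma = float(np.sum(w * (ses**2 + (thetas - theta_ma) ** 2)))
    se_ma = float(np.sqrt(var_ma))
    K_best = list(results)[int(np.argmin(bics))]
    invalid_ids = [input.ids[j] for j in np.flatnonzero(results[K_best][2])]
    return MRResult("cml", theta_ma, se_ma, _normal_p(theta_ma, se_ma), m,
                    {"K_best": K_best, "K_weights": {int(K): float(wk) for K, wk in zip(results, w)},
                     "theta_bic": float(results[K_best][0]),
                     "invalid_ids_bic": invalid_ids, "seed": seed})


# ---------------------------------------------------------------------------
# Steiger filtering


def steiger_filter(input: MRInput, n_x=None, n_y=None) -> tuple[MRInput, "pd.DataFrame"]:
    """Directionality filter: drop IVs explaining more outcome than exposure
    variance.

    Explained-variance proxies r2 = z^2/(z^2 + n); an IV is removed iff
    r2_y > r2_x (ties retained).  Returns the filtered input and a report.
    """
    import pandas as pd

    nx = np.asarray(n_x if n_x is not None else input.n_x, float)
    ny = np.asarray(n_y if n_y is not None else input.n_y, float)
    if nx is None or ny is None or np.any(~np.isfinite(nx)) or np.any(~np.isfinite(ny)):
        raise MRError("Steiger filtering requires sample sizes for both traits")
    nx = np.broadcast_to(nx, (len(input),))
    ny = np.broadcast_to(ny, (len(input),))
    zx = input.beta_x / input.se_x
    zy = input.beta_y / input.se_y
    r2x = zx**2 / (zx**2 + nx)
    r2y = zy**2 / (zy**2 + ny)
    removed = r2y > r2x
    report = pd.DataFrame({"iv_id": input.ids, "r2_x": r2x, "r2_y": r2y,
                           "removed": removed})
    return input.subset(~removed), report
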