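"""Conditional-and-joint (COJO-style) analysis from summary statistics.

Recovers multi-SNP joint regression coefficients from marginal GWAS
statistics plus a reference LD matrix, performs forward-backward stepwise
selection of jointly associated SNPs on conditional p-values, and computes
conditional effect estimates of instruments given a conditioning set — the
first stage of the conditional-MR framework.

All internal algebra is on the standardized scale (genotypes and trait with
unit variance), where the marginal effect of SNP j is b_j = z_j / sqrt(n_j)
and the joint coefficients solve R b_joint = b_marginal with R the LD
correlation matrix.  Results are mapped back to each SNP's input scale via
the per-SNP factor c_j = se_j * sqrt(n_j), which preserves z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldref import ReferencePanel, ld_corr
from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)

P_COJO_DEFAULT = 5e-6          # stage-1 joint-significance threshold
COLLINEARITY_R = 0.9           # |r| at/above which conditioning is refused
RESIDUAL_VAR_FLOOR = 1e-6
MAX_CONDITION_NUMBER = 1e8


class CollinearityError(ValueError):
    pass


@dataclass
class JointFit:
    """Joint multi-SNP fit on the standardized scale."""

    snp_ids: list[str]
    beta: np.ndarray           # joint coefficients, standardized scale
    se: np.ndarray
    pval: np.ndarray
    resid_var: float
    n_eff: float

    def coef(self, snp_id: str) -> tuple[float, float, float]:
        j = self.snp_ids.index(snp_id)
        return float(self.beta[j]), float(self.se[j]), float(self.pval[j])


def _marginal_std(stats_ds: SummaryDataset, snp_ids: list[str]):
    """Standardized marginal betas and per-SNP scale factors.

    The marginal coefficient on the standardized scale is the genotype-trait
    correlation, recovered exactly from the t-statistic of a simple
    regression with intercept: r = z / sqrt(z^2 + n - 2).
    """
    t = stats_ds.table.set_index("snp_id").loc[snp_ids]
    beta = t["beta"].to_numpy(float)
    se = t["se"].to_numpy(float)
    n = t["n"].to_numpy(float)
    z = beta / se
    b_std = z / np.sqrt(z**2 + n - 2)
    # maps standardized estimates back to the input scale (≈ sd(y)/sd(g))
    scale = np.where(b_std != 0, beta / b_std, se * np.sqrt(n))
    return b_std, scale, n


def joint_fit(snps: list[str], stats_ds: SummaryDataset,
              panel: ReferencePanel, R: np.ndarray | None = None) -> JointFit:
    """Joint coefficients of ``snps`` from marginal statistics and panel LD.

    b_joint = R^-1 b_marg on the standardized scale; residual variance
    sigma^2 = max(1 - b'R^-1 b, floor); se = sqrt(sigma^2 diag(R^-1)/n_eff)
    with n_eff the median per-SNP sample size; two-sided normal p-values.
    """
    if len(snps) == 0:
        raise ValueError("need at least one SNP")
    if R is None:
        R = ld_corr(panel, snps)
    cond = np.linalg.cond(R)
    if cond >= MAX_CONDITION_NUMBER:
        off = np.abs(R - np.eye(len(snps)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise CollinearityError(
            f"LD matrix near-singular (cond={cond:.2e}); worst pair "
            f"{snps[i]}/{snps[j]} |r|={off[i, j]:.3f}")
    b_marg, _, n = _marginal_std(stats_ds, snps)
    Rinv = np.linalg.inv(R)
    b_joint = Rinv @ b_marg
    n_eff = float(np.median(n))
    resid_var = max(1.0 - float(b_marg @ b_joint), RESIDUAL_VAR_FLOOR)
    se = np.sqrt(resid_var * np.diag(Rinv) / n_eff)
    pval = 2.0 * stats.norm.sf(np.abs(b_joint) / se)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return JointFit(list(snps), b_joint, se, pval, resid_var, n_eff)


def stepwise_select(stats_ds: SummaryDataset, panel: ReferencePanel,
                    block: list[str], p_cojo: float = P_COJO_DEFAULT,
                    collinearity_r: float = COLLINEARITY_R,
                    max_model_size: int | None = None) -> list[str]:
    """Forward-backward stepwise selection of jointly associated SNPs.

    Seeds with the block's smallest-p SNP if p <= ``p_cojo``; repeatedly adds
    the candidate with the smallest conditional p (its coefficient p in the
    joint fit of selected + candidate) subject to p <= ``p_cojo`` and
    max |r| with the selected set < ``collinearity_r``; after each addition
    drops any selected SNP whose joint p exceeds ``p_cojo``.  Deterministic:
    ties broken by genomic position then snp_id.
    """
    if not block:
        raise ValueError("block must be nonempty")
    t = stats_ds.table.set_index("snp_id")
    block = [s for s in block if s in t.index]
    if not block:
        return []
    # canonical candidate order for determinism
    pv = panel.variants.set_index("snp_id")
    order = sorted(block, key=lambda s: (int(pv.at[s, "pos"]), s))
    pvals = t.loc[order, "pval"].astype(float)
    R_all = ld_corr(panel, order)
    idx = {s: k for k, s in enumerate(order)}
    n_med = float(np.median(t.loc[order, "n"].astype(float)))
    if max_model_size is None:
        max_model_size = max(1, min(len(order), int(n_med // 10)))

    seed = min(order, key=lambda s: (pvals[s], int(pv.at[s, "pos"]), s))
    if pvals[seed] > p_cojo:
        return []
    selected = [seed]

    while len(selected) < max_model_size:
        best: tuple[float, str] | None = None
        sel_idx = [idx[s] for s in selected]
        for cand in order:
            if cand in selected:
                continue
            r_with_sel = np.abs(R_all[idx[cand], sel_idx])
            if r_with_sel.max() >= collinearity_r:
                continue
            trial = selected + [cand]
            tix = [idx[s] for s in trial]
            try:
                fit = joint_fit(trial, stats_ds, panel, R=R_all[np.ix_(tix, tix)])
            except CollinearityError:
                continue
            p_cond = fit.coef(cand)[2]
            if p_cond <= p_cojo and (best is None or p_cond < best[0]):
                best = (p_cond, cand)
        if best is None:
            break
        selected.append(best[1])
        # backward elimination
        while len(selected) > 1:
            tix = [idx[s] for s in selected]
            fit = joint_fit(selected, stats_ds, panel, R=R_all[np.ix_(tix, tix)])
            worst = int(np.argmax(fit.pval))
            if fit.pval[worst] > p_cojo:
                dropped = selected.pop(worst)
                logger.debug("stepwise: dropped %s (joint p=%.2e)", dropped, fit.pval[worst])
            else:
                break
    return sorted(selected, key=lambda s: (int(pv.at[s, "pos"]), s))


@dataclass
class ConditionalResult:
    """Per-instrument conditional effect estimates for exposure and outcome.

    ``table`` columns: iv_id, beta_x_star, se_x_star, beta_y_star, se_y_star,
    adjusted, excluded_collinear.  Estimates are on the input (marginal)
    scale; excluded instruments carry NaN estimates.
    """

    table: pd.DataFrame
    conditioning_set: list[str] = field(default_factory=list)
    block_id: str = ""

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[~self.table["excluded_collinear"]]


def conditional_estimates(ivs: list[str], Ol: list[str],
                          exposure: SummaryDataset, outcome: SummaryDataset,
                          panel: ReferencePanel,
                          collinearity_r: float = COLLINEARITY_R,
                          block_id: str = "") -> ConditionalResult:
    """Conditional effects of instruments given the selected set ``Ol``.

    With an empty ``Ol`` the marginal estimates are copied through exactly.
    Otherwise instruments with |r| >= ``collinearity_r`` to any SNP of
    ``Ol`` (other than themselves) are flagged ``excluded_collinear``; the
    remaining instruments take their coefficients from the joint fit over
    (retained instruments + Ol), run on the exposure and on the outcome
    separately, mapped back to the input scale.
    """
    if not ivs:
        raise ValueError("ivs must be nonempty")
    ex = exposure.table.set_index("snp_id")
    ou = outcome.table.set_index("snp_id")

    def marginal_row(iv):
        return (float(ex.at[iv, "beta"]), float(ex.at[iv, "se"]),
                float(ou.at[iv, "beta"]), float(ou.at[iv, "se"]))

    if len(Ol) == 0:
        rows = [(iv, *marginal_row(iv), False, False) for iv in ivs]
        return ConditionalResult(_result_frame(rows), [], block_id)

    # collinearity screen of IVs vs Ol
    others = [s for s in Ol if s not in ivs]
    excluded: set[str] = set()
    if others:
        R_io = ld_corr(panel, list(ivs) + others)
        k = len(ivs)
        for i, iv in enumerate(ivs):
            if np.abs(R_io[i, k:]).max() >= collinearity_r:
                excluded.add(iv)
    retained = [iv for iv in ivs if iv not in excluded]
    if not retained:
        logger.warning("block %s: all instruments collinear with the "
                       "conditioning set", block_id or "<unnamed>")
        rows = [(iv, np.nan, np.nan, np.nan, np.nan, False, True) for iv in ivs]
        return ConditionalResult(_result_frame(rows), list(Ol), block_id)

    model = list(dict.fromkeys(retained + list(Ol)))  # union, order-stable
    R = ld_corr(panel, model)
    fit_x = joint_fit(model, exposure, panel, R=R)
    fit_y = joint_fit(model, outcome, panel, R=R)
    _, scale_x, _ = _marginal_std(exposure, model)
    _, scale_y, _ = _marginal_std(outcome, model)

    rows = []
    for iv in ivs:
        if iv in excluded:
            rows.append((iv, np.nan, np.nan, np.nan, np.nan, False, True))
            continue
        j = model.index(iv)
        rows.append((iv,
                     fit_x.beta[j] * scale_x[j], fit_x.se[j] * scale_x[j],
                     fit_y.beta[j] * scale_y[j], fit_y.se[j] * scale_y[j],
                     True, False))
    return ConditionalResult(_result_frame(rows), list(Ol), block_id)


def _result_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=[
        "iv_id", "beta_x_star", "se_x_star", "beta_y_star", "se_y_star",
        "adjusted", "excluded_collinear"])
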