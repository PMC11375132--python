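"""End-to-end orchestration of the two-stage conditional-MR analysis.

``run_standard_mr`` is the classic two-sample analysis: clump instruments on
the exposure, feed the marginal effect pairs to the robust estimators.
``run_cmr`` inserts stage 1 in between: per LD block, a stepwise
conditional-and-joint selection on the *outcome* statistics finds nearby
outcome-associated SNPs, and every instrument's effect on exposure and
outcome is re-estimated conditional on them, removing pleiotropy that is
purely due to LD with those neighbors.  Stage 2 then runs the same
estimators on the conditional effect pairs, so the two frameworks are
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mr as mrmod
from .cojo import CollinearityError, conditional_estimates, stepwise_select
from .config import RunConfig
from .ldref import LDBlockPartition, ReferencePanel, assign_blocks, block_snps, clump
from .sumstats import HarmonizedPair

logger = logging.getLogger(__name__)


class InsufficientInstrumentsError(ValueError):
    pass


def build_mr_input(table: pd.DataFrame, x=("beta_x", "se_x"),
                   y=("beta_y", "se_y")) -> mrmod.MRInput:
    return mrmod.MRInput(
        table[x[0]].to_numpy(float), table[x[1]].to_numpy(float),
        table[y[0]].to_numpy(float), table[y[1]].to_numpy(float),
        ids=table["snp_id"].tolist() if "snp_id" in table else table["iv_id"].tolist(),
        n_x=table["n_x"].to_numpy(float) if "n_x" in table else None,
        n_y=table["n_y"].to_numpy(float) if "n_y" in table else None)


def run_methods(mr_input: mrmod.MRInput, config: RunConfig,
                prefix: str = "MR") -> list[mrmod.MRResult]:
    """Dispatch the configured estimator battery on one MRInput."""
    n_eff = (float(np.median(mr_input.n_y)) if mr_input.n_y is not None
             else float(np.median(mr_input.n_x)) if mr_input.n_x is not None
             else 1e5)
    out = []
    for method in config.methods:
        if method == "ivw":
            res = mrmod.ivw_random(mr_input)
        elif method == "raps":
            res = mrmod.raps(mr_input)
        elif method == "weighted_median":
            res = mrmod.weighted_median(mr_input, n_boot=config.n_boot,
                                        seed=config.seed)
        elif method == "weighted_mode":
            res = mrmod.weighted_mode(mr_input, n_boot=config.n_boot,
                                      seed=config.seed)
        elif method == "cml":
            res = mrmod.cml(mr_input, n=n_eff, seed=config.seed)
        else:
            raise ValueError(f"unknown MR method {method!r}")
        res.method = f"{prefix}-{res.method}"
        out.append(res)
    return out


def results_frame(results: list[mrmod.MRResult]) -> pd.DataFrame:
    import json
    return pd.DataFrame([{
        "method": r.method, "theta": r.theta, "se": r.se, "pval": r.pval,
        "n_iv": r.n_iv, "diagnostics": json.dumps(r.diagnostics, default=str),
    } for r in results])


def run_standard_mr(pair: HarmonizedPair, panel: ReferencePanel,
                    config: RunConfig, iv_ids: list[str] | None = None):
    """Standard two-sample MR on marginal estimates.

    Returns (results, diagnostics).  ``iv_ids`` overrides clumping when the
    instrument list is already fixed (used for side-by-side comparison).
    """
    from .sumstats import pair_exposure_dataset

    if iv_ids is None:
        exposure = pair_exposure_dataset(pair)
        iv_ids = clump(exposure, panel, config.clump_p, config.clump_r2,
                       config.clump_window_kb)
    if len(iv_ids) < config.min_ivs:
        raise InsufficientInstrumentsError(
            f"insufficient instruments: {len(iv_ids)} < {config.min_ivs}")
    t = pair.table.set_index("snp_id").loc[iv_ids].reset_index()
    mr_input = build_mr_input(t)
    steiger_report = None
    if config.steiger:
        mr_input, steiger_report = mrmod.steiger_filter(mr_input)
        if len(mr_input) < config.min_ivs:
            raise InsufficientInstrumentsError(
                f"insufficient instruments after Steiger filtering: {len(mr_input)}")
    results = run_methods(mr_input, config, prefix="MR")
    Q, df, qp = mrmod.cochran_q(mr_input)
    f_stats = (mr_input.beta_x / mr_input.se_x) ** 2
    diagnostics = {"n_iv": len(mr_input), "Q": Q, "Q_df": df, "Q_pval": qp,
                   "F_per_iv": dict(zip(mr_input.ids, f_stats.tolist())),
                   "iv_ids": list(mr_input.ids),
                   "steiger_report": steiger_report}
    return results, diagnostics


@dataclass
class CMRRun:
    """Full record of a conditional-MR analysis next to its standard-MR twin."""

    config: dict
    iv_ids: list[str]
    blocks: dict[str, list[str]]
    conditioning_sets: dict[str, list[str]]
    conditional: pd.DataFrame           # pooled per-IV conditional estimates
    cmr_results: list = field(default_factory=list)
    mr_results: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def results_table(self) -> pd.DataFrame:
        return pd.concat([results_frame(self.mr_results),
                          results_frame(self.cmr_results)], ignore_index=True)


def run_cmr(pair: HarmonizedPair, panel: ReferencePanel,
            partition: LDBlockPartition, config: RunConfig) -> CMRRun:
    """Two-stage conditional MR (stage 1 per LD block, stage 2 pooled).

    Stage 1 runs the stepwise selection on the OUTCOME statistics of each
    block holding at least one instrument; instruments keep their marginal
    estimates when nothing is selected, are re-estimated conditionally when
    neighbors are selected, and are excluded when collinear (|r| >=
    ``collinearity_r``) with a selected neighbor.  A block whose LD matrix
    is numerically singular degrades to marginal estimates with a logged
    flag.  Stage 2 applies the configured estimators to the pooled
    conditional pairs; the standard-MR analysis is run on the identical
    instrument list for side-by-side reporting.
    """
    from .sumstats import pair_exposure_dataset, pair_outcome_dataset

    exposure = pair_exposure_dataset(pair)
    outcome = pair_outcome_dataset(pair)
    iv_ids = clump(exposure, panel, config.clump_p, config.clump_r2,
                   config.clump_window_kb)
    if len(iv_ids) < config.min_ivs:
        raise InsufficientInstrumentsError(
            f"insufficient instruments: {len(iv_ids)} < {config.min_ivs}")

    blocks = assign_blocks(iv_ids, partition, panel)
    cond_frames = []
    conditioning_sets: dict[str, list[str]] = {}
    n_fallback = 0
    for label, block_ivs in blocks.items():
        candidates = block_snps(partition, panel, label)
        try:
            if config.p_cojo <= 0:
                Ol: list[str] = []
            else:
                Ol = stepwise_select(outcome, panel, candidates,
                                     p_cojo=config.p_cojo,
                                     collinearity_r=config.collinearity_r)
            res = conditional_estimates(block_ivs, Ol, exposure, outcome,
                                        panel, config.collinearity_r,
                                        block_id=label)
        except CollinearityError as err:
            logger.warning("block %s: singular LD (%s); falling back to "
                           "marginal estimates", label, err)
            n_fallback += 1
            Ol = []
            res = conditional_estimates(block_ivs, [], exposure, outcome,
                                        panel, config.collinearity_r,
                                        block_id=label)
        conditioning_sets[label] = Ol
        frame = res.table.copy()
        frame["block"] = label
        cond_frames.append(frame)
    conditional = pd.concat(cond_frames, ignore_index=True)

    retained = conditional[~conditional["excluded_collinear"]]
    if len(retained) < config.min_ivs:
        raise InsufficientInstrumentsError(
            f"insufficient instruments after conditioning: {len(retained)}")
    marg = pair.table.set_index("snp_id")
    cmr_input = mrmod.MRInput(
        retained["beta_x_star"].to_numpy(float), retained["se_x_star"].to_numpy(float),
        retained["beta_y_star"].to_numpy(float), retained["se_y_star"].to_numpy(float),
        ids=retained["iv_id"].tolist(),
        n_x=marg.loc[retained["iv_id"], "n_x"].to_numpy(float),
        n_y=marg.loc[retained["iv_id"], "n_y"].to_numpy(float))

    cmr_results = run_methods(cmr_input, config, prefix="CMR")
    Qc, dfc, qpc = mrmod.cochran_q(cmr_input)

    mr_results, mr_diag = run_standard_mr(pair, panel, config, iv_ids=iv_ids)

    f_after = (cmr_input.beta_x / cmr_input.se_x) ** 2
    marg_iv = marg.loc[iv_ids]
    deltas = conditional.merge(
        marg_iv[["beta_x", "se_x", "beta_y", "se_y"]].reset_index()
        .rename(columns={"snp_id": "iv_id"}), on="iv_id")
    deltas["delta_beta_y"] = deltas["beta_y_star"] - deltas["beta_y"]

    n_adj = int(conditional["adjusted"].sum())
    n_exc = int(conditional["excluded_collinear"].sum())
    diagnostics = {
        "n_iv": len(iv_ids), "n_adjusted": n_adj, "n_excluded_collinear": n_exc,
        "n_unadjusted": len(iv_ids) - n_adj - n_exc,
        "n_block_fallback": n_fallback,
        "Q_mr": mr_diag["Q"], "Q_cmr": Qc, "Q_cmr_df": dfc, "Q_cmr_pval": qpc,
        "F_before": mr_diag["F_per_iv"],
        "F_after": dict(zip(cmr_input.ids, f_after.tolist())),
        "per_iv_deltas": deltas,
    }
    return CMRRun(config.to_dict(), iv_ids, blocks, conditioning_sets,
                  conditional, cmr_results, mr_results, diagnostics)
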