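"""GWAS summary-statistics containers, I/O and allele harmonization.

A :class:`SummaryDataset` holds per-SNP marginal association records for one
trait (effect sizes, standard errors, p-values, sample sizes, alleles and
allele frequencies).  The native text dialect is the GCTA ``.ma`` format
(columns ``SNP A1 A2 freq b se p N``); a generic TSV with a column-name map
is also accepted.  :func:`harmonize` orients two datasets onto a common
effect allele against a genotype reference panel, resolving strand flips and
dropping ambiguous palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .ldref import ReferencePanel

logger = logging.getLogger(__name__)

#: canonical column order of a SummaryDataset table
SUMSTAT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_MA_COLUMNS = {"SNP": "snp_id", "A1": "effect_allele", "A2": "other_allele",
               "freq": "eaf", "b": "beta", "se": "se", "p": "pval", "N": "n"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

#: default frequency window in which a palindromic (A/T or C/G) SNP is
#: considered strand-ambiguous
PALINDROME_EAF_WINDOW = (0.42, 0.58)


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics file cannot be parsed."""


class SumstatsValidationError(ValueError):
    """Raised when a parsed dataset violates a hard invariant."""


@dataclass
class SummaryDataset:
    """Marginal GWAS summary statistics for a single trait.

    The backing ``table`` is a DataFrame with columns :data:`SUMSTAT_COLUMNS`.
    ``chrom``/``pos`` may be missing (NaN) when the source file carries no
    coordinates; they are filled from the reference panel at harmonization.
    """

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in ("snp_id", "effect_allele", "other_allele",
                               "beta", "se", "pval", "n") if c not in self.table.columns]
        if missing:
            raise SumstatsFormatError(f"missing required columns: {missing}")
        for c in ("chrom", "pos", "eaf"):
            if c not in self.table.columns:
                self.table[c] = np.nan
        self.table = self.table[SUMSTAT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def validate(self) -> "SummaryDataset":
        """Enforce invariants; reject bad records, error on duplicates."""
        t = self.table
        dup = t["snp_id"][t["snp_id"].duplicated()]
        if len(dup):
            raise SumstatsValidationError(
                f"duplicate snp_id(s): {sorted(dup.unique())[:5]}")

        keep = np.ones(len(t), dtype=bool)
        bad_se = ~(t["se"].to_numpy(float) > 0)
        for i in np.flatnonzero(bad_se):
            logger.warning("record %s rejected: non-positive se", t["snp_id"].iat[i])
        keep &= ~bad_se

        a1 = t["effect_allele"].astype(str).str.upper()
        a2 = t["other_allele"].astype(str).str.upper()
        bad_allele = ~(a1.isin(_VALID_ALLELES) & a2.isin(_VALID_ALLELES)) | (a1 == a2)
        for i in np.flatnonzero(bad_allele.to_numpy() & keep):
            logger.warning("record %s rejected: non-biallelic SNP alleles %s/%s",
                           t["snp_id"].iat[i], a1.iat[i], a2.iat[i])
        keep &= ~bad_allele.to_numpy()

        bad_p = ~((t["pval"].to_numpy(float) > 0) & (t["pval"].to_numpy(float) <= 1))
        for i in np.flatnonzero(bad_p & keep):
            logger.warning("record %s rejected: p-value outside (0,1]", t["snp_id"].iat[i])
        keep &= ~bad_p

        bad_n = ~(t["n"].to_numpy(float) > 0)
        keep &= ~bad_n

        out = t.loc[keep].copy()
        out["effect_allele"] = a1[keep]
        out["other_allele"] = a2[keep]

        # soft check: p consistent with |beta/se| under a normal reference
        with np.errstate(divide="ignore"):
            z = np.abs(out["beta"].to_numpy(float) / out["se"].to_numpy(float))
            p_implied = 2.0 * stats.norm.sf(z)
        p_obs = out["pval"].to_numpy(float)
        mask = p_implied > 1e-300
        rel = np.abs(p_obs[mask] - p_implied[mask]) / p_implied[mask]
        n_bad = int((rel > 0.10).sum())
        if n_bad:
            logger.warning("%d record(s) have p-values inconsistent with beta/se "
                           "beyond 10%% relative tolerance", n_bad)
        return SummaryDataset(out.reset_index(drop=True), trait=self.trait)


def read_sumstats(path: str | Path, dialect: str = "ma",
                  column_map: dict[str, str] | None = None,
                  default_n: float | None = None,
                  trait: str | None = None) -> SummaryDataset:
    """Read and validate a summary-statistics file.

    Parameters
    ----------
    path
        Whitespace/tab-delimited text file with a header row.
    dialect
        ``"ma"`` for GCTA ``.ma`` column names (``SNP A1 A2 freq b se p N``),
        ``"tsv"`` for a generic table (``column_map`` maps file columns to
        canonical names where they differ).
    default_n
        Dataset-level sample size used when the file has no N column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    if dialect == "ma":
        rename = {k: v for k, v in _MA_COLUMNS.items() if k in df.columns}
        df = df.rename(columns=rename)
    elif dialect == "tsv":
        if column_map:
            df = df.rename(columns=column_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if "n" not in df.columns:
        if default_n is None:
            raise SumstatsFormatError(
                f"{path.name}: no N column and no dataset-level N supplied")
        df["n"] = float(default_n)
    required = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path.name}: missing column(s) {missing}")
    ds = SummaryDataset(df, trait=trait or path.stem)
    return ds.validate()


def write_sumstats(ds: SummaryDataset, path: str | Path, dialect: str = "ma") -> None:
    """Write a dataset as ``.ma`` (default) or full canonical TSV.

    Numeric fields are written with ``repr`` round-trip precision.
    """
    path = Path(path)
    if dialect == "ma":
        inv = {v: k for k, v in _MA_COLUMNS.items()}
        out = ds.table[["snp_id", "effect_allele", "other_allele",
                        "eaf", "beta", "se", "pval", "n"]].rename(columns=inv)
    else:
        out = ds.table
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class HarmonizedPair:
    """Exposure and outcome statistics on a common effect-allele orientation.

    ``table`` carries one row per retained SNP with exposure columns
    (``beta_x``, ``se_x``, ``p_x``, ``n_x``, ``eaf_x``) and outcome columns
    (``beta_y``, ...), plus provenance flags.  ``dropped`` records SNPs
    removed during harmonization and the reason.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp_id", "reason"]))

    def __len__(self) -> int:
        return len(self.table)


def _orient(a1: pd.Series, a2: pd.Series, ref1: pd.Series, ref2: pd.Series):
    """Classify allele pairs vs a reference orientation.

    Returns (match, flip, bad): boolean arrays.  ``flip`` means effect/other
    swapped (beta sign flips); strand complements are resolved first.
    """
    c1 = a1.map(_COMPLEMENT)
    c2 = a2.map(_COMPLEMENT)
    same = (a1 == ref1) & (a2 == ref2)
    swap = (a1 == ref2) & (a2 == ref1)
    same_c = (c1 == ref1) & (c2 == ref2)
    swap_c = (c1 == ref2) & (c2 == ref1)
    match = (same | same_c).to_numpy()
    flip = (~match) & (swap | swap_c).to_numpy()
    bad = ~(match | flip)
    return match, flip, bad


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset,
              panel: "ReferencePanel",
              palindrome_policy: str = "drop_ambiguous",
              eaf_window: tuple[float, float] = PALINDROME_EAF_WINDOW,
              ) -> HarmonizedPair:
    """Intersect exposure, outcome and panel SNPs and orient alleles.

    The exposure orientation is first aligned to the panel, then the outcome
    is aligned to the exposure; outcome betas are sign-flipped where its
    effect/other alleles are swapped.  Palindromic SNPs (A/T, C/G) are
    dropped when ambiguous (``drop_ambiguous``: exposure eaf inside
    ``eaf_window``) or always (``drop_all``).
    """
    if palindrome_policy not in ("drop_ambiguous", "drop_all"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")

    ex = exposure.table.set_index("snp_id")
    ou = outcome.table.set_index("snp_id")
    pv = panel.variants.set_index("snp_id")

    shared = ex.index.intersection(ou.index).intersection(pv.index)
    dropped: list[tuple[str, str]] = []
    for sid in ex.index.difference(shared).union(ou.index.difference(shared)):
        dropped.append((sid, "missing"))
    if len(shared) == 0:
        raise SumstatsValidationError(
            "empty intersection of exposure, outcome and panel SNPs")

    ex = ex.loc[shared]
    ou = ou.loc[shared]
    pv = pv.loc[shared]

    # exposure orientation defines the common effect allele
    m, f, bad = _orient(ou["effect_allele"], ou["other_allele"],
                        ex["effect_allele"], ex["other_allele"])
    flipped = pd.Series(f, index=shared)
    irreconcilable = pd.Series(bad, index=shared)

    beta_y = ou["beta"].to_numpy(float).copy()
    eaf_y = ou["eaf"].to_numpy(float).copy()
    beta_y[f] *= -1.0
    eaf_y[f] = 1.0 - eaf_y[f]

    pal = ((ex["effect_allele"].map(_COMPLEMENT) == ex["other_allele"])
           ).to_numpy()
    eaf_x = ex["eaf"].to_numpy(float)
    if palindrome_policy == "drop_all":
        pal_drop = pal
    else:
        lo, hi = eaf_window
        ambiguous = np.isnan(eaf_x) | ((eaf_x >= lo) & (eaf_x <= hi))
        pal_drop = pal & ambiguous

    keep = ~(irreconcilable.to_numpy() | pal_drop)
    for sid in shared[irreconcilable.to_numpy()]:
        dropped.append((sid, "irreconcilable_alleles"))
        logger.warning("SNP %s dropped: irreconcilable allele pairs", sid)
    for sid in shared[pal_drop & ~irreconcilable.to_numpy()]:
        dropped.append((sid, "palindromic"))

    out = pd.DataFrame({
        "snp_id": shared,
        "chrom": pv["chrom"].to_numpy(),
        "pos": pv["pos"].to_numpy(),
        "effect_allele": ex["effect_allele"].to_numpy(),
        "other_allele": ex["other_allele"].to_numpy(),
        "eaf_x": eaf_x,
        "beta_x": ex["beta"].to_numpy(float),
        "se_x": ex["se"].to_numpy(float),
        "p_x": ex["pval"].to_numpy(float),
        "n_x": ex["n"].to_numpy(float),
        "eaf_y": eaf_y,
        "beta_y": beta_y,
        "se_y": ou["se"].to_numpy(float),
        "p_y": ou["pval"].to_numpy(float),
        "n_y": ou["n"].to_numpy(float),
        "flipped": flipped.to_numpy(),
    })[keep].reset_index(drop=True)

    drop_df = pd.DataFrame(dropped, columns=["snp_id", "reason"])
    return HarmonizedPair(out, drop_df)


def pair_exposure_dataset(pair: HarmonizedPair, trait: str = "exposure") -> SummaryDataset:
    """View the exposure side of a harmonized pair as a SummaryDataset."""
    t = pair.table
    return SummaryDataset(pd.DataFrame({
        "snp_id": t["snp_id"], "chrom": t["chrom"], "pos": t["pos"],
        "effect_allele": t["effect_allele"], "other_allele": t["other_allele"],
        "eaf": t["eaf_x"], "beta": t["beta_x"], "se": t["se_x"],
        "pval": t["p_x"], "n": t["n_x"]}), trait=trait)


def pair_outcome_dataset(pair: HarmonizedPair, trait: str = "outcome") -> SummaryDataset:
    """View the outcome side of a harmonized pair as a SummaryDataset."""
    t = pair.table
    return SummaryDataset(pd.DataFrame({
        "snp_id": t["snp_id"], "chrom": t["chrom"], "pos": t["pos"],
        "effect_allele": t["effect_allele"], "other_allele": t["other_allele"],
        "eaf": t["eaf_y"], "beta": t["beta_y"], "se": t["se_y"],
        "pval": t["p_y"], "n": t["n_y"]}), trait=trait)
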