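"""Genotype reference panels, LD correlation, clumping and LD blocks.

A :class:`ReferencePanel` is an individuals-by-variants additive genotype
matrix (0/1/2, NaN for missing) with a variant table.  Panels load from
PLINK ``bed/bim/fam`` triplets or from a plain-text TSV fixture.  LD is the
Pearson correlation of mean-imputed genotype columns.  :func:`clump`
performs greedy p-value-ordered index-SNP selection, and
:class:`LDBlockPartition` maps variants into pre-computed approximately
independent LD blocks (LDetect-style 3-column interval files).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)

MAX_VARIANT_MISSINGNESS = 0.10


class PanelError(ValueError):
    pass


class MonomorphicVariantError(ValueError):
    pass


@dataclass
class ReferencePanel:
    """Additive genotypes (n individuals x m variants) plus variant metadata.

    ``variants`` columns: snp_id, chrom, pos, a1 (counted allele), a2, maf.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise PanelError("genotype matrix must be 2-D")
        if self.genotypes.shape[1] != len(self.variants):
            raise PanelError("variant table does not match genotype columns")
        self.variants = self.variants.reset_index(drop=True)
        self._index = pd.Index(self.variants["snp_id"])

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> pd.Index:
        return self._index

    def column_indices(self, snp_ids) -> np.ndarray:
        idx = self._index.get_indexer(list(snp_ids))
        missing = [s for s, i in zip(snp_ids, idx) if i < 0]
        if missing:
            raise PanelError(f"SNP(s) not in panel: {missing[:5]}")
        return idx

    def standardized(self, snp_ids) -> np.ndarray:
        """Mean-imputed, centered, unit-variance genotype columns."""
        cols = self.genotypes[:, self.column_indices(snp_ids)].astype(float)
        mu = np.nanmean(cols, axis=0)
        inds = np.where(np.isnan(cols))
        cols[inds] = np.take(mu, inds[1])
        cols -= cols.mean(axis=0)
        sd = cols.std(axis=0)
        zero = sd == 0
        if zero.any():
            bad = np.asarray(list(snp_ids))[zero]
            raise MonomorphicVariantError(f"monomorphic variant(s): {bad[:5].tolist()}")
        return cols / sd


def _postload_filter(genotypes: np.ndarray, variants: pd.DataFrame) -> ReferencePanel:
    """Apply missingness cap and compute MAF from the data."""
    miss = np.mean(np.isnan(genotypes), axis=0)
    keep = miss < MAX_VARIANT_MISSINGNESS
    n_rej = int((~keep).sum())
    if n_rej:
        logger.warning("%d variant(s) rejected at load: missingness >= %.0f%%",
                       n_rej, 100 * MAX_VARIANT_MISSINGNESS)
    genotypes = genotypes[:, keep]
    variants = variants.loc[keep].reset_index(drop=True)
    freq = np.nanmean(genotypes, axis=0) / 2.0
    variants = variants.copy()
    variants["maf"] = np.minimum(freq, 1.0 - freq)
    return ReferencePanel(genotypes, variants)


def read_plink(prefix: str | Path) -> ReferencePanel:
    """Load a PLINK bed/bim/fam triplet (SNP-major, 2-bit encoding)."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise PanelError(f"{prefix}.bed: bad magic bytes or not SNP-major")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes: 00=hom a1 (2 copies), 01=missing, 10=het, 11=hom a2
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    genotypes = lut[codes].T  # n x m, counting a1 alleles
    variants = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return _postload_filter(genotypes, variants)


def read_genotype_tsv(genotype_path: str | Path, variant_path: str | Path) -> ReferencePanel:
    """Load the plain-text fixture format.

    ``genotype_path``: TSV, one row per individual, one column per SNP
    (header = snp ids, missing = NA).  ``variant_path``: TSV with columns
    snp_id, chrom, pos, a1, a2.
    """
    geno = pd.read_csv(genotype_path, sep="\t")
    variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    if list(geno.columns) != list(variants["snp_id"]):
        raise PanelError("genotype header does not match variant table order")
    return _postload_filter(geno.to_numpy(float), variants)


def ld_corr(panel: ReferencePanel, snp_ids) -> np.ndarray:
    """Pearson LD correlation matrix among ``snp_ids``.

    Missing genotypes are mean-imputed per variant.  The result is symmetric
    with a unit diagonal.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("need at least one SNP")
    z = panel.standardized(snp_ids)
    r = (z.T @ z) / z.shape[0]
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def clump(dataset: SummaryDataset, panel: ReferencePanel,
          p_thresh: float = 5e-8, r2_thresh: float = 0.001,
          window_kb: int = 10_000) -> list[str]:
    """Greedy LD clumping; returns index SNPs in retention order.

    SNPs with p <= ``p_thresh`` are visited in ascending p (ties: smaller
    position, then snp_id); a SNP is retained iff its r^2 with every
    previously retained SNP on the same chromosome within ``window_kb``
    (inclusive, |pos difference| <= window_kb*1000) is below ``r2_thresh``.
    """
    t = dataset.table
    pv = panel.variants.set_index("snp_id")
    t = t[t["snp_id"].isin(pv.index)]
    cand = t[t["pval"] <= p_thresh].copy()
    if cand.empty:
        return []
    meta = pv.loc[cand["snp_id"]]
    cand["chrom"] = meta["chrom"].to_numpy()
    cand["pos"] = meta["pos"].to_numpy()
    cand = cand.sort_values(["pval", "pos", "snp_id"], kind="mergesort")

    win = window_kb * 1000
    kept: list[str] = []
    kept_chrom: list[str] = []
    kept_pos: list[int] = []
    kept_z: list[np.ndarray] = []
    z_cache = panel.standardized(cand["snp_id"])
    for k, (_, row) in enumerate(cand.iterrows()):
        zi = z_cache[:, k]
        ok = True
        for j in range(len(kept)):
            if kept_chrom[j] != row["chrom"]:
                continue
            if abs(int(kept_pos[j]) - int(row["pos"])) > win:
                continue
            r = float(zi @ kept_z[j]) / panel.n_individuals
            if r * r >= r2_thresh:
                ok = False
                break
        if ok:
            kept.append(row["snp_id"])
            kept_chrom.append(row["chrom"])
            kept_pos.append(int(row["pos"]))
            kept_z.append(zi)
    return kept


# ---------------------------------------------------------------------------
# LD blocks


class BlockFormatError(ValueError):
    pass


@dataclass
class LDBlockPartition:
    """Ordered, non-overlapping (chrom, start, end) intervals, 1-based inclusive."""

    intervals: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        iv = self.intervals.copy()
        iv["chrom"] = iv["chrom"].astype(str)
        iv = iv.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in iv.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts > ends).any():
                raise BlockFormatError(f"interval with start > end on {chrom}")
            if (starts[1:] <= ends[:-1]).any():
                raise BlockFormatError(f"overlapping intervals on {chrom}")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def read(cls, path: str | Path, zero_based: bool = False) -> "LDBlockPartition":
        """Read a 3-column chrom/start/end text file.

        ``zero_based=True`` treats starts as 0-based half-open (LDetect BED
        convention) and converts to 1-based inclusive.
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end"], dtype={0: str})
        if df.iloc[0]["chrom"] in ("chr", "chrom", "chromosome"):  # header row
            df = df.iloc[1:].reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if zero_based:
            df["start"] += 1
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)

    def locate(self, chrom: str, pos: int) -> int | None:
        """Index of the covering interval, or None."""
        iv = self.intervals
        hit = iv[(iv["chrom"] == str(chrom)) & (iv["start"] <= pos) & (iv["end"] >= pos)]
        if hit.empty:
            return None
        return int(hit.index[0])


def assign_blocks(snp_ids, partition: LDBlockPartition,
                  panel: ReferencePanel) -> dict[str, list[str]]:
    """Map SNPs to covering LD blocks.

    Returns ``{block_label: [snp_id, ...]}`` preserving input order within
    each block.  Block labels are ``"chrom:start-end"``; SNPs covered by no
    interval get singleton pseudo-blocks labelled ``"singleton:<snp_id>"``.
    """
    pv = panel.variants.set_index("snp_id")
    out: dict[str, list[str]] = {}
    for sid in snp_ids:
        if sid not in pv.index:
            raise PanelError(f"SNP {sid} not in panel")
        chrom, pos = str(pv.at[sid, "chrom"]), int(pv.at[sid, "pos"])
        k = partition.locate(chrom, pos)
        if k is None:
            logger.warning("SNP %s (%s:%d) outside every LD block; singleton", sid, chrom, pos)
            label = f"singleton:{sid}"
        else:
            row = partition.intervals.loc[k]
            label = f"{row['chrom']}:{row['start']}-{row['end']}"
        out.setdefault(label, []).append(sid)
    return out


def block_snps(partition: LDBlockPartition, panel: ReferencePanel,
               block_label: str) -> list[str]:
    """All panel SNPs falling inside a block label (singletons: the SNP itself)."""
    if block_label.startswith("singleton:"):
        return [block_label.split(":", 1)[1]]
    chrom, span = block_label.split(":")
    start, end = (int(x) for x in span.split("-"))
    pv = panel.variants
    sel = (pv["chrom"].astype(str) == chrom) & (pv["pos"] >= start) & (pv["pos"] <= end)
    return pv.loc[sel, "snp_id"].tolist()
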