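import numpy as np
import pandas as pd
import pytest

from cmrkit.ldref import ReferencePanel


def panel_from_genotypes(geno: np.ndarray, chrom="1", pos0=1000, spacing=1000,
                         prefix="s") -> ReferencePanel:
    """Build a ReferencePanel around an explicit genotype matrix."""
    m = geno.shape[1]
    freq = np.nanmean(geno, axis=0) / 2.0
    variants = pd.DataFrame({
        "snp_id": [f"{prefix}{j}" for j in range(m)],
        "chrom": chrom, "pos": pos0 + spacing * np.arange(m),
        "a1": "A", "a2": "G", "maf": np.minimum(freq, 1 - freq)})
    return ReferencePanel(geno.astype(float), variants)


def sumstats_for_panel(panel, beta, se, pval=None, n=10000.0, trait="t"):
    """SummaryDataset aligned to a panel's variants."""
    from cmrkit.sumstats import SummaryDataset
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pval is None:
        from scipy import stats
        pval = 2 * stats.norm.sf(np.abs(beta / se))
    v = panel.variants
    return SummaryDataset(pd.DataFrame({
        "snp_id": v["snp_id"], "chrom": v["chrom"], "pos": v["pos"],
        "effect_allele": v["a1"], "other_allele": v["a2"],
        "eaf": np.nanmean(panel.genotypes, axis=0) / 2.0,
        "beta": beta, "se": se, "pval": pval, "n": float(n)}), trait=trait)


@pytest.fixture(scope="session")
def tiny_world():
    """Small in-memory panel + genome + truth (3 blocks x 50 SNPs, n=2000)."""
    from cmrkit.fixtures import tiny_panel_in_memory
    return tiny_panel_in_memory(seed=0)


@pytest.fixture()
def rng():
    # fresh, identically-seeded generator per test: deterministic and
    # independent of test execution order
    return np.random.default_rng(20240802)
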