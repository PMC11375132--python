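"""Deterministic small on-disk fixtures for tests, docs and CLI demos."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ldref import ReferencePanel
from .simulate import ScenarioConfig, build_genome, gwas, simulate_phenotypes, draw_truth
from .sumstats import SummaryDataset, write_sumstats

FIXTURE_KINDS = ("tiny_gwas", "tiny_panel", "blocks")


def _tiny_setup(seed: int):
    # beta* boosted so the 2,000-individual fixture yields genome-wide
    # significant instruments in every block
    cfg = ScenarioConfig(scenario=1, n_blocks=3, snps_per_block=(50, 50),
                         n_individuals=2000, theta=0.2, prop_ld=1.0,
                         beta_star_range=(0.35, 0.5), seed=seed)
    rng = np.random.default_rng(seed)
    genome = build_genome(cfg, rng)
    truth = draw_truth(cfg, genome, rng)
    geno = genome.sample_genotypes(cfg.n_individuals, rng)
    return cfg, genome, truth, geno, rng


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write a deterministic fixture set; returns the created paths.

    ``tiny_gwas``: exposure.ma + outcome.ma summary files (3 blocks x 50
    SNPs, n = 2,000).  ``tiny_panel``: genotypes.tsv + variants.tsv in the
    text panel format.  ``blocks``: blocks.tsv partition covering every
    panel variant.  The same seed always produces byte-identical files.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg, genome, truth, geno, rng = _tiny_setup(seed)
    created: list[Path] = []

    if kind == "tiny_gwas":
        X, _, _ = simulate_phenotypes(geno, truth, np.random.default_rng(seed + 1))
        geno_y = genome.sample_genotypes(cfg.n_individuals, rng)
        _, Y, _ = simulate_phenotypes(geno_y, truth, np.random.default_rng(seed + 2))
        for name, g, ph in (("exposure.ma", geno, X), ("outcome.ma", geno_y, Y)):
            ds = gwas(g, ph, genome.variants, trait=name.split(".")[0])
            path = out_dir / name
            write_sumstats(ds, path)
            created.append(path)
    elif kind == "tiny_panel":
        import pandas as pd
        gpath = out_dir / "genotypes.tsv"
        vpath = out_dir / "variants.tsv"
        pd.DataFrame(geno, columns=genome.variants["snp_id"]).to_csv(
            gpath, sep="\t", index=False)
        genome.variants[["snp_id", "chrom", "pos", "a1", "a2"]].to_csv(
            vpath, sep="\t", index=False)
        created += [gpath, vpath]
    else:  # blocks
        path = out_dir / "blocks.tsv"
        genome.partition().write(path)
        created.append(path)
    return created


def tiny_panel_in_memory(seed: int) -> tuple:
    """In-memory counterpart of the fixtures (panel, genome, truth, config)."""
    cfg, genome, truth, geno, _ = _tiny_setup(seed)
    variants = genome.variants.copy()
    freq = geno.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(freq, 1 - freq)
    return ReferencePanel(geno, variants), genome, truth, cfg
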