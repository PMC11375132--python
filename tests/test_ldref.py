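import numpy as np
import pandas as pd
import pytest

from cmrkit.ldref import (BlockFormatError, LDBlockPartition,
                          MonomorphicVariantError, assign_blocks, block_snps,
                          clump, ld_corr, read_genotype_tsv, read_plink)
from cmrkit.simulate import ScenarioConfig, build_genome

from conftest import panel_from_genotypes, sumstats_for_panel


class TestLDCorr:
    def test_unit_diagonal_and_oracle(self, rng):
        geno = rng.integers(0, 3, size=(500, 6)).astype(float)
        geno[rng.random(geno.shape) < 0.05] = np.nan  # some missing
        panel = panel_from_genotypes(geno)
        ids = panel.snp_ids.tolist()
        R = ld_corr(panel, ids)
        assert np.allclose(np.diag(R), 1.0)
        # naive two-pass oracle: mean-impute then np.corrcoef
        g = geno.copy()
        mu = np.nanmean(g, axis=0)
        for j in range(g.shape[1]):
            g[np.isnan(g[:, j]), j] = mu[j]
        assert np.allclose(R, np.corrcoef(g.T), atol=1e-10)

    def test_independent_variants_near_zero(self, rng):
        geno = rng.binomial(2, 0.3, size=(10000, 2)).astype(float)
        panel = panel_from_genotypes(geno)
        R = ld_corr(panel, panel.snp_ids.tolist())
        assert abs(R[0, 1]) < 0.05

    def test_copula_generator_roundtrip(self):
        # adjacent variants at copula target 0.8 reproduce it in-sample
        cfg = ScenarioConfig(scenario=1, n_blocks=1, snps_per_block=(5, 5),
                             adjacent_r_range=(0.8, 0.8), maf_range=(0.3, 0.3))
        genome = build_genome(cfg, np.random.default_rng(42))
        geno = genome.sample_genotypes(10000, np.random.default_rng(43))
        r = np.corrcoef(geno.T.astype(float))
        adj = np.diag(r, k=1)
        assert np.all(np.abs(adj - 0.8) < 0.05)

    def test_monomorphic_named(self, rng):
        geno = rng.integers(0, 3, size=(100, 2)).astype(float)
        geno[:, 1] = 2.0
        panel = panel_from_genotypes(geno)
        with pytest.raises(MonomorphicVariantError, match="s1"):
            ld_corr(panel, ["s0", "s1"])


class TestClump:
    def _correlated_panel(self, rng, r2=0.5, n=2000):
        g0 = rng.binomial(2, 0.5, size=n).astype(float)
        flip = rng.random(n) < (1 - np.sqrt(r2)) / 2
        g1 = np.where(flip, rng.binomial(2, 0.5, size=n), g0).astype(float)
        g2 = rng.binomial(2, 0.4, size=n).astype(float)
        return panel_from_genotypes(np.column_stack([g0, g1, g2]))

    def test_greedy_rule_keeps_best_p(self, rng):
        panel = self._correlated_panel(rng)
        ds = sumstats_for_panel(panel, beta=[0.2, 0.19, 0.0],
                                se=[0.02, 0.02, 0.02],
                                pval=[1e-10, 1e-9, 0.5])
        kept = clump(ds, panel, p_thresh=5e-8, r2_thresh=0.1, window_kb=10)
        assert kept == ["s0"]

    def test_no_significant_snp_empty(self, rng):
        panel = self._correlated_panel(rng)
        ds = sumstats_for_panel(panel, beta=[0.01] * 3, se=[0.02] * 3,
                                pval=[0.1, 0.2, 0.3])
        assert clump(ds, panel) == []

    def test_different_chromosomes_both_retained(self, rng):
        g = rng.binomial(2, 0.5, size=(2000, 2)).astype(float)
        g[:, 1] = g[:, 0]  # perfectly correlated but on another chromosome
        panel = panel_from_genotypes(g)
        panel.variants.loc[1, "chrom"] = "2"
        ds = sumstats_for_panel(panel, beta=[0.2, 0.2], se=[0.02, 0.02],
                                pval=[1e-9, 1e-9])
        assert set(clump(ds, panel)) == {"s0", "s1"}

    def test_output_internally_independent(self, rng):
        cfg = ScenarioConfig(scenario=1, n_blocks=2, snps_per_block=(30, 30))
        genome = build_genome(cfg, np.random.default_rng(7))
        geno = genome.sample_genotypes(3000, np.random.default_rng(8))
        variants = genome.variants.copy()
        variants["maf"] = np.minimum(geno.mean(0) / 2, 1 - geno.mean(0) / 2)
        from cmrkit.ldref import ReferencePanel
        panel = ReferencePanel(geno.astype(float), variants)
        beta = np.random.default_rng(9).normal(0, 0.1, genome.n_variants)
        ds = sumstats_for_panel(panel, beta=beta, se=np.full(genome.n_variants, 0.01))
        kept = clump(ds, panel, p_thresh=1e-4, r2_thresh=0.05, window_kb=50_000)
        if len(kept) > 1:
            R = ld_corr(panel, kept)
            off = R[~np.eye(len(kept), dtype=bool)]
            assert np.all(off**2 < 0.05)


class TestBlocks:
    def _partition(self):
        return LDBlockPartition(pd.DataFrame(
            {"chrom": ["1", "1"], "start": [1, 2001], "end": [2000, 4000]}))

    def test_assignment_and_singleton(self, rng):
        geno = rng.integers(0, 3, size=(50, 3)).astype(float)
        panel = panel_from_genotypes(geno, pos0=500, spacing=2500)  # 500, 3000, 5500
        mapping = assign_blocks(["s0", "s1", "s2"], self._partition(), panel)
        assert mapping["1:1-2000"] == ["s0"]
        assert mapping["1:2001-4000"] == ["s1"]
        assert mapping["singleton:s2"] == ["s2"]
        # partition property: each SNP exactly once
        all_snps = [s for v in mapping.values() for s in v]
        assert sorted(all_snps) == ["s0", "s1", "s2"]

    def test_two_ivs_share_block(self, rng):
        geno = rng.integers(0, 3, size=(50, 2)).astype(float)
        panel = panel_from_genotypes(geno, pos0=100, spacing=200)
        mapping = assign_blocks(["s0", "s1"], self._partition(), panel)
        assert mapping["1:1-2000"] == ["s0", "s1"]

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(BlockFormatError, match="overlap"):
            LDBlockPartition(pd.DataFrame(
                {"chrom": ["1", "1"], "start": [1, 1500], "end": [2000, 3000]}))

    def test_read_write_roundtrip_and_zero_based(self, tmp_path):
        p = self._partition()
        path = tmp_path / "blocks.tsv"
        p.write(path)
        p2 = LDBlockPartition.read(path)
        pd.testing.assert_frame_equal(p.intervals, p2.intervals)
        # LDetect-style 0-based half-open start converts to 1-based
        path0 = tmp_path / "bed.tsv"
        path0.write_text("1\t0\t2000\n1\t2000\t4000\n")
        p3 = LDBlockPartition.read(path0, zero_based=True)
        assert p3.intervals["start"].tolist() == [1, 2001]

    def test_block_snps_covers_interval(self, rng):
        geno = rng.integers(0, 3, size=(50, 4)).astype(float)
        panel = panel_from_genotypes(geno, pos0=500, spacing=1000)
        assert block_snps(self._partition(), panel, "1:1-2000") == ["s0", "s1"]


class TestPanelIO:
    def _write_plink(self, tmp_path, geno, prefix="test"):
        """Encode a genotype matrix as a PLINK bed/bim/fam triplet."""
        n, m = geno.shape
        lines = [f"1\tsnp{j}\t0\t{1000 + j}\tA\tG" for j in range(m)]
        (tmp_path / f"{prefix}.bim").write_text("\n".join(lines) + "\n")
        (tmp_path / f"{prefix}.fam").write_text(
            "\n".join(f"f{i} i{i} 0 0 0 -9" for i in range(n)) + "\n")
        code = {2: 0b00, 1: 0b10, 0: 0b11}  # counted-allele dosage -> 2-bit
        body = bytearray([0x6C, 0x1B, 0x01])
        for j in range(m):
            for s in range(0, n, 4):
                byte = 0
                for k, i in enumerate(range(s, min(s + 4, n))):
                    g = geno[i, j]
                    bits = 0b01 if np.isnan(g) else code[int(g)]
                    byte |= bits << (2 * k)
                body.append(byte)
        (tmp_path / f"{prefix}.bed").write_bytes(bytes(body))
        return tmp_path / prefix

    def test_plink_roundtrip(self, tmp_path, rng):
        geno = rng.integers(0, 3, size=(13, 5)).astype(float)
        geno[2, 1] = np.nan
        prefix = self._write_plink(tmp_path, geno)
        panel = read_plink(prefix)
        assert panel.n_individuals == 13 and panel.n_variants == 5
        np.testing.assert_array_equal(np.isnan(panel.genotypes), np.isnan(geno))
        np.testing.assert_allclose(panel.genotypes[~np.isnan(geno)],
                                   geno[~np.isnan(geno)])

    def test_tsv_fixture_roundtrip(self, tmp_path, rng):
        geno = rng.integers(0, 3, size=(20, 3))
        ids = [f"s{j}" for j in range(3)]
        pd.DataFrame(geno, columns=ids).to_csv(tmp_path / "genotypes.tsv",
                                               sep="\t", index=False)
        pd.DataFrame({"snp_id": ids, "chrom": "1", "pos": [1, 2, 3],
                      "a1": "A", "a2": "G"}).to_csv(
            tmp_path / "variants.tsv", sep="\t", index=False)
        panel = read_genotype_tsv(tmp_path / "genotypes.tsv",
                                  tmp_path / "variants.tsv")
        np.testing.assert_allclose(panel.genotypes, geno)

    def test_high_missingness_variant_rejected(self, tmp_path, rng):
        geno = rng.integers(0, 3, size=(20, 2)).astype(float)
        geno[:10, 1] = np.nan  # 50% missing
        prefix = self._write_plink(tmp_path, geno)
        panel = read_plink(prefix)
        assert panel.n_variants == 1
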