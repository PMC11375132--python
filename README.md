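# cmrkit

Two-sample Mendelian randomization (MR) with **automated adjustment of
LD-induced horizontal pleiotropy**: a conditional-MR ("CMR") toolkit for
statistical geneticists and epidemiologists working from GWAS summary
statistics and an LD reference panel.

## The problem

MR uses genetic variants as instruments: a variant Z_j associated with an
exposure X identifies the causal effect θ of X on an outcome Y through the
per-variant relation

```
β_Yj = θ β_Xj + α_j
```

where (β_Xj, β_Yj) are the variant's marginal GWAS effects and α_j is its
horizontal-pleiotropy effect, which must be zero (or suitably behaved) for
valid inference. A pervasive and under-appreciated source of nonzero α_j is
**linkage disequilibrium**: a neighboring variant G_j with a direct effect
r_j on the outcome transmits `α_j = ρ_j r_j` to the instrument through their
LD correlation ρ_j — even when the instrument itself is biologically clean.
Robust estimators (weighted median/mode, cML, RAPS) can absorb *some*
invalid instruments, but LD-induced pleiotropy is often directional and can
affect most instruments at once, violating every standard assumption.

The remedy implemented here is a two-stage framework built on conditional
genetic effects. Writing β*_Xj, β*_Yj for the effects of Z_j *conditional*
on its outcome-associated neighbors,

```
β*_Yj = θ β*_Xj + α*_j          with   α_j = α*_j + ρ'_j r_j
```

so conditioning removes the LD-transmitted term ρ'_j r_j entirely while the
causal parameter θ is unchanged. Concretely:

* **Stage 1** — per LD block containing instruments: a stepwise
  conditional-and-joint (COJO-style) selection on the *outcome* summary
  statistics finds nearby jointly associated SNPs (p < 5×10⁻⁶); each
  instrument's exposure and outcome effects are then re-estimated
  conditional on that set, using only marginal summary statistics and the
  panel LD matrix. Instruments collinear with a selected neighbor
  (|r| ≥ 0.9) are excluded.
* **Stage 2** — robust two-sample MR estimators (random-effects IVW, RAPS,
  weighted median, weighted mode, cML with BIC model averaging) run on the
  conditional effect pairs, handling any residual *biological* pleiotropy.

The package also ships LD clumping, allele harmonization, Steiger
directionality filtering, a per-instrument Bayesian colocalization
sensitivity analysis (PP0–PP4 and the per-SNP PP4-IV that flags
colocalization at a neighbor rather than at the instrument), and a
block-LD synthetic genome simulator used for the validation study.

## Worked example

Generate a deterministic toy dataset (3 LD blocks × 50 SNPs, n = 2,000, true
causal effect **θ = 0.2**, and two neighboring outcome-effect SNPs per block
— i.e. LD-induced pleiotropy everywhere) and run both frameworks:

```bash
cmrkit fixture --kind tiny_gwas  --seed 0 --out data
cmrkit fixture --kind tiny_panel --seed 0 --out data
cmrkit fixture --kind blocks     --seed 0 --out data
cmrkit cmr --exposure data/exposure.ma --outcome data/outcome.ma \
           --panel data/panel --blocks data/blocks.tsv --out results --seed 1
```

which prints (abridged):

```
             method    theta       se         pval  n_iv
             MR-ivw 0.456189 0.086039 1.144714e-07     3
            MR-raps 0.460177 0.068325 1.637854e-11     3
 MR-weighted_median 0.443431 0.097489 5.402213e-06     3
   MR-weighted_mode 0.402425 0.108011 1.947034e-04     3
             MR-cml 0.457009 0.084005 5.319351e-08     3
            CMR-ivw 0.239330 0.082587 3.756464e-03     3
           CMR-raps 0.240421 0.043240 2.695123e-08     3
CMR-weighted_median 0.213668 0.094309 2.347515e-02     3
  CMR-weighted_mode 0.180446 0.106861 9.129306e-02     3
            CMR-cml 0.238511 0.086346 5.740297e-03     3
```

Every standard-MR estimate is inflated to ≈ 0.46 — more than double the
truth — because all three instruments carry positive LD-induced pleiotropy.
After stage-1 conditioning, the CMR estimates cluster around the true 0.2,
and the heterogeneity among ratio estimates drops (Cochran's Q 2.58 → 0.73
in the diagnostics). `results/` also contains the per-instrument marginal
vs conditional estimates, the diagnostics JSON and the resolved config
snapshot.

The same machinery is scriptable from Python (`cmrkit.run_cmr`,
`cmrkit.run_scenario`, …); see `docs/methods.md` for the model, parameter
and design details.

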