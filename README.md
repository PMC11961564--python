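# mrscreen

Two-sample Mendelian randomization (MR) screening and two-step
mediation analysis from GWAS summary statistics — with a synthetic
summary-data generator so the whole pipeline is verifiable offline.

Epidemiologists increasingly ask causal questions of the form *does
disease X raise the risk of outcomes Y₁…Yₖ, and is the effect carried
by a measurable mediator M?* using only published GWAS association
tables.  `mrscreen` implements that workflow end to end: instrument
selection (p < 5×10⁻⁸ with a 5×10⁻⁶ fallback, greedy LD clumping at
r² ≤ 0.001 within 10,000 kb, per-SNP F ≥ 10), allele harmonization with
unconditional removal of palindromic SNPs, four causal estimators,
heterogeneity/pleiotropy diagnostics, Bonferroni-tiered screening of
outcome families, bidirectional (reverse) analysis, replication, and
product-of-coefficients mediation with delta-method intervals.

## The statistics at the core

For harmonized per-SNP effects (β̂ˣⱼ, β̂ʸⱼ) the inverse-variance-weighted
estimate of the causal effect θ is

    θ̂_IVW = Σⱼ wⱼ β̂ˣⱼ β̂ʸⱼ / Σⱼ wⱼ (β̂ˣⱼ)²,   wⱼ = 1/(σʸⱼ)²,

with multiplicative random-effects SE floored at the fixed-effect
value.  MR-Egger refits with an intercept (average directional
pleiotropy); the weighted median interpolates the weighted ratio
distribution at weight ½; the weighted mode maximizes a weighted kernel
density of the ratios.  Instrument strength is
F = ((N−K−1)/K)·(R²/(1−R²)).  A total effect β₀ decomposes through a
mediator as indirect = β₁β₂, direct = β₀ − β₁β₂, proportion = β₁β₂/β₀,
with delta-method SEs.  Sensitivity: Cochran's Q, Egger intercept,
MR-PRESSO (simulation-based global/outlier/distortion tests),
leave-one-out.  See `docs/methods.md` for the full account.

## Worked example

```python
import mrscreen as mr

cfg = mr.SimConfig(m_snps=50, theta=0.25)          # known truth: 0.25
exposure, outcome, truth = mr.simulate_pair(cfg, seed=1)
h = mr.harmonize(exposure, outcome)
for r in mr.run_all_methods(h, seed=2, n_boot=500):
    print(f"{r.method:16s} beta={r.beta:.4f} se={r.se:.4f} "
          f"OR={r.or_:.3f} p={r.pval:.2e}")
```

prints

```
ivw              beta=0.2505 se=0.0080 OR=1.285 p=5.39e-213
egger            beta=0.2618 se=0.0126 OR=1.299 p=1.35e-25
weighted_median  beta=0.2537 se=0.0114 OR=1.289 p=4.30e-110
weighted_mode    beta=0.2578 se=0.0833 OR=1.294 p=1.97e-03
```

— all four estimators recover the planted log-odds effect 0.25
(OR ≈ 1.28) with sign-consistent estimates, the concordance pattern a
screen requires before trusting the IVW headline number.  The
`examples/` directory has one short script per capability (estimation,
instrument selection, sensitivity analysis, mediation, family
screening); each prints its numbers with a note on what they mean.

A thin CLI drives the same library from YAML run configs:

```sh
mr simulate --config run.yaml
mr screen   --config run.yaml --seed 12 --out results/
```

writing results/sensitivity/forest/exclusion TSVs, a run log with
per-stage counts, and a JSON manifest (inputs, config hash, seed,
version).  Reruns with the same config and seed are byte-identical.

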