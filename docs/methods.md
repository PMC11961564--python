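# Methods

`mrscreen` implements a two-sample Mendelian randomization (MR)
screening and mediation pipeline operating entirely on GWAS summary
statistics, together with a summary-level simulator that provides ground
truth for every stage.

## Model and assumptions

For SNP *j*, let β̂ˣⱼ (SE σˣⱼ) be its association with the exposure and
β̂ʸⱼ (SE σʸⱼ) its association with the outcome, estimated in
non-overlapping samples and harmonized to the same effect allele.  MR
treats each SNP as an instrumental variable under the three core IV
assumptions — relevance (the SNP affects the exposure), independence
(no confounding of the SNP–outcome relation), and exclusion restriction
(no effect on the outcome except through the exposure).  Under these,
each Wald ratio β̂ʸⱼ/β̂ˣⱼ estimates the causal effect θ on the log-odds
scale, and estimators differ in how they combine ratios when some
instruments are invalid.

### Estimators

- **IVW** (primary): weighted regression of β̂ʸ on β̂ˣ through the
  origin with weights 1/σʸ².  θ̂ = Σwβ̂ˣβ̂ʸ / Σw(β̂ˣ)²,
  SE = √(1/Σw(β̂ˣ)²) · max(1, σ̂), where σ̂² is the weighted residual
  mean square (multiplicative random effects, under-dispersion floored
  at 1); p from the standard normal.  The floor makes the test slightly
  conservative: exactly computed at 50 instruments the size of a
  nominal 5% test is 4.3%, and 0.30% at a 0.05/13 Bonferroni threshold
  (nominal 0.38%) — a property to keep in mind when interpreting
  calibration studies of the screen.
- **MR-Egger**: the same regression with an intercept, rows oriented so
  β̂ˣ ≥ 0.  The slope is robust to directional pleiotropy under the
  InSIDE assumption; the intercept estimates the average pleiotropic
  effect.  SEs share the max(1, σ̂) multiplier; inference uses t with
  n−2 df.  Note the finite-sample caveat: instruments whose observed
  exposure effect has the wrong sign carry misoriented pleiotropy, so
  the intercept is attenuated by roughly 2·arctan(σˣ/sd(γ))/π plus an
  extrapolation term; it disappears only as instruments become
  noise-free.
- **Weighted median**: per-SNP ratios with weights (β̂ˣ)²/(σʸ)²
  (inverse first-order ratio variance); the estimate interpolates the
  weighted cumulative distribution at weight ½ (midpoint convention).
  Consistent when ≥ 50% of weight is valid — as an asymptotic
  statement: with a fraction π of invalid instruments all biased in
  the same direction, the finite-noise estimand sits at the
  ½/(1−π)-quantile of the valid-ratio distribution, i.e. a bias of
  order z₍½/(1−π)₎ × (per-ratio noise SD) that vanishes only as
  instrument noise does.  SEs by parametric bootstrap (resampling β̂ˣ,
  β̂ʸ from normals at the observed values; `n_boot` default 1000, seed
  mandatory).
- **Weighted mode**: argmax of a Gaussian-kernel density over the
  ratios with the same weights as kernel masses; bandwidth is
  Silverman's rule (0.9·min(sd, IQR/1.34)·m^(−1/5)) times a
  configurable factor (default 1), maximized on a 2001-point grid
  spanning the ratio range ± 3 bandwidths; bootstrap SE as above.
- **Wald ratio** for single-instrument pairs; first-order SE σʸ/|β̂ˣ|
  by default (a second-order option adds the exposure-noise term).

### Instrument selection

SNPs associate with the exposure at p < 5×10⁻⁸, relaxed to 5×10⁻⁶ when
fewer than three pass (both configurable); mediator screens use
p < 1×10⁻⁵ to admit enough instruments per cytokine.  Greedy clumping
(rank by p, ties by genomic position; an index SNP removes every
remaining same-chromosome SNP within 10,000 kb with r² > 0.001) yields
approximately independent instruments; the LD matrix is an explicit
input (square or long TSV) so no reference panel or network service is
involved.  Instrument strength uses F = ((N−K−1)/K)·(R²/(1−R²)) with
K = 1 per SNP; when no R² column is supplied, R² = β²/(β² + (N−2)σ²),
under which per-SNP F equals (β/σ)² exactly.  F < 10 marks a weak
instrument and removes it.

### Harmonization

Records match by rsID only.  Outcome effects are flipped when the
allele pair is swapped; palindromic (A/T, C/G) SNPs are removed
unconditionally (no frequency-based strand inference); mismatched
allele pairs are removed as ambiguous; SNPs absent from the outcome are
dropped (no proxy search).  Every exclusion is logged with a reason, so
rows plus exclusions always account for the full instrument set.

### Sensitivity analyses

Cochran's Q on the Wald ratios (first-order SEs, fixed-effect weighted
mean, χ²ₙ₋₁); the Egger intercept test (threshold 0.05); leave-one-out
IVW (flag when removal flips the sign or moves the estimate by more
than one full-set SE, configurable); and MR-PRESSO.  The MR-PRESSO
global statistic is the weighted residual sum of squares of each SNP
around its leave-one-out IVW prediction, ranked against `n_sim`
parametric simulations of the no-pleiotropy null; per-SNP outlier
p-values compare each observed residual with its simulated
distribution, Bonferroni-corrected across SNPs at 0.05.  Empirical
p-values use add-one smoothing, (1 + #{≥ obs})/(1 + n_sim), so the
smallest achievable Bonferroni-corrected outlier p is
m/(n_sim+1) — with 30 SNPs, `n_sim` ≥ 600 is needed before any flag is
possible; the default is 1000.  The distortion test compares the
raw-minus-corrected slope difference against the distribution obtained
by removing random subsets of the same size.  When outliers are
flagged, the screen reports both MR-PRESSO's corrected estimate and a
manual IVW re-run without the flagged SNPs (they coincide by
construction here, but both columns are emitted).  A very large
outlier can contaminate every leave-one-out slope and trigger cascade
flagging in small instrument sets — a known behavior of the procedure,
visible in the planted-outlier studies if the outlier is made extreme.

### Screening design

A forward screen runs one exposure against a family of outcomes;
verdicts follow two tiers: raw p < 0.05 "potential", Bonferroni p < 0.05
"strong", with the family size m an explicit, reported parameter
defaulting to the number of outcomes.  Outcome-level failures (no
shared SNPs, no instruments) mark that outcome failed without aborting
the screen.  The reverse screen swaps roles, selecting instruments per
outcome-as-exposure with the same threshold fallback and F filter.  The
mediator screen is two-step: (A) mediator → outcome for every mediator
(instruments at the mediator threshold), keeping IVW p < 0.05 with
direction-consistent secondary methods (configurable); (B) exposure →
mediator for survivors, keeping p < 0.05; (C) delta-method
decomposition through each survivor.  Replication re-runs the same
instruments against an independent cohort; "replicated" requires
p < 0.05 with the primary's sign.

### Mediation decomposition

With β₀ the total exposure → outcome effect, β₁ exposure → mediator and
β₂ mediator → outcome (all log-scale), the indirect effect is β₁β₂, the
direct effect β₀ − β₁β₂, and the proportion mediated β₁β₂/β₀ — negative
exactly when the mediated path opposes the total effect (suppression).
First-order delta method with zero covariance across the independent
GWAS samples: Var(β₁β₂) = β₁²se₂² + β₂²se₁² (the se₁²se₂² term is an
option, off by default);
Var(prop) = (se_ind/β₀)² + (β₁β₂·se₀/β₀²)²; 95% CIs are normal.  The
identities indirect + direct = total and proportion·total = indirect
hold to machine precision by construction.  β₀ = 0 flags the
proportion undefined while still returning the decomposition.  The
delta CI for the product is known to be only approximately calibrated
when both factors are near zero; the calibration study measures ~95%
coverage away from that boundary and ~95% at the β₁ = 0 boundary for
well-separated β₂.

Worked arithmetic at published step odds ratios 0.9804 (exposure →
mediator) and 1.0954 (mediator → outcome) against a total OR of 1.021
gives indirect = ln(0.9804)·ln(1.0954) = −0.0018037 and proportion
= −8.68%.  The source report prints −14.3% for this configuration,
which its own printed odds ratios do not reproduce (an unprinted,
possibly unrounded or different-estimator β₀ would be required); the
package reports the formula's value.

## Synthetic data generator

Two-sample MR consumes only summary statistics, so the generator draws
them directly — no individual-level genotypes.  True instrument
effects γⱼ ~ N(0, γ_sd²); effect-allele frequencies ~ U(0.1, 0.9)
(avoiding degenerate SEs); standard errors 1/√(2·eaf·(1−eaf)·N);
observed effects are normal draws around the truth; binary outcomes are
emulated directly on the log-odds scale (no liability model).  A
fraction `pleio_frac` of instruments receives pleiotropy
αⱼ ~ N(pleio_mean, pleio_sd²), optionally correlated with |γⱼ| via a
Gaussian-copula-style coupling (`inside_violation`) to break InSIDE.
Directional pleiotropy is planted relative to the exposure-raising
allele (the outcome mean is θγⱼ + sign(γⱼ)αⱼ): defining it relative to
an arbitrary allele coding would make "directional" meaningless, since
MR-Egger's β̂ˣ ≥ 0 orientation would cancel it in expectation.  The
triad generator adds a mediator with its own disjoint instrument block
(κⱼ): mediator effect β₁γⱼ + κⱼ, outcome effect θ_direct·γⱼ +
β₂(β₁γⱼ + κⱼ) + αⱼ, so the true total is θ_direct + β₁β₂.  The AR(1)
block LD matrix (r² = ρ^(2|i−j|) within blocks) drives clumping
semantics only; observed effect draws are independent across SNPs.
That, plus single-ancestry homogeneity, rsID-perfect matching, no
sample overlap and no population structure, is what the simulator does
*not* emulate about real GWAS data — passing calibration here
demonstrates correctness of the statistical machinery under the MR
model, not robustness to those real-data pathologies.

### Reference study conditions (defaults)

| parameter | default | rationale |
|---|---|---|
| m_snps | 50 | order of a well-powered immune-trait GWAS hit count |
| n_exp, n_out | 100,000 | large modern case-control meta-analyses |
| n_med | 14,824 | the circulating-cytokine GWAS scale |
| γ_sd | 0.1 | typical strong log-odds effects for autoimmune loci |
| θ | 0.25 | clearly detectable reference effect |
| β₁, β₂, θ_direct | −0.02, 0.09, 0.0226 | the published mediation scale (total ≈ 0.0208, proportion ≈ −8.65%) |
| pleio_sd | 0.02 | pleiotropy spread smaller than its directional mean (0.05) in robustness studies |
| ld_rho | 0 | instruments independent, matching the MR assumption |

## Calibration studies and their problem sizes

`mrscreen.calibration` (driven by `scripts/acceptance.py` and the
acceptance test suite) recomputes, at these sizes: IVW recovery
(500 replicates), type-I error (2000), the directional-pleiotropy
robustness split and Egger-intercept recovery (500, 40% invalid,
mean 0.05), MR-PRESSO planted-outlier detection (200, outlier on the
strongest instrument) and global-test calibration (500), delta CI
coverage (5000), mediation identities (1000 random inputs), oracle
equivalence (clumping vs exhaustive pairwise verification on 500
instances of ≤ 15 SNPs; weighted median vs a cumulative-weight scan;
IVW vs generic no-intercept WLS; Q vs a fixed-effect meta-analysis),
and the family-wise strong-verdict rate over 2000 all-null 13-outcome
families.  Two documented gaps between idealized bands and the actual
sampling theory: the weighted median under 40% same-direction
pleiotropy retains the quantile-shift bias described above (its mean
does not sit within Monte-Carlo error of the truth at any instrument
strength), and the floored random-effects SE places the family-wise
rate near 0.038 rather than 0.05.  Both are reported as measured.

Power notes: step B of the mediator screen (exposure → mediator at
β₁ = −0.02) needs se(β̂₁) ≤ 0.0062 for 90% power, i.e. a mediator GWAS
of roughly 150,000+ at these instrument strengths; at the
cytokine-GWAS scale (14,824) power is ~20%, so planted-path recovery
studies use a larger mediator sample and real cytokine-scale screens
should be read as low-powered for small β₁.  Reverse-MR null behavior
requires the downstream trait to carry its own genetic architecture
with the exposure's per-SNP spillover below genome-wide significance;
if a trait's only hits are inherited from the exposure, reverse MR
estimates 1/θ — the classic reverse-causation artifact, reproduced by
the simulator when configured that way.

## Numerical conventions

95% CIs use the normal 0.975 quantile (t for MR-Egger); p-values are
clamped to (0, 1]; bootstrap and simulation procedures require explicit
seeds and are byte-reproducible; clumping ties break by genomic
position; duplicate rsIDs keep the smallest-p row; zero-bandwidth mode
inputs (all ratios equal) return the common ratio with zero SE;
weighted-median interpolation follows the midpoint convention; Egger is
undefined (raises) when all oriented instrument strengths coincide.
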