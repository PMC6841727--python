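# Methods

## Model

For a centred phenotype **y** (n × 1) and genotype matrix **X** (n × p,
allele counts 0/1/2, columns centred and optionally variance-scaled), the
multiple regression **y** = **Xβ** + **ε**, ε ~ N(0, σ²ε I), is re-expressed
in terms of the per-SNP marginal least-squares effects
**b** = **D**⁻¹**X**′**y**, **D** = diag(x′ⱼxⱼ):

    b = D^{-1/2} B D^{1/2} β + D^{-1} X'ε,

with **B** = **D**<sup>−1/2</sup>**X**′**X** **D**<sup>−1/2</sup> the LD
correlation matrix. Inference about **β** therefore needs only (b, D, B)
plus a scalar y′y. Each βⱼ carries the BayesR prior — a point mass at zero
with probability π₁ and C−1 normal components N(0, γ_c σ²β) — with scaled
inverse-χ² priors on σ²β and σ²ε and a Dirichlet(α) prior on π.

Assumptions inherited from the model: the summary statistics come from a
least-squares analysis of one homogeneous sample at fully observed
genotypes; the reference panel's LD resembles that sample's LD; the
phenotype was centred (and here, variance-standardised). Violations show
up as convergence pathologies rather than graceful degradation — see
*Limitations*.

## Reconstruction of the sufficient statistics

* `D̂ⱼⱼ = 1/(se²ⱼ + b²ⱼ/nⱼ)` for centred genotypes, or `D̂ⱼⱼ = nⱼ` when the
  genotypes are taken as variance-scaled (`scaled=True`). The first form
  recovers x′ⱼxⱼ up to a multiplicative O(1/n) + O(R²ⱼ/n) error *provided
  the phenotype has unit variance*; the implementation therefore assumes a
  standardised trait throughout.
* `X′y = D̂ b`.
* `y′y = n̄` with n̄ the median per-SNP sample size — exact for a phenotype
  scaled to unit population variance. Because the se-based D̂ absorbs any
  phenotype scale into an overall factor, the sampler's h² and π estimates
  are invariant to the trait's scaling; only the reported effect sizes
  change scale.
* Per-SNP sample-size heterogeneity enters only through D̂; the σ²ε update
  uses the single effective sample size n̄.

## LD reference

The reference correlation matrix is built chromosome-wise from a genotype
panel: Pearson correlations on mean-imputed, centred hard calls, each
off-diagonal multiplied by the shrinkage factor

    exp(-ϱᵢⱼ / 2m),    ϱᵢⱼ = 4 Nₑ cᵢⱼ,

and set to zero when the factor falls below a hard cutoff. Defaults:
Nₑ = 11,400 (European effective population size), m = 183 (CEU individuals
behind the 1000G OMNI genetic map), cutoff 10⁻³.

**Units.** ϱ = 4Nₑc takes the genetic distance c in **Morgans** (the
Li–Stephens population-scaled recombination rate). Descriptions of this
estimator sometimes say "centimorgans"; with Nₑ ≈ 10⁴ that reading would
zero all but immediately adjacent pairs, whereas the Morgan convention
gives the ~10 Mb windows the estimator is known for (the cutoff distance
with defaults is −ln(10⁻³)·2m/4Nₑ ≈ 0.0554 Morgans ≈ 5.5 cM). This
package uses Morgans; `interpolate_cm` returns cM and the builder divides
by 100.

Storage is one contiguous window per SNP (positions are sorted, so the
factor threshold yields contiguous supports), concatenated CSC-style, with
a CRC-checked binary container (`docs/FORMATS.md`). No positive-
semidefinite repair is applied after thresholding; the Gibbs sweep does
not require PSD input, but the quadratic form β′X′Xβ can then dip
marginally below zero — σ²g is floored at 0 when h² is recorded.
`build_full_ld` bypasses shrinkage and windowing entirely and returns the
exact in-sample correlation matrix (used for validation against the
individual-level sampler).

## Gibbs sampler

Per iteration, in fixed genomic order (a seeded permutation is optional;
fixed order is the default so the summary-level and individual-level
chains can be compared draw-for-draw):

1. For each SNP j: rⱼ = r*ⱼ + (X′X)ⱼⱼβⱼ, where r* = X′y − X′Xβ is
   maintained incrementally. The component label is drawn from the
   integrated conditional — log L₁ = log π₁ and, for c > 1 with
   l<sub>jc</sub> = (X′X)ⱼⱼ + σ²ε/(γ_c σ²β),
   log L_c = log π_c + ½[log(σ²ε/(σ²ε + γ_c σ²β (X′X)ⱼⱼ)) +
   r²ⱼ γ_c σ²β/(σ²ε(σ²ε + γ_c σ²β (X′X)ⱼⱼ))]. A null draw sets βⱼ = 0;
   otherwise βⱼ ~ N(rⱼ/l<sub>jc</sub>, σ²ε/l<sub>jc</sub>). The update
   r* ← r* − (X′xⱼ)Δβⱼ touches only the SNP's stored LD window.
2. σ²β ~ scaled-inv-χ²(νβ + q, (Σ β²ⱼ/γ_{cⱼ} + νβS²β)/(νβ + q)) over the
   q SNPs in non-null components.
3. π ~ Dirichlet(α + component counts).
4. σ²ε ~ scaled-inv-χ²(νε + n̄, (SSE + νεS²ε)/(νε + n̄)) with
   SSE = y′y − β′(X′y + r*), floored at 10⁻¹² y′y.
5. h² = σ²g/(σ²g + σ²ε) with σ²g = β′(X′y − r*)/n̄ (= var(Xβ) for centred
   X), recorded every iteration; thinned post-burn-in states feed the
   posterior summaries.

Defaults: C = 4, γ = (0, 0.01, 0.1, 1), π₀ = (0.95, 0.02, 0.02, 0.01),
α = 1 per component, νβ = νε = 4, 10,000 iterations / 4,000 burn-in /
thinning 1-in-10. S²β is initialised so the implied genetic variance is
half the phenotypic variance under π₀ (S²β = ½·var(y) / (D̄/n̄ · p · Σ_c
π₀c γ_c)); S²ε at the phenotypic variance y′y/n̄. The chain is insensitive
to these at the default lengths (the recovery tests start from them).

Numerical choices: component selection uses one uniform draw against the
log-sum-exp-normalised cumulative weights; the spike is component 1 and
wins ties at the boundary by the ≤ comparison; all draws come from a
single seeded stream consumed in a fixed order, so runs are bit-
reproducible given the seed. A sampled h² > 1 or any non-finite state
aborts with a divergence error that points at summary-data QC, since that
is the usual cause. Effects are returned per allele; under the scaled
convention the model-scale means are divided by √(2f(1−f)) first.

The production path is a numba-compiled kernel; the categorical,
Dirichlet and scaled-inv-χ² draws are composed from uniform/normal/gamma/
chi-square primitives inside it. A pure-NumPy single-step API
(`GibbsState`, `sweep_snp`, `sample_sigma2_beta`, `sample_sigma2_eps`,
`sample_pi`, `compute_h2`) exposes the same conditionals for direct
testing. `rhs_check_every=k` makes the kernel recompute r* from scratch
every k iterations and report the maximum relative deviation of the
incremental vector (an internal-consistency check used by the tests).

## Individual-level BayesR

`BayesR` fits the same hierarchical model on (X, y) directly, maintaining
the residual vector w = y − Xβ on individuals so rⱼ = x′ⱼw + x′ⱼxⱼβⱼ uses
exact inner products. Its kernel is deliberately coded without sharing any
sampling code with the summary-level kernel (only the configuration
dataclasses are shared): with B and D computed exactly from the GWAS panel
the two samplers are the same Markov chain, and the test suite checks
their thinned draws agree to 1e−6 under a shared seed — the strongest
correctness anchor either sampler has.

## Synthetic data

`simulate_genotypes` draws, per block of `block_size` SNPs, two latent
AR(1, ρ) Gaussian haplotypes per individual, thresholds them at Φ⁻¹(MAF)
(MAF ~ Uniform(0.05, 0.5) by default) and sums to hard-call 0/1/2
genotypes. Blocks are independent and laid out as separate "chromosomes"
(1 SNP per 10 kb, constant 1 cM/Mb map), so a chromosome-wise LD build
sees every simulated correlation. Causal architectures follow the mixture
used genome-wide at full scale — 2,500 / 5,000 / 2,500 effects from
N(0, 0.01), N(0, 0.1), N(0, 1) — or a single normal (50,000 standard-
normal effects); `ArchitectureSpec.scaled_mixture(k)` keeps the 1:2:1
component ratio at k causal variants. Phenotypes are built on centred-
and-scaled genotypes with the residual variance set to var(g)(1−h²)/h²;
case-control status thresholds a standardised liability at Φ⁻¹(1−K).

What the generator does *not* emulate: minor-allele-frequency/LD
coupling, recombination-rate variation along the map (the simulated cM
scale is uniform, so the shrinkage factor mildly distorts the simulated
within-block LD rather than matching its decay), relatedness, population
stratification, imputation error, and any mismatch between the GWAS and
reference populations. Passing tests on these data therefore demonstrate
the *algorithmic* correctness and calibration of the samplers, not
robustness to the data pathologies of real meta-analysis summary
statistics.

## Summary-statistic QC

MAF threshold (default 0.01 on min(f, 1−f), strict), strand-ambiguous
(A/T, C/G) removal, region exclusion from 3-column interval files
(1-based inclusive start, half-open end), and a per-SNP sample-size band:
SNPs strictly below the `n_lower_pct` or strictly above the `n_upper_pct`
linear-interpolation percentile of the n distribution are dropped (the
full-scale protocol used 2.5 / 95). Because the band is defined relative
to the *current* n distribution, re-applying the filter can remove
further SNPs; the distribution-independent rules are idempotent. Allele
alignment to the LD reference flips b and f when (A1, A2) are swapped,
drops other pairings, and flags post-flip allele-frequency discrepancies
above 0.2 (warning by default, drop on request).

## Validation studies and problem sizes

`sbayesr.workflows` wires the full pipelines used by the tests and the
acceptance script:

* `recovery_study` — n = 5,000 GWAS + 1,000 held-out, p = 2,000, 200
  causal, h² = 0.5, exact in-sample LD, 3,000-iteration chains (desk-scale
  lengths; posterior means are stable well before this), 5 seeds. Checks
  h² recovery, held-out PRS R² and the calibration slope.
* `h2_bias_study` — the heritability twin of the genome-wide quantitative
  scenarios: n = 3,000 GWAS + 1,000 LD-reference, p = 2,000 (20 blocks of
  100, ρ = 0.9), 20 causal (1% density, mirroring 10,000 of ~1.1 M at
  full scale), h² ∈ {0.1, 0.2, 0.5}, shrunk chromosome-wise LD from the
  reference subsample, 5,000-iteration chains, 5 replicates per scenario.
* `liability_prevalence_study` — 100,000 standard-normal liabilities
  thresholded at prevalence 0.05.

## Limitations

* **Truncated-LD runaway at small n.** With the exact in-sample LD matrix
  the summary sampler matches the individual-level sampler draw-for-draw
  and recovers h² cleanly. With a chromosome-wise (windowed) reference,
  the between-window sample correlations of the GWAS panel — each
  O(1/√n) — are unmodelled; at desk-scale GWAS sizes (thousands of
  individuals, as in `h2_bias_study`) the residual signal they leave in
  r* lets ever more SNPs enter the smallest non-null component, σ²ε
  collapses and the h² estimate escalates towards 1. The effect weakens
  as the GWAS n grows and is negligible at biobank scale, which is the
  regime the method is designed for; `h2_bias_study` documents the
  sampler's behaviour in the unstable regime rather than a defect of the
  implementation — the equivalence and recovery studies are the
  correctness anchors. Practical mitigations at small n: use the GWAS
  panel itself (or a much larger panel) for LD, or full in-sample LD.
* The σ²ε conditional uses a single n̄; strongly heterogeneous per-SNP
  sample sizes (meta-analyses) are only partially absorbed by D̂, and no
  effective-sample-size correction for mixed-model summary statistics is
  implemented.
* The LD store keeps whole contiguous windows (including interior zeros)
  to make the sweep a single vector operation per SNP; memory scales with
  the window widths, not the nonzero count.
* No annotation-stratified priors, no multi-trait models, no imputation
  of missing summary records, no liftover/ID mapping.
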