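# Methods

This note records the statistical model, the algorithmic choices behind the
donor-compressed computations, the simulators' design, and the limits of what
the synthetic benchmarks can show.

## Linear mixed model and its compressed evaluation

Per gene and SNP the model is `y = αC + βx + ε`, `ε ~ MVN(0, σ²(I + λK))`
over cells. `K` is the cell-level GRM from standardized donor genotypes,
`K_d = ẐᵀẐ/n_SNP` at donor level (so its diagonal is ≈ 1 and λ is
interpretable as the donor-to-cell variance ratio; the `1/n_SNP` scale is a
convention, any rescaling is absorbed by λ). The cell-level `K` is the
donor-block expansion of `K_d` and is never materialized.

**Eigenstructure.** With `C = diag(cells per donor)`, the nonzero spectrum of
the cell-level GRM equals that of `M = C^{1/2} K_d C^{1/2}`; each eigenvector
is donor-block constant with per-cell value `v_r[d]/√c_d`. Eigendecomposition
is therefore `O(n_donor³)`. Whitening maps `y ↦ y − Σ_r u_r (1 −
(1+λs_r)^{-1/2}) (u_r·y)` and costs `O(n_donor² + n_cell)` per vector; it
preserves donor-block structure, so genotype rows stay compressed end to end.

**λ estimation.** Maximum likelihood under the null with σ² profiled
analytically, evaluated in the eigenbasis from cached cross-products (each λ
evaluation is `O(rank·n_cov²)`): a 100-point logarithmic grid on
`[1e-4, 1e4]` plus λ = 0, refined by golden-section search to 1e-4 in log-λ.
Genes with `λ̂ > 3` (donor share λ/(1+λ) > 75%) are excluded: such dominance
of donor-level variance over measurement noise usually signals batch
structure rather than biology. For the interaction test λ is re-estimated per
(gene, SNP) under the extended null, since that null contains
genotype-dependent covariates.

**Testing.** At fixed `λ̂` the LRT for β = 0 is monotone in the conditional
R² between whitened, covariate-residualized x and y. Its exact null law is
`Beta(1/2, dof₂/2)` with `dof₂ = n_cell − n_cov − 1`; the default reports the
`χ²₁` survival at `dof₂·R²`, which agrees with the Beta tail to a few percent
at the cell counts this package targets (tens of thousands) and degrades in
the extreme tail at small `dof₂` — the exact Beta route is one flag away.

**Numerical conventions.** Covariances divide by `n_cell` (population
convention; a uniform rescaling of test statistics). GRM eigenvalues within
−1e-8 of zero are clipped to zero; more negative values raise. Cis means
`|pos − TSS| ≤ 1 Mb` inclusive, same chromosome. Zero-variance (monomorphic)
SNPs are an error: QC must remove them. Allele flips `x ↦ 2−x` negate β and
leave R² and P unchanged, which the tests assert exactly.

## Quality control and normalization

QC iterates to a fixpoint, because removals cascade: cells with < 100
expressed genes or < 500 reads; genes expressed in < 10% of donors, < 100
cells, or < 2% of cells; donors with ≤ 5 cells. "Expressed in a donor" is
evaluated on the currently surviving cells. A per-state subset must keep
≥ 500 cells, 40 donors, 10,000 SNPs and 500 genes to be mapped.

Normalization is a deliberately simple stand-in with a pluggable seam:
`log2(1e6·c/lib + 1)` expression, standardized log-library-size and
log-gene-count technical covariates, and per-gene division by the residual
standard deviation after OLS on those covariates. It preserves the two
properties the mapper needs (log scale, library-size covariates). It is not
a minimum-mean-square-error estimator of log expression: its response to a
latent log-expression shift is nonlinear for sparsely measured genes (see
"measurement gain" below), and shrinkage-based normalizers behave better
there. Effect sizes are reported on this standardized scale.

## Simulators

The generative model is latent log expression
`y_i = α_i + Σ_j β_ji x_j + ε⁰ + ε¹` with `ε⁰ ~ N(0, σ₀²)` i.i.d. per cell
and `ε¹` donor-block multivariate normal with variance σ₁², pushed through a
per-cell softmax across genes and binomial read sampling at empirically
resampled per-cell totals (an exact-total multinomial variant is available;
the per-gene marginals coincide).

- `synthetic_base` builds an effect-free base population. Defaults: per-gene
  intercepts `N(0, 1.5²)`, totals `LogNormal(log 3000, 0.3²)`, σ₀ = 0.5, and
  donor-level σ₁ = 2.0. The elevated base donor variance stands in for the
  inter-individual heterogeneity (ancestry, environment, condition, batch)
  of real population data: downstream "true" effect sizes are *fitted* to
  the base, so the base's donor variance determines their spread, and a
  near-homogeneous base would make the benchmark truth pure estimation
  noise.
- `resample_and_permute` downsamples genes (autosomes), restricts SNPs to
  1 Mb cis windows and downsamples them, up/downsamples donors (resampled
  donors become new distinct donors) and cells (at least one per donor), and
  permutes each SNP's donor genotypes independently — MAF is preserved
  exactly, LD and population structure are destroyed.
- `simulate_eqtl_dataset` marks each in-window (SNP, gene) pair a cis-eQTL
  with probability 0.5, fits effect sizes by least squares of the base's
  normalized expression on the selected genotypes plus covariates, scales
  them by 1.5, and regenerates counts with fresh σ₀ = 0.5 / σ₁ = 1.0 noise
  (donor-level intraclass correlation 0.8).
- `simulate_celltype_dataset` carries a binary cell-state one-hot through the
  fits (technical covariates orthogonalized against it), gives each cis-eQTL
  a 50% chance of a state×genotype interaction effect, and replaces the
  pseudo-bulk intercept with the fitted covariate contributions.
- `simulate_calibration_null` mimics a given dataset at identical dimensions
  with unpermuted genotypes, cis effects scaled by 2.0, and no
  state-specific effects — every interaction P value from it is a null draw.
- `plant_regulation_dataset` wires a regulator gene to cis instruments and a
  trans target at a known 2SLS ratio γ, for end-to-end network benchmarks.
  The target receives compensating donor noise so regulator and target have
  matched variance and the normalized-scale estimand stays at γ. Its
  defaults (200 donors, 600 background SNPs, instrument effects ±0.6,
  σ₁ = 0.3) come from a power calculation: with few background SNPs the GRM
  is rank-degenerate and whitening suppresses exactly the instruments' own
  span (proximal contamination), so the SNP panel must be comfortably larger
  than the donor count, and instrument z-scores saturate at
  `√(n_donor·var(x)·β²/Σ_other β²var(x))` however strong the effects are.

**Units and measurement gain.** True effects are stored on the latent
natural-log scale. The analysis scale is per-gene linear in log2 CPM, but
the *measurement* is not linear in the latent value: for a gene with
expected count m per cell, the response of `E[ln(1e6·c/T + 1)]` to a unit
latent shift is `E[(c−m)·ln(1e6·c/T+1)]` under the count model — ≈ 1 for
well-measured genes but > 2 near m ≈ 1, because the transform jumps by
`ln(1e6/T)` between zero and one read. `SimTruth` tabulates this gain on an
(m, T) grid from the realized latent abundances (times the `1−p` softmax
self-share) and `on_analysis_scale` applies it together with the `ln 2 ×`
standardization factor. This is a property of the generative model, computed
without reference to mapper output; without it a perfectly calibrated mapper
would appear biased upward on sparse genes, since it correctly estimates the
realized effect on the measured scale.

## Calibration

The Beta-null model `p ~ Beta(e^{α₀+α₁x}, e^{β₀+β₁x})` is fitted to null P
values by full-batch gradient ascent on the summed log likelihood (digamma
gradients) from the origin, default learning rate 1e-6 for 20,000 epochs;
P values below 1e-300 are clipped up first, and x is standardized with the
constants stored for later application. Any optimizer reaching the same
maximum is acceptable — the tests verify likelihood increase, recovery of
Beta(1,1) on uniform input and of known Beta shapes, and the probability
integral transform (calibrated draws from the model's own null are uniform).
Calibration is the Beta CDF at the observed p with the entry's own x, hence
monotone in p at fixed x. Candidate parameters are ranked by KS distance to
uniform, then Storey π₁, then name. π₀ is estimated on the λ-grid
0.05…0.95 with a cubic extrapolation to λ → 1, clipped to [0, 1].

## Network inference

Trans scans keep only P < 1e-4 for tractability, so BH Q values are computed
on the sub-cutoff head with global ranks and the full test count; every
omitted step-up term exceeds the cutoff, so this equals full BH wherever
q ≤ cutoff (all decisions happen there) and is conservative above it. Cis
and trans Q values are computed separately. Instruments must have exactly one
cis gene at Q < 0.1 with every other cis association at raw P > 0.1, and
edges need ≥ 2 instruments whose donor genotype vectors are distinct up to
allele flip. Strength is the median per-instrument trans/cis ratio;
relative variability `(max−min)/(2·max|e|)` is 0/0.5/1 in the canonical
cases (identical estimates; one null instrument; equal-magnitude opposite
signs). Gene names containing `-`, `.`, `_` are excluded upstream.

## What the synthetic benchmarks do and do not show

The simulators reproduce donor-block covariance, count sparsity,
library-size variation, MAF spectra, and known effect sizes — the features
the statistics act on. They do not contain LD (genotypes are permuted by
design), realistic population structure, cell-type hierarchies beyond a
binary label, doublets or ambient RNA, or a shrinkage-based (MMSE)
measurement model of log expression. Consequently: passing tests demonstrate algebraic
exactness of the compressed computations, correct type-I error under the
model's own null, and unbiased recovery of effects the model can represent;
they say nothing about robustness to LD leakage into trans signals (the
instrument-uniqueness and pleiotropy filters address only its grossest
form), and effect-size recovery for sparsely measured genes depends on the
measurement-gain correction described above.

## Problem sizes

Default test and benchmark dimensions (e.g., 100 donors × 20,000 cells with
~100,000 null tests; 400 genes × 1,000 SNPs with ~2,000 planted cis pairs)
were chosen so every statistical check retains clear power while the whole
suite runs on a single CPU in minutes; the compressed algebra makes the
donor dimension, not the cell count, the binding cost.
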