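# Methods

This note documents the statistical model, the estimators and their
numerical details, the synthetic-data generators, and the design choices
made where several constructions were defensible. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Nested variance components

The trait model is purely nested and fully random:

    y_ijkl = μ + r_i + p_ij + f_ijk + e_ijkl,

with regions *r*, populations-within-regions *p*, selfed seed
families-within-populations *f* and residuals *e* independent zero-mean
Gaussians of variances (V_R, V_P, V_F, V_E). Region is treated as random
so that its percentage contribution to total variance is defined; the
regional *mean* test is a separate fixed-effect F-test (below).

Two estimators are implemented:

- **REML** (`method="reml"`, the default for variance-component tables):
  the restricted likelihood is maximised directly over the variance
  vector with an analytic gradient (the intercept-only fixed design makes
  the REML projection a rank-one correction to V⁻¹, so every term is a
  Cholesky solve). Components are bounded at zero, so boundary estimates
  come out clamped by construction. Optimization is L-BFGS-B on
  variances scaled by the sample variance, started from the clamped
  moment estimates, with a flat-start retry; a persistent failure falls
  back to clamped moment estimates and clears the convergence flag.
- **Expected mean squares** (`method="ems"`): the closed-form
  Henderson/method-of-moments solution of the unbalanced nested ANOVA.
  The triangular moment equations are solved from the residual stratum
  upward using the general unbalanced coefficients (sums of squared cell
  counts within each stratum), so balanced and unbalanced designs are
  handled by one code path. Raw (possibly negative) solutions are kept
  alongside the zero-clamped ones.

On balanced designs with interior estimates the two coincide; the test
suite asserts agreement to 1e-6 against an independently hand-coded
balanced oracle.

**Broad-sense heritability** is H² = V_F/(V_F + V_E). With selfed seed
families the among-family variance is a total genetic variance, so no
narrow-sense interpretation is offered. The bootstrap CI resamples
families with replacement *within populations*, each family carrying all
its replicates, refits the components per resample with the closed-form
estimator (a thousand refits stay inexpensive), and takes the percentile
interval. A resample with zero family and residual variance contributes
no H² value; if every resample is degenerate the CI is an error.
H² is invariant under affine rescaling of the trait; CV_G = 100·√V_F/x̄
is invariant under multiplicative rescaling only — a shifted trait scale
(e.g. log-transformed volumes) changes CV_G, which is why CV_G values
for log-scale traits should be interpreted on that scale.

**Regional F-test.** Populations, not plants, are the replicates for a
regional contrast: F = MS(region)/MS(population-within-region) with
(n_regions − 1, n_pops − n_regions) degrees of freedom — (1, 8) for ten
populations in two regions. On balanced designs this ratio is exactly
F-distributed under the regional null; the test suite checks the 5%
size empirically on 2000 simulated null datasets.

## Pairwise divergence

**Q_ST** for a population pair is V_P/(V_P + 2·V_F) from a two-level
nested ANOVA (population, family, residual) on that pair's data, with
components clamped at zero first; if both components vanish Q_ST is
defined as 0. The moment estimator is the default for pair matrices
(the two-level fits are closed-form and the all-pairs matrix needs
hundreds of them); REML is available per pair. No selfing correction is
applied to the denominator: the among-selfed-family variance is used as
the additive-variance term exactly as printed in the source formula.

A caveat the test suite documents quantitatively: with only two
populations the V_P estimate has a single degree of freedom, so the
clamped ratio is noisy and, by Jensen's inequality, biased downward for
small true Q_ST. At (V_P, V_F) = (0.02, 0.02) with 30 families × 6
replicates the mean estimate over 500 simulations is ≈ 0.24 against a
generative ratio of 1/3, even though the component estimates themselves
are unbiased to within 1%. This is a property of the estimator, not of
the implementation; the within-region medians of exactly 0 seen in such
analyses are the same clamping in action.

**F_ST** is Weir & Cockerham's θ for multiallelic codominant loci:
per-locus, per-allele components a (among populations), b (among
individuals within populations) and c (within individuals) from sample
sizes, allele frequencies and observed heterozygote frequencies, with
θ = Σa / Σ(a+b+c) summed over alleles and loci (ratio-of-sums, the
recommended multiallelic weighting; per-locus averaging is not offered).
Missing calls drop out of that locus's counts only; monomorphic loci
contribute identically zero. **R_ST** decomposes allele sizes by a
one-way ANOVA over populations per locus (each allele copy one
observation, unbalanced-design n₀ coefficient), pools components over
loci by summation, and reports among/(among + within). It is invariant
under affine maps of allele size, as a variance ratio must be.

## Mantel machinery

The Mantel statistic is the Pearson correlation of the n(n−1)/2
lower-triangle entries; Spearman first replaces the triangle entries by
midranks (written back symmetrically, so permutations transport ranks
correctly even with heavy ties such as a 0/1 indicator). The null
applies the same relabelling to rows and columns of X, vectorized over
all sampled permutations. One-sided (greater) p-values with +1
smoothing are the default, because the scientific hypothesis —
between-region divergence exceeds within-region divergence — is
directional; `tail="less"`/`"two-sided"` are exposed. When n! ≤ 5040
the full permutation group is enumerated instead and the p-value is
exact (no smoothing term). Pairs missing in either matrix are removed
pairwise from every correlation.

The partial Mantel statistic is the first-order partial correlation
r_XY·Z on (optionally midranked) triangles; permutations relabel X only,
recomputing r_XY and r_XZ. Two permutation schemes are provided:

- `permutation="raw"` (default): permutes X itself. Simulation in the
  test suite shows this holds close to its nominal 5% size for moderate
  confounder correlation (≈ 6% at r_XZ ≈ 0.6) but grows liberal as
  r_XZ → 1 (8–10% at r_XZ ≥ 0.85): the permutation null ignores the
  fixed observed X–Z alignment. The calibration test therefore uses a
  moderately confounded construction, which is also the regime where a
  partial Mantel analysis is scientifically sensible — when trait and
  neutral matrices are nearly collinear no permutation scheme can
  separate them.
- `permutation="residual"`: permutes the triangle-wise residuals of X on
  Z with the fit added back, better calibrated under strong confounding.

BH-FDR adjustment is delegated to `statsmodels.stats.multitest` behind a
validating wrapper; an independent step-up implementation in the test
suite checks it property-wise. Geographic distances are great-circle
kilometres (Earth radius 6371.0 km) via scikit-learn's haversine kernel.

## Environmental analysis

Each variable is shifted so its minimum equals one, log-transformed
(natural log; the base washes out in the final z-score), then
standardized to mean 0, variance 1 (sample variance, ddof = 1). The
shift must precede the log — non-positive raw values would otherwise be
unloggable — and the observed minimum maps to log 1 = 0. Constant
variables are dropped with a warning. PCA is an eigendecomposition of
the correlation matrix (covariance mode available), components ordered
by eigenvalue, each unit-norm loading column signed so its
largest-magnitude entry is positive, eigenvalues below 1e-10 treated as
null and dropped (26 variables on 10 populations yield at most 9
informative axes); variance fractions stay relative to the total
variance of all variables. Environmental distance is the equal-weight
Euclidean distance on the standardized table; PC-axis distance is
|score_i − score_j| on one axis (by convention axis 2, the regional
contrast in this design).

## Synthetic data

The generators define the study conditions for every simulation-based
check:

- **Design**: 2 regions with 3 + 7 populations; families per population
  drawn uniformly from 8–14 and replicates per family from 3–6 (the
  default totals ≈ 500 plants, matching a design of 10–20 collected
  genotypes per population thinned by germination failure); multiple
  traits share one plant design but draw effects independently.
- **Trait parameters**: per-trait variance components equal to the
  published nested-ANOVA estimates for the five traits (leaf width,
  rosette diameter, rosette height, log rosette volume, water-use
  efficiency), grand means equal to the published EAST means, and the
  regional contrast carried as a *fixed* mean shift equal to the
  published WEST−EAST difference with V_R = 0 in the generator. The
  fixed-shift parameterization was chosen over a random region effect
  because a two-level random draw makes the realized regional contrast
  of any single dataset essentially arbitrary; the implied regional
  variance (shift²/2) matches the published V_R estimates to within
  their own uncertainty for all five traits.
- **Genotypes**: Balding–Nichols. Per locus, an ancestral frequency
  vector over 6 alleles is drawn from a flat Dirichlet (rejecting
  near-fixed vectors); population frequencies are
  Dirichlet(p_anc·(1−F)/F), with F either a shared value (default 0.4,
  anchoring the estimator to the published pairwise F_ST medians of
  ≈ 0.37–0.41) or per-population values for heterogeneous drift.
  Genotypes are drawn with the equilibrium inbreeding F_IS = s/(2−s) of
  a selfing rate s (default 0.9; the species is highly selfing): an
  individual is autozygous with probability F_IS. Allele labels are
  fragment sizes on a lattice (base 100, step 2). No stepwise-mutation
  or coalescent process is modelled, so R_ST has no mutational advantage
  here — the generator exercises the estimators, not microsatellite
  evolution.
- **Environment**: 26 variables (altitude, BIO1–BIO11 temperature,
  BIO12–BIO19 precipitation, five topographic variables, stream
  distance) as block-equicorrelated Gaussians (within-block ρ = 0.6,
  zero across blocks), a regional mean shift on the precipitation block
  (pipeline default 2 SD on the WEST analogue), exponentiated so all
  values are positive and the log-transform stage is genuinely
  exercised. With ρ = 0.6 the eight precipitation variables are heavily
  redundant, so a 2 SD shift is detected by the region-environment
  Mantel test in roughly 60% of seeds and a 3 SD shift in ≈ 90%; the
  generator-level detection test uses the 3 SD setting.
- **Coordinates**: two clusters ≈ 100 km apart with ≈ 15 km within-region
  scatter, placed at realistic Rocky-Mountain latitudes.

What passing tests on these synthetics do *not* show: robustness to
non-Gaussian traits, genotyping error, null alleles, linked loci,
spatially autocorrelated environments, or family structure departing
from pure selfing. The generators are deliberately the assumed model of
the estimators (plus the unbalancedness knobs), so the simulation checks
validate estimator implementation and calibration, not model robustness.

## Problem sizes in the checks

The acceptance-style checks use: 500 seeds for REML component recovery
(2×5×10×4 balanced design) and for pairwise-Q_ST recovery; 100
replicates for θ calibration (10 pops × 20 individuals × 13 loci); 2000
null datasets each for Mantel and regional-F size; 1000 datasets for the
partial-Mantel confounding check; 500 replicates × 1000 resamples for
bootstrap coverage (one population, 50 families × 6 replicates, true
H² = 0.6); and 100 seeds each for the end-to-end power and global-null
studies. The end-to-end studies run the pipeline with the moment
estimator for variance components, 499 permutations and 30 bootstrap
resamples per trait — problem sizes chosen so the whole battery runs in
a few minutes on one core while keeping every Monte-Carlo standard error
well inside the asserted bands. The end-to-end power construction gives
divergent traits fixed regional shifts of 2 within-population phenotypic
SD ( √(V_F+V_E) ), a separation large enough that a pairwise design
with only three populations in one region can detect it reliably.

## Known limitations

- Pairwise Q_ST with two populations is intrinsically high-variance and
  downward-biased as a ratio (see above); medians and Mantel-style rank
  analyses of the matrix are the intended use, not individual pair
  values.
- The raw-permutation partial Mantel is liberal under strong
  trait-neutral collinearity; use the residual scheme there.
- GenePop population labels are recovered from shared `LABEL_` prefixes
  of individual ids (falling back to Pop1, Pop2, …): the format itself
  has no population-name field.
- The REML fit builds dense covariance blocks, fine for hundreds of
  plants per fit but not for designs orders of magnitude larger.
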