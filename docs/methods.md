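# Methods

## Data model and chronology conventions

A lens chronology is an ordered stack of layers indexed outward-in
(index 1 = the unhardened outermost layer, the core = the innermost
layer that could be delaminated). Within one fish and eye, diameter must
strictly decrease with index; ties are rejected as input errors because
two layers cannot share a diameter in a physically dissected lens. If a
lens never delaminated to a recognizable core, the innermost dissected
layer is the core by definition. Diameters are carried at full floating
precision internally; rounding (0.01 mm for diameters, 0.01 ‰ for
isotope values, two decimals for derived metrics) happens only at the
report layer.

Left-eye replicates and true duplicates enter only the precision QC and
are excluded from model fitting; the primary right-eye series is the
analysis set. Including them would double-count layers in a model whose
grouping structure assumes one series per fish. A left-eye replicate
pairs to the right-eye layer with the same index, falling back to the
nearest-diameter layer when the diameters disagree by more than 0.2 mm —
the threshold is a package choice reflecting measurement precision, not
a measured quantity.

## Lens geometry

The intact lens diameter (LD) and first-hard-layer diameter (HD) scale
linearly; `fit_geometry_regression` fits LD on HD by OLS (statsmodels)
with at least 3 pairs and reports slope/intercept standard errors from
the residual variance, plus the mean and SD of the per-pair HD:LD
ratio. `predict_ld` interpolates LD for damaged lenses; a missing
interior layer diameter is the arithmetic midpoint of its neighbours,
which preserves strict monotonicity whenever the neighbours are
strictly ordered.

## Hierarchical model

Per lake: y_ij = α_i + β_i x_ij + ε_ij with ε ~ N(0, σ²), random
intercepts α_i ~ N(μ_α, σ_α²) and slopes β_i ~ N(μ_β, σ_β²), priors
μ_α ~ N(6 ‰, variance 25) and μ_β ~ N(0 ‰/mm, variance 6.25). The
intercept prior centre of 6 ‰ is a plausible early-life δ15N; the
predictor is deliberately left uncentered so the intercept reads as the
expected δ15N at zero lens diameter, i.e. the earliest-life trophic
level. Cores (maternal yolk signal) and outermost layers (across the
HD→LD diameter gap) are excluded before fitting.

Variance components default to inverse-gamma(0.001, 0.001) hyperpriors
on each variance — the conjugate vague choice idiomatic to Gibbs-based
samplers. A half-normal(scale 5 ‰) alternative on each SD is available
(`variance_hyperprior="half_normal"`) and is updated by univariate
slice sampling; it serves as a sensitivity check since vague
inverse-gammas can behave poorly when a variance is near zero. Any
component can instead be fixed; fixing σ_α = σ_β = 0 collapses the
model to a single-level Bayesian regression whose posterior has a
bivariate-normal closed form — the test suite uses this as an
independent oracle for the sampler.

### Sampler

A blocked Gibbs sampler, vectorized across chains: per fish,
(α_i, β_i) are drawn jointly from their bivariate-normal full
conditional (blocking matters because intercept and slope are strongly
correlated with an uncentered predictor); population means from
conjugate normals; variances from inverse-gamma full conditionals (or
slice steps). With zero observations every full conditional reduces to
its prior, so the no-data posterior reproduces the prior exactly — a
property the tests exploit. Defaults follow the production settings:
3 chains × 25 000 iterations, 10 000 burn-in, thinning 1. Chain *k*
starts the population means at prior mean ± ⌈k/2⌉ prior SDs
(alternating sign) and the variances at sample-variance-based guesses
spread over roughly a factor of four, so the Gelman–Rubin diagnostic
starts from genuinely dispersed points. All randomness flows from a
single integer seed; identical (data, spec) reproduce identical draws.

Numerical guards: gamma draws that underflow to zero under the vague
hyperprior (possible only in prior-only runs) are floored at 1e-290 so
every stored draw is finite; the 2×2 Cholesky clamps a negatively
rounded Schur complement at zero; non-finite population draws abort the
run with the iteration number.

### Diagnostics and summaries

R̂ is the classic Gelman–Rubin potential scale reduction factor
(between/within-chain variance, no rank normalization or chain
splitting), matching the tooling era of the analyses this package
supports; identical constant chains return R̂ = 1 with a warning rather
than 0/0. Effective sample size is delegated to ArviZ. The 95% HPDI is
the shortest contiguous interval containing ⌈0.95 n⌉ sorted pooled
draws, ties broken toward the lower start; chains are pooled for
moments and HPDI.

## Posterior overlap

Population similarity of a marginal posterior is the overlap
coefficient Δ = ∫ min(f̂_a, f̂_b): Gaussian KDE per sample set with the
Silverman rule-of-thumb bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5),
both densities evaluated on one shared 512-point grid spanning the
union of sample ranges padded by 4 maximum bandwidths, integrated by
the trapezoid rule and clipped to [0, 1]. Using a shared grid makes the
coefficient exactly symmetric. For equal-variance normals the
population value is 2Φ(−|Δμ|/2σ), which the tests verify at n = 10⁵ to
±0.02. Overlap is stored as a proportion; percent formatting is a
report-layer concern. Bandwidths and grid bounds are recorded in every
result for reproducibility, since KDE-variant choices shift overlap at
the few-percent level.

## Trophic conversions

δ15N enriches by one trophic discrimination factor (TDF, default
3.4 ‰) per trophic level, so Δδ15N / TDF is a trophic-level change. A
regression slope (‰/mm) integrates over the average core-to-HD span
0.67 → 2.96 mm: TL change = β·2.29/3.4. Lifetime Δ per individual is
defined as the within-fish **range** (max − min) of the isotope over
all layers including core and outermost — interlayer variation can
dominate a weak trend, and a range is reorder-invariant and
nonnegative; a core-to-outermost difference would instead be signed and
trend-dependent. Baseline summaries report per lake × habitat ×
isotope mean and SD, with δ13C means additionally corrected by +0.4 ‰
for consumption-step discrimination when compared against consumers.

## Synthetic generator

`generate_lake` emulates: per-fish intercepts/slopes from the
population normals; core and HD diameters from lake-level normals
(defaults 0.67 ± 0.08 mm and 2.96 ± 0.25 mm); hard layers evenly spaced
between core and HD with bounded uniform jitter (bounded so strict
monotonicity is guaranteed, with the first hard layer pinned exactly at
HD); the outermost layer at LD = HD / 0.52; δ15N linear in diameter
plus N(0, σ) residual noise; a +1.5 ‰ maternal offset added to the core
only. δ13C follows a lake-mean drift from the pelagic toward the
littoral side with AR(1)(φ = 0.6) inter-layer noise clipped between the
two baseline means — invented scaffolding for chronology plots, of
which only boundedness is asserted. Baseline samples are i.i.d. normal
per habitat/isotope from the preset means/SDs.

The four presets carry the reported per-lake population slopes and
intercepts (Floods 1.01/7.25 with 4 fish; Long 0.42/7.48 with 3;
Wadleigh 0.05/7.17 with 4; Gardner −1.31/13.01 with 2 and fewer layers
per lens) and the reported littoral/pelagic baseline means ± SDs. The
variance components are **not** reported anywhere and are package
choices made once: σ_fish_intercept = 0.5 ‰, σ_fish_slope = 0.2 ‰/mm,
σ_resid = 0.3 ‰ — residual scatter a little above the ~0.1–0.2 ‰
analytical precision of duplicate layers, leaving room for biological
interlayer variation; all overridable per preset. Geometry-pair noise
(0.42 mm) was set so the expected r² of the LD-on-HD fit is ≈ 0.7 at
n = 18, matching the strength of the observed relationship.

What the generator does **not** emulate: mechanistic lens growth or
isotope turnover, seasonal/episodic diet switches, age structure,
species mixtures within a lake, or measurement failures (missing
diameters, damaged lenses). Passing parameter-recovery tests therefore
shows the inference machinery is correct under the model's own
assumptions, not that the linear model is adequate for any particular
real population (the Gardner preset's negative slope, for instance, is
reproduced but a linear fit may be a poor description of such data).

## Problem sizes used in the checks

Recovery/calibration runs use 50 simulated datasets per preset at
4 fish × 12 layers (40 regression layers) with 3 chains × 3000
iterations (1000 burn-in) — chain lengths at which HPDI coverage is
stable while a 100-fit calibration study stays quick on a laptop.
Convergence and closed-form checks use the full production settings
(3 × 25 000, 10 000 burn-in). Overlap and KDE checks use 10⁵ draws
where a closed form is compared, as the estimator's own bias at
Silverman bandwidths is of order 0.01 there.

## Known limitations

- The Gibbs sampler assumes normal likelihood and normal random
  effects; no robust (t) alternative is provided.
- Vague inverse-gamma hyperpriors with very few fish (n = 2) let the
  between-fish variances make brief excursions to large values; R̂
  stays ≤ 1.01 at the default chain lengths, but the half-normal
  alternative is the safer choice for new data with tiny n.
- Overlap is computed on marginal posteriors only; a joint
  slope–intercept overlap would require a bivariate density estimate.
- The CLI's `fit` recomputes nothing about geometry interpolation; LD
  repair is a library-level operation (`predict_ld`) left to the user's
  preprocessing, since damaged-lens bookkeeping is dataset-specific.
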