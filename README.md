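# isolens

Eye-lens stable-isotope chronology analysis for lake fishes.

Fish eye lenses grow by accreting concentric protein layers that are
metabolically inert once hardened, so the δ13C and δ15N values of
successive layers inside one lens form a lifetime record of that fish's
basal resource use (littoral vs pelagic carbon) and trophic position.
`isolens` is aimed at trophic ecologists working with such chronologies
in data-limited salmonid populations: it assembles and validates
per-fish layer tables, fits per-population Bayesian hierarchical linear
regressions of δ15N on lens diameter, compares populations by the
overlap of their posterior densities, and converts isotope changes into
trophic-level changes.

## The model

For lake *k*, layer *j* of fish *i* (response y = δ15N in ‰, predictor
x = lens diameter in mm, cores and outermost layers excluded):

    y_ij = α_i + β_i x_ij + ε_ij        ε_ij ~ N(0, σ²)
    α_i ~ N(μ_α, σ_α²)                  β_i ~ N(μ_β, σ_β²)
    μ_α ~ N(6, 1/0.04)                  μ_β ~ N(0, 1/0.16)

with inverse-gamma(0.001, 0.001) hyperpriors on the variances. The
hierarchy accounts for repeated measures within fish; posteriors are
drawn by a blocked Gibbs sampler (3 chains × 25 000 iterations, 10 000
burn-in) and summarized as mean, SD, and 95% highest-posterior-density
intervals, with classic Gelman–Rubin R̂ per parameter. Between-lake
similarity of a parameter is the overlap coefficient
Δ = ∫ min(f̂_a, f̂_b) of the two Gaussian-KDE posterior densities
(Silverman bandwidth). A slope converts to a trophic-level change as
β · (2.96 − 0.67) mm / 3.4 ‰, i.e. the slope integrated over the
average core-to-first-hard-layer diameter span divided by the δ15N
trophic discrimination factor.

A synthetic-data generator (`isolens.synthetic`) simulates lakes with
known population slopes/intercepts, per-fish random effects, maternal
core δ15N offsets, realistic lens geometry (core ≈ 0.67 mm, first hard
layer ≈ 2.96 mm, HD:LD ≈ 0.52), and littoral/pelagic baseline samples,
so the whole pipeline can be validated by parameter recovery.

## Worked example

```bash
isolens run --preset Floods --preset Long --preset Wadleigh --preset Gardner \
    --seed 7 --out demo/
```

This simulates the four lake presets, fits each population, and writes
`summary.csv`, `overlap.csv`, `metrics.csv`, per-lake draws, and a
`manifest.json` reporting e.g. `"rhat_max": 1.0012` (all chains
converged). The population rows of `summary.csv` for seed 7:

```
    lake parameter  n_fish  n_layers      mean       sd  hpdi_low  hpdi_high
  Floods   mu_beta       4        39  1.008590 0.183961  0.666211   1.359480
    Long   mu_beta       3        34  0.229130 0.421060 -0.554821   1.055030
Wadleigh   mu_beta       4        40  0.166099 0.147203 -0.126903   0.439766
 Gardner   mu_beta       2        13 -1.561490 0.420917 -2.241740  -0.860712
```

The fitted Floods slope (1.01 ‰/mm, HPDI 0.67–1.36) recovers that
preset's generating truth of 1.01: δ15N rises steeply with lens
diameter, the signature of a population that shifts toward piscivory
through life. Wadleigh's near-zero slope is a population planktivorous
at all sizes, and Gardner (2 fish, 13 usable layers) shows the widest
intervals. In `overlap.csv`, the slope posteriors of the two shallow-
sloped lakes overlap most (Long–Wadleigh 0.633 here) while steep-vs-flat
pairs overlap by ≤ 0.11 — less overlap is stronger evidence the
populations differ. In Python:

```python
from isolens.trophic import slope_tl_change
slope_tl_change(1.01)   # 0.68 trophic levels gained core -> first hard layer
```

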