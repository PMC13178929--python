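"""Bayesian hierarchical linear regression of δ15N on lens diameter.

Model, per lake: layer j of fish i has

    y_ij = alpha_i + beta_i * x_ij + eps_ij,   eps_ij ~ N(0, sigma_resid^2)
    alpha_i ~ N(mu_alpha, sigma_alpha^2)
    beta_i  ~ N(mu_beta,  sigma_beta^2)

with weakly informative priors on the population means — mu_beta ~
N(0, 1/0.16) (slope) and mu_alpha ~ N(6, 1/0.04) (intercept; 6 permil is
an early-life δ15N level) — and, by default, inverse-gamma(0.001, 0.001)
hyperpriors on each variance component. The predictor (lens diameter,
mm) is left uncentered so the intercept reads as expected δ15N at zero
diameter, i.e. the earliest-life trophic level.

Inference is a blocked Gibbs sampler: (alpha_i, beta_i) are drawn
jointly per fish from their bivariate-normal full conditional, the
population means from conjugate normals, and the variances from their
inverse-gamma full conditionals (or by slice sampling under the
half-normal hyperprior alternative). Chains are initialized at
dispersed points; all randomness flows from the spec seed.

Variance components may be fixed instead of sampled; fixing
sigma_alpha = sigma_beta = 0 collapses the hierarchy to a single-level
regression whose posterior has a conjugate closed form, which the test
suite uses as an independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from isolens.lens_data import LayerRecord

__all__ = [
    "ModelSpec",
    "ModelData",
    "PosteriorDraws",
    "build_model_data",
    "fit_population",
    "gelman_rubin",
    "hpdi",
    "summarize",
    "effective_sample_size",
]


@dataclass(frozen=True)
class ModelSpec:
    """Priors, hyperpriors and MCMC settings for one population fit.

    Precisions follow the field convention (1/variance): the slope prior
    N(0, precision 0.16) has variance 6.25, the intercept prior
    N(6, precision 0.04) variance 25. ``sigma_alpha``/``sigma_beta``/
    ``sigma_resid`` may each be fixed to a nonnegative SD; ``None`` means
    the component is sampled under ``variance_hyperprior``.
    """

    prior_slope_mean: float = 0.0
    prior_slope_precision: float = 0.16
    prior_intercept_mean: float = 6.0
    prior_intercept_precision: float = 0.04
    variance_hyperprior: str = "inverse_gamma"  # or "half_normal"
    ig_shape: float = 0.001
    ig_rate: float = 0.001
    half_normal_scale: float = 5.0
    sigma_alpha: float | None = None
    sigma_beta: float | None = None
    sigma_resid: float | None = None
    n_chains: int = 3
    n_iter: int = 25000
    n_burnin: int = 10000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_slope_precision <= 0 or self.prior_intercept_precision <= 0:
            raise ValueError("prior precisions must be positive")
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for R-hat")
        if self.variance_hyperprior not in ("inverse_gamma", "half_normal"):
            raise ValueError(
                "variance_hyperprior must be 'inverse_gamma' or 'half_normal'"
            )
        for s in (self.sigma_alpha, self.sigma_beta, self.sigma_resid):
            if s is not None and s < 0:
                raise ValueError("fixed sigmas must be >= 0")
        if self.sigma_resid is not None and self.sigma_resid == 0:
            raise ValueError("sigma_resid cannot be fixed to 0 (degenerate likelihood)")


@dataclass
class ModelData:
    """Grouped regression data for one lake: y = δ15N, x = diameter (mm)."""

    lake: str
    fish_ids: list[str]
    x: np.ndarray  # (n_obs,)
    y: np.ndarray  # (n_obs,)
    group: np.ndarray  # (n_obs,) int index into fish_ids

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    @property
    def n_layers(self) -> int:
        return int(self.x.size)


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws, shaped (n_chains, n_kept) per parameter.

    Parameters: ``mu_alpha``, ``mu_beta``, ``sigma_alpha``, ``sigma_beta``,
    ``sigma_resid``, and per-fish ``alpha[<fish>]``/``beta[<fish>]``.
    """

    lake: str
    params: dict[str, np.ndarray]
    spec: ModelSpec
    n_fish: int
    n_layers: int

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.params[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iter, parameter, value) long format."""
        rows = []
        for name, arr in self.params.items():
            c, n = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), n),
                        "iter": np.tile(np.arange(n), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def build_model_data(layers: Sequence[LayerRecord]) -> ModelData:
    """Assemble grouped regression data from filtered layer records.

    Input must already have core/outermost layers removed (see
    :func:`isolens.lens_data.filter_regression_layers`). A single-fish
    input is allowed with a warning; empty input is an error.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("no layers: cannot build model data")
    bad = [r for r in layers if r.role in ("core", "outermost")]
    if bad:
        raise ValueError(
            f"{len(bad)} core/outermost layers present: filter before modelling"
        )
    lakes = {r.lake for r in layers}
    if len(lakes) > 1:
        raise ValueError(f"layers span multiple lakes {sorted(lakes)}: fit per lake")
    fish_ids = sorted({r.fish_id for r in layers})
    if len(fish_ids) < 2:
        warnings.warn(
            "only one fish in this lake: between-fish variances are "
            "informed solely by the hyperprior",
            stacklevel=2,
        )
    index = {f: i for i, f in enumerate(fish_ids)}
    x = np.array([r.diameter_mm for r in layers], dtype=float)
    y = np.array([r.d15N for r in layers], dtype=float)
    group = np.array([index[r.fish_id] for r in layers], dtype=int)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite diameter or δ15N in model data")
    return ModelData(lake=lakes.pop(), fish_ids=fish_ids, x=x, y=y, group=group)


def empty_model_data(lake: str = "none") -> ModelData:
    """Dataset with zero observations (posterior = prior)."""
    return ModelData(
        lake=lake,
        fish_ids=[],
        x=np.empty(0),
        y=np.empty(0),
        group=np.empty(0, dtype=int),
    )


# ---------------------------------------------------------------------------
# Gibbs sampler

def _inv_gamma(rng: np.random.Generator, shape, rate):
    """Draw elementwise from InverseGamma(shape, rate).

    Gamma draws can underflow to 0 for the tiny shapes of a vague
    hyperprior sampled with no data; those are floored to keep every
    draw finite.
    """
    g = rng.gamma(shape, 1.0 / np.asarray(rate, dtype=float))
    return 1.0 / np.maximum(g, 1e-290)


def _slice_sample_sd(rng, sd0, ss, k, scale, w=1.0, max_steps=50):
    """One slice-sampling update of an SD with half-normal(scale) prior.

    Target (up to a constant): p(s) ∝ s^-k exp(-ss/(2 s^2)) exp(-s^2/(2 scale^2)),
    the conditional of an SD given k centred normal deviates with summed
    squares ``ss``. Vectorized over chains.
    """
    sd0 = np.asarray(sd0, dtype=float)

    def logp(s):
        with np.errstate(divide="ignore"):
            out = -k * np.log(s) - ss / (2.0 * s**2) - s**2 / (2.0 * scale**2)
        return np.where(s > 0, out, -np.inf)

    y = logp(sd0) + np.log(rng.uniform(size=sd0.shape))
    lo = np.maximum(sd0 - w * rng.uniform(size=sd0.shape), 1e-12)
    hi = lo + w
    for _ in range(max_steps):  # step out
        grow_lo = logp(lo) > y
        grow_hi = logp(hi) > y
        if not (grow_lo.any() or grow_hi.any()):
            break
        lo = np.where(grow_lo, np.maximum(lo - w, 1e-12), lo)
        hi = np.where(grow_hi, hi + w, hi)
    new = sd0.copy()
    todo = np.ones(sd0.shape, dtype=bool)
    for _ in range(max_steps):  # shrink
        prop = rng.uniform(lo, hi)
        ok = todo & (logp(prop) > y)
        new = np.where(ok, prop, new)
        todo &= ~ok
        if not todo.any():
            break
        above = prop > sd0
        hi = np.where(todo & above, prop, hi)
        lo = np.where(todo & ~above, prop, lo)
    return new


def fit_population(data: ModelData, spec: ModelSpec) -> PosteriorDraws:
    """Run the blocked Gibbs sampler and return post-burn-in draws.

    Deterministic given (data, spec.seed). Raises if any draw goes
    non-finite, reporting the iteration at which it happened.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.n_chains
    F = data.n_fish
    x, y, g = data.x, data.y, data.group

    # prior (variance parameterization)
    a0 = spec.prior_intercept_mean
    A0 = 1.0 / spec.prior_intercept_precision
    b0 = spec.prior_slope_mean
    B0 = 1.0 / spec.prior_slope_precision

    # per-fish sufficient statistics
    if F:
        n_i = np.bincount(g, minlength=F).astype(float)
        Sx = np.bincount(g, weights=x, minlength=F)
        Sxx = np.bincount(g, weights=x * x, minlength=F)
        Sy = np.bincount(g, weights=y, minlength=F)
        Sxy = np.bincount(g, weights=x * y, minlength=F)
    N = float(x.size)

    collapse_a = spec.sigma_alpha == 0
    collapse_b = spec.sigma_beta == 0
    sample_sa = spec.sigma_alpha is None
    sample_sb = spec.sigma_beta is None
    sample_sr = spec.sigma_resid is None

    # dispersed initialization: chain k offset by ±ceil(k/2) prior SDs
    offs = np.array([(-1) ** k * ((k + 1) // 2) for k in range(C)], dtype=float)
    mu_a = a0 + offs * np.sqrt(A0)
    mu_b = b0 + offs * np.sqrt(B0)
    y_var = float(np.var(y)) if N > 1 else 1.0
    disperse = np.exp(np.linspace(-0.7, 0.7, C))
    sr2 = (
        np.full(C, spec.sigma_resid**2)
        if not sample_sr
        else np.maximum(y_var, 0.1) * disperse
    )
    sa2 = (
        np.full(C, float(spec.sigma_alpha) ** 2)
        if spec.sigma_alpha is not None
        else np.maximum(y_var, 0.1) * disperse
    )
    sb2 = (
        np.full(C, float(spec.sigma_beta) ** 2)
        if spec.sigma_beta is not None
        else np.full(C, 1.0) * disperse
    )
    alpha = np.tile(mu_a[:, None], (1, F))
    beta = np.tile(mu_b[:, None], (1, F))

    n_keep = (spec.n_iter - spec.n_burnin) // spec.thin
    names = ["mu_alpha", "mu_beta", "sigma_alpha", "sigma_beta", "sigma_resid"]
    out = {nm: np.empty((C, n_keep)) for nm in names}
    for f in data.fish_ids:
        out[f"alpha[{f}]"] = np.empty((C, n_keep))
        out[f"beta[{f}]"] = np.empty((C, n_keep))

    ig_a, ig_b = spec.ig_shape, spec.ig_rate
    kept = 0
    for it in range(spec.n_iter):
        if F:
            if collapse_a and collapse_b:
                # single-level: (mu_a, mu_b) from the conjugate bivariate normal
                P11 = N / sr2 + 1.0 / A0
                P12 = np.sum(x) / sr2
                P22 = np.sum(x * x) / sr2 + 1.0 / B0
                h1 = np.sum(y) / sr2 + a0 / A0
                h2 = np.sum(x * y) / sr2 + b0 / B0
                mu_a, mu_b = _draw_bvn(rng, P11, P12, P22, h1, h2)
                alpha = np.tile(mu_a[:, None], (1, F))
                beta = np.tile(mu_b[:, None], (1, F))
            else:
                if collapse_a:
                    alpha = np.tile(mu_a[:, None], (1, F))
                    # beta_i | alpha: scalar conjugate normal per fish
                    r_Sxy = Sxy[None, :] - mu_a[:, None] * Sx[None, :]
                    prec = Sxx[None, :] / sr2[:, None] + 1.0 / sb2[:, None]
                    mean = (r_Sxy / sr2[:, None] + mu_b[:, None] / sb2[:, None]) / prec
                    beta = mean + rng.standard_normal((C, F)) / np.sqrt(prec)
                elif collapse_b:
                    beta = np.tile(mu_b[:, None], (1, F))
                    r_Sy = Sy[None, :] - mu_b[:, None] * Sx[None, :]
                    prec = n_i[None, :] / sr2[:, None] + 1.0 / sa2[:, None]
                    mean = (r_Sy / sr2[:, None] + mu_a[:, None] / sa2[:, None]) / prec
                    alpha = mean + rng.standard_normal((C, F)) / np.sqrt(prec)
                else:
                    # joint (alpha_i, beta_i) bivariate-normal block, per fish
                    P11 = n_i[None, :] / sr2[:, None] + 1.0 / sa2[:, None]
                    P12 = Sx[None, :] / sr2[:, None]
                    P22 = Sxx[None, :] / sr2[:, None] + 1.0 / sb2[:, None]
                    h1 = Sy[None, :] / sr2[:, None] + mu_a[:, None] / sa2[:, None]
                    h2 = Sxy[None, :] / sr2[:, None] + mu_b[:, None] / sb2[:, None]
                    alpha, beta = _draw_bvn(rng, P11, P12, P22, h1, h2)

                # population means
                if collapse_a:
                    resid_sum = np.sum(y[None, :] - beta[:, g] * x[None, :], axis=1)
                    prec = 1.0 / A0 + N / sr2
                    mean = (a0 / A0 + resid_sum / sr2) / prec
                else:
                    prec = 1.0 / A0 + F / sa2
                    mean = (a0 / A0 + alpha.sum(axis=1) / sa2) / prec
                mu_a = mean + rng.standard_normal(C) / np.sqrt(prec)

                if collapse_b:
                    rs = np.sum(
                        (y[None, :] - alpha[:, g]) * x[None, :], axis=1
                    )
                    prec = 1.0 / B0 + np.sum(x * x) / sr2
                    mean = (b0 / B0 + rs / sr2) / prec
                else:
                    prec = 1.0 / B0 + F / sb2
                    mean = (b0 / B0 + beta.sum(axis=1) / sb2) / prec
                mu_b = mean + rng.standard_normal(C) / np.sqrt(prec)

            # variance components
            if sample_sa:
                ss = np.sum((alpha - mu_a[:, None]) ** 2, axis=1)
                if spec.variance_hyperprior == "inverse_gamma":
                    sa2 = _inv_gamma(rng, ig_a + F / 2.0, ig_b + ss / 2.0)
                else:
                    sd = _slice_sample_sd(
                        rng, np.sqrt(sa2), ss, F, spec.half_normal_scale
                    )
                    sa2 = sd**2
            if sample_sb:
                ss = np.sum((beta - mu_b[:, None]) ** 2, axis=1)
                if spec.variance_hyperprior == "inverse_gamma":
                    sb2 = _inv_gamma(rng, ig_a + F / 2.0, ig_b + ss / 2.0)
                else:
                    sd = _slice_sample_sd(
                        rng, np.sqrt(sb2), ss, F, spec.half_normal_scale
                    )
                    sb2 = sd**2
            if sample_sr:
                resid = (
                    y[None, :] - alpha[:, g] - beta[:, g] * x[None, :]
                )
                ssr = np.sum(resid**2, axis=1)
                if spec.variance_hyperprior == "inverse_gamma":
                    sr2 = _inv_gamma(rng, ig_a + N / 2.0, ig_b + ssr / 2.0)
                else:
                    sd = _slice_sample_sd(
                        rng, np.sqrt(sr2), ssr, N, spec.half_normal_scale
                    )
                    sr2 = sd**2
        else:
            # no data: population posteriors equal their priors
            mu_a = a0 + np.sqrt(A0) * rng.standard_normal(C)
            mu_b = b0 + np.sqrt(B0) * rng.standard_normal(C)
            if sample_sa:
                sa2 = _inv_gamma(rng, np.full(C, ig_a), np.full(C, ig_b))
            if sample_sb:
                sb2 = _inv_gamma(rng, np.full(C, ig_a), np.full(C, ig_b))
            if sample_sr:
                sr2 = _inv_gamma(rng, np.full(C, ig_a), np.full(C, ig_b))

        if it >= spec.n_burnin and (it - spec.n_burnin) % spec.thin == 0:
            out["mu_alpha"][:, kept] = mu_a
            out["mu_beta"][:, kept] = mu_b
            out["sigma_alpha"][:, kept] = np.sqrt(sa2)
            out["sigma_beta"][:, kept] = np.sqrt(sb2)
            out["sigma_resid"][:, kept] = np.sqrt(sr2)
            for i, f in enumerate(data.fish_ids):
                out[f"alpha[{f}]"][:, kept] = alpha[:, i]
                out[f"beta[{f}]"][:, kept] = beta[:, i]
            kept += 1

        if not (np.all(np.isfinite(mu_a)) and np.all(np.isfinite(mu_b))):
            raise RuntimeError(
                f"sampler diverged (non-finite draws) at iteration {it}"
            )

    return PosteriorDraws(
        lake=data.lake,
        params=out,
        spec=spec,
        n_fish=F,
        n_layers=int(N),
    )


def _draw_bvn(rng, P11, P12, P22, h1, h2):
    """Sample from N(P^-1 h, P^-1) for 2x2 precision blocks, elementwise.

    Accepts arrays of matching shape for the precision entries and the
    linear term; returns the two coordinate arrays.
    """
    det = P11 * P22 - P12**2
    c11 = P22 / det
    c12 = -P12 / det
    c22 = P11 / det
    m1 = c11 * h1 + c12 * h2
    m2 = c12 * h1 + c22 * h2
    L11 = np.sqrt(c11)
    L21 = c12 / L11
    L22 = np.sqrt(np.maximum(c22 - L21**2, 0.0))
    z1 = rng.standard_normal(np.shape(m1))
    z2 = rng.standard_normal(np.shape(m2))
    return m1 + L11 * z1, m2 + L21 * z1 + L22 * z2


# ---------------------------------------------------------------------------
# Diagnostics and summaries

def gelman_rubin(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws). Between-chain variance B/n is the
    variance of chain means; W the mean within-chain variance; the PSRF
    is sqrt(((n-1)/n W + B/n) / W). Identical constant chains have zero
    within-chain variance; by convention that degenerate case returns
    exactly 1 with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length, shaped (chains, draws)")
    m, n = chains.shape
    if n < 100:
        raise ValueError(f"need chain length >= 100, got {n}")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        warnings.warn(
            "zero within-chain variance (constant chains): R-hat defined as 1",
            stacklevel=2,
        )
        return 1.0
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def hpdi(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval: the shortest contiguous
    interval containing ``ceil(prob * n)`` of the sorted samples.

    Ties in width break toward the lower interval start.
    """
    if not (0.0 < prob < 1.0):
        raise ValueError(f"prob must be in (0, 1), got {prob}")
    s = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    n = s.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for a stable HPDI, got {n}")
    m = int(np.ceil(prob * n))
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) minimum
    return float(s[i]), float(s[i + m - 1])


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size (delegated to ArviZ)."""
    import arviz as az

    return float(az.ess(az.convert_to_dataset(np.asarray(chains, dtype=float)))["x"])


def summarize(draws: PosteriorDraws, prob: float = 0.95) -> pd.DataFrame:
    """Posterior summary table: mean, SD, HPDI bounds, R-hat, ESS.

    Chains are pooled for the moments and HPDI; R-hat compares across
    chains. One row per parameter, population-level parameters first.
    """
    rows = []
    for name, arr in draws.params.items():
        pooled = arr.reshape(-1)
        lo, hi = hpdi(pooled, prob)
        rows.append(
            {
                "lake": draws.lake,
                "parameter": name,
                "n_fish": draws.n_fish,
                "n_layers": draws.n_layers,
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                "hpdi_low": lo,
                "hpdi_high": hi,
                "rhat": gelman_rubin(arr),
                "ess": effective_sample_size(arr),
            }
        )
    return pd.DataFrame(rows)
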