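"""Gibbs-sampler correctness, diagnostics, and HPDI behaviour."""

from dataclasses import replace

import numpy as np
import pytest

from isolens.hier_model import (
    ModelSpec,
    build_model_data,
    empty_model_data,
    fit_population,
    gelman_rubin,
    hpdi,
    summarize,
)
from isolens.lens_data import filter_regression_layers
from isolens.synthetic import default_presets, generate_lake


def _model_data_from(layers):
    by_fish = {}
    for r in layers:
        by_fish.setdefault(r.fish_id, []).append(r)
    kept = [r for c in by_fish.values() for r in filter_regression_layers(c)]
    return build_model_data(kept)


class TestModelSpec:
    def test_prior_defaults_match_reported_settings(self):
        spec = ModelSpec()
        assert spec.prior_slope_mean == 0.0
        assert spec.prior_slope_precision == 0.16
        assert spec.prior_intercept_mean == 6.0
        assert spec.prior_intercept_precision == 0.04
        assert (spec.n_chains, spec.n_iter, spec.n_burnin) == (3, 25000, 10000)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_burnin": 30000},
            {"n_chains": 1},
            {"prior_slope_precision": 0.0},
            {"sigma_resid": 0.0},
            {"variance_hyperprior": "flat"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)


class TestBuildModelData:
    def test_counts(self, floods_sim):
        _, layers, _, _ = floods_sim
        data = _model_data_from(layers)
        assert data.n_fish == 4
        assert data.n_layers == len(layers) - 2 * 4

    def test_single_fish_warns(self, floods_sim):
        _, layers, _, _ = floods_sim
        one = [r for r in layers if r.fish_id == layers[0].fish_id]
        with pytest.warns(UserWarning, match="one fish"):
            data = _model_data_from(one)
        assert data.n_fish == 1

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="no layers"):
            build_model_data([])

    def test_unfiltered_input_is_error(self, floods_sim):
        _, layers, _, _ = floods_sim
        with pytest.raises(ValueError, match="filter"):
            build_model_data(layers)


class TestSampler:
    def test_seeded_determinism(self, floods_sim, fast_spec):
        _, layers, _, _ = floods_sim
        data = _model_data_from(layers)
        a = fit_population(data, fast_spec)
        b = fit_population(data, fast_spec)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_prior_recovery_with_no_data(self):
        spec = ModelSpec(n_chains=3, n_iter=6000, n_burnin=1000, seed=5)
        draws = fit_population(empty_model_data(), spec)
        mu_b = draws.pooled("mu_beta")
        mu_a = draws.pooled("mu_alpha")
        n = mu_b.size
        # prior moments: mu_beta ~ N(0, 6.25), mu_alpha ~ N(6, 25)
        assert abs(mu_b.mean() - 0.0) < 3 * 2.5 / np.sqrt(n)
        assert abs(mu_a.mean() - 6.0) < 3 * 5.0 / np.sqrt(n)
        assert abs(mu_b.var(ddof=1) - 6.25) / 6.25 < 0.10
        assert abs(mu_a.var(ddof=1) - 25.0) / 25.0 < 0.10

    def test_single_level_limit_matches_conjugate_closed_form(self, floods_sim):
        """With sigma_alpha = sigma_beta = 0 and known residual SD the model
        is a plain Bayesian linear regression with a bivariate-normal
        posterior available in closed form."""
        _, layers, _, _ = floods_sim
        data = _model_data_from(layers)
        sigma = 0.35
        spec = ModelSpec(
            sigma_alpha=0.0,
            sigma_beta=0.0,
            sigma_resid=sigma,
            n_chains=3,
            n_iter=8000,
            n_burnin=1000,
            seed=13,
        )
        draws = fit_population(data, spec)
        x, y = data.x, data.y
        X = np.column_stack([np.ones_like(x), x])
        P0 = np.diag([0.04, 0.16])  # prior precisions (intercept, slope)
        m0 = np.array([6.0, 0.0])
        P = P0 + X.T @ X / sigma**2
        V = np.linalg.inv(P)
        m = V @ (P0 @ m0 + X.T @ y / sigma**2)
        mu_a = draws.pooled("mu_alpha")
        mu_b = draws.pooled("mu_beta")
        n = mu_a.size
        mcse_a = np.sqrt(V[0, 0] / n)
        mcse_b = np.sqrt(V[1, 1] / n)
        assert abs(mu_a.mean() - m[0]) < 3 * mcse_a
        assert abs(mu_b.mean() - m[1]) < 3 * mcse_b
        assert abs(mu_a.var(ddof=1) - V[0, 0]) / V[0, 0] < 0.10
        assert abs(mu_b.var(ddof=1) - V[1, 1]) / V[1, 1] < 0.10
        # per-fish effects collapse onto the population line
        fish = data.fish_ids[0]
        np.testing.assert_allclose(draws.params[f"alpha[{fish}]"], draws.params["mu_alpha"])

    def test_parameter_recovery_floods(self, floods_sim):
        preset, layers, _, truth = floods_sim
        data = _model_data_from(layers)
        spec = ModelSpec(n_chains=3, n_iter=4000, n_burnin=1000, seed=2)
        draws = fit_population(data, spec)
        mu_b = draws.pooled("mu_beta")
        assert abs(mu_b.mean() - preset.pop_slope) < 2 * mu_b.std()

    def test_half_normal_hyperprior_alternative(self, floods_sim):
        _, layers, _, _ = floods_sim
        data = _model_data_from(layers)
        spec = ModelSpec(
            variance_hyperprior="half_normal",
            n_chains=2,
            n_iter=1500,
            n_burnin=500,
            seed=3,
        )
        draws = fit_population(data, spec)
        mu_b = draws.pooled("mu_beta")
        assert np.all(np.isfinite(mu_b))
        assert abs(mu_b.mean() - 1.01) < 1.0
        assert np.all(draws.pooled("sigma_resid") > 0)

    def test_fixed_nonzero_variances_respected(self, floods_sim):
        _, layers, _, _ = floods_sim
        data = _model_data_from(layers)
        spec = ModelSpec(
            sigma_alpha=0.5, sigma_beta=0.2, sigma_resid=0.3,
            n_chains=2, n_iter=800, n_burnin=200, seed=4,
        )
        draws = fit_population(data, spec)
        assert np.all(draws.pooled("sigma_alpha") == 0.5)
        assert np.all(draws.pooled("sigma_beta") == 0.2)


class TestGelmanRubin:
    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(0, 1, size=(3, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_offset_chains_flagged(self, rng):
        chains = rng.normal(0, 1, size=(2, 1000))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 1.5

    def test_constant_chains_convention(self):
        with pytest.warns(UserWarning, match="R-hat defined as 1"):
            assert gelman_rubin(np.ones((3, 200))) == 1.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 500)))


class TestHPDI:
    def test_uniform_grid(self):
        lo, hi = hpdi(np.arange(1, 1001, dtype=float), prob=0.95)
        assert hi - lo == pytest.approx(949.0)
        assert lo == 1.0  # ties break toward the lower start

    def test_standard_normal_interval(self, rng):
        s = rng.normal(0, 1, size=100_000)
        lo, hi = hpdi(s, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_samples(self):
        lo, hi = hpdi(np.full(500, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_shorter_than_central_interval_when_skewed(self, rng):
        s = rng.gamma(2.0, 1.0, size=50_000)
        lo, hi = hpdi(s, 0.95)
        central = np.percentile(s, [2.5, 97.5])
        assert (hi - lo) <= (central[1] - central[0])

    @pytest.mark.parametrize("prob", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prob(self, prob):
        with pytest.raises(ValueError):
            hpdi(np.arange(200, dtype=float), prob)


class TestSummarize:
    def test_moments_and_shape(self, floods_sim, fast_spec):
        _, layers, _, _ = floods_sim
        data = _model_data_from(layers)
        draws = fit_population(data, fast_spec)
        table = summarize(draws)
        assert set(
            ["mu_alpha", "mu_beta", "sigma_alpha", "sigma_beta", "sigma_resid"]
        ) <= set(table["parameter"])
        row = table.set_index("parameter").loc["mu_beta"]
        pooled = draws.pooled("mu_beta")
        assert row["mean"] == pytest.approx(pooled.mean())
        assert row["sd"] == pytest.approx(pooled.std(ddof=1))
        assert row["hpdi_low"] < row["mean"] < row["hpdi_high"]
        assert (table["n_fish"] == 4).all()
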