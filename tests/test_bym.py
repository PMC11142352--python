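"""Sampler correctness: log posterior, Polya-Gamma draws, Gibbs invariants."""

import numpy as np
import pandas as pd
import pytest

from denialmap import (
    BYMModelSpec,
    ModelData,
    SyntheticConfig,
    fit_msa,
    generate,
    log_posterior,
    sample_posterior,
)
from denialmap.bym import icar_pairwise_energy, sample_polya_gamma
from denialmap.spatial import AdjacencyStructure


def two_node_adj():
    return AdjacencyStructure.from_edges(["a", "b"], [("a", "b")])


class TestLogPosterior:
    def test_single_loan_null_state_is_log_half(self):
        data = ModelData(
            y=np.array([1.0]),
            X=np.zeros((1, 0)),
            tract_index=np.array([0]),
            adjacency=two_node_adj(),
        )
        spec = BYMModelSpec(include_spatial=False, include_unstructured=False, covariates=())
        lp = log_posterior({"alpha": 0.0, "beta": np.zeros(0)}, data, spec)
        assert lp == pytest.approx(np.log(0.5))

    def test_icar_pairwise_term_two_nodes(self):
        adj = two_node_adj()
        u = np.array([1.0, -1.0])
        energy = icar_pairwise_energy(u, adj)  # (u1 - u2)^2 = 4
        assert -0.5 * energy / 1.0 == pytest.approx(-2.0)

    def test_binary_weights_energy_unchanged_by_doubled_listing(self):
        # listing an edge twice must not change the binary graph's energy
        adj_once = AdjacencyStructure.from_edges(["a", "b"], [("a", "b")])
        adj_twice = AdjacencyStructure.from_edges(["a", "b"], [("a", "b"), ("b", "a")])
        u = np.array([0.7, -0.7])
        assert icar_pairwise_energy(u, adj_once) == icar_pairwise_energy(u, adj_twice)

    def test_non_finite_state_rejected(self):
        data = ModelData(
            y=np.array([1.0]),
            X=np.zeros((1, 0)),
            tract_index=np.array([0]),
            adjacency=two_node_adj(),
        )
        spec = BYMModelSpec(include_spatial=False, include_unstructured=False, covariates=())
        with pytest.raises(ValueError, match="non-finite"):
            log_posterior({"alpha": np.inf, "beta": np.zeros(0)}, data, spec)


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.5, 2.0, 6.0])
    def test_mean_matches_closed_form(self, z):
        rng = np.random.default_rng(99)
        draws = sample_polya_gamma(np.full(40_000, z), rng)
        mean = 0.25 if z == 0 else np.tanh(z / 2) / (2 * z)
        assert draws.mean() == pytest.approx(mean, abs=4 * draws.std() / 200)
        assert (draws > 0).all()

    def test_even_in_z(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        a = sample_polya_gamma(np.full(100, 1.7), rng1)
        b = sample_polya_gamma(np.full(100, -1.7), rng2)
        np.testing.assert_allclose(a, b)


@pytest.fixture(scope="module")
def fitted_small():
    cfg = SyntheticConfig(
        n_msa=1, grid_rows=3, grid_cols=3, loans_per_tract=30,
        sigma2_u=0.3, sigma2_v=0.1, seed=21,
    )
    ds = generate(cfg)
    msa = ds.geometry.msas[0]
    data = ModelData.from_records(ds.loans, ds.adjacency[msa])
    draws = sample_posterior(data, BYMModelSpec(), n_chains=2, n_iter=600, burn_in=200, seed=3)
    return ds, data, draws


class TestSampler:
    def test_sum_to_zero_every_kept_draw(self, fitted_small):
        _, data, draws = fitted_small
        comp = data.adjacency.component_labels
        u = draws.stacked("u")
        for c in np.unique(comp):
            sums = u[:, comp == c].sum(axis=1)
            assert np.abs(sums).max() < 1e-8

    def test_variance_draws_positive(self, fitted_small):
        _, _, draws = fitted_small
        assert (draws.stacked("sigma2_u") > 0).all()
        assert (draws.stacked("sigma2_v") > 0).all()

    def test_determinism_same_seed(self, fitted_small):
        _, data, draws = fitted_small
        again = sample_posterior(
            data, BYMModelSpec(), n_chains=2, n_iter=600, burn_in=200, seed=3
        )
        np.testing.assert_array_equal(draws.alpha, again.alpha)
        np.testing.assert_array_equal(draws.u, again.u)

    def test_row_permutation_invariance(self, fitted_small):
        ds, data, draws = fitted_small
        msa = ds.geometry.msas[0]
        shuffled = ds.loans.sample(frac=1.0, random_state=0)
        data2 = ModelData.from_records(shuffled, ds.adjacency[msa])
        again = sample_posterior(
            data2, BYMModelSpec(), n_chains=2, n_iter=600, burn_in=200, seed=3
        )
        np.testing.assert_array_equal(draws.alpha, again.alpha)
        np.testing.assert_array_equal(draws.beta, again.beta)
        np.testing.assert_array_equal(draws.u, again.u)

    def test_diagnostics_attached(self, fitted_small):
        _, _, draws = fitted_small
        assert "rhat" in draws.meta and "ess_bulk" in draws.meta
        assert isinstance(draws.meta["converged"], bool)
        assert draws.meta["acceptance_rate"] == 1.0

    def test_no_denials_pushes_alpha_negative_rr_proper(self):
        """All y = 0: alpha mass moves far negative; RR posteriors stay proper."""
        cfg = SyntheticConfig(
            n_msa=1, grid_rows=2, grid_cols=2, loans_per_tract=25,
            alpha=-20.0, sigma2_u=0.0, sigma2_v=0.0, seed=2,
        )
        ds = generate(cfg)
        assert ds.loans["denied"].sum() == 0
        msa = ds.geometry.msas[0]
        draws, estimates = fit_msa(
            ds.loans, ds.adjacency[msa], n_chains=1, n_iter=500, burn_in=200, seed=1
        )
        assert draws.stacked("alpha").mean() < -2
        for e in estimates:
            assert np.isfinite(e.rr_mean) and e.rr_mean > 0
            assert 0 < e.rr_lower <= e.rr_upper < np.inf

    def test_prior_recovery_with_zero_loans(self):
        """No likelihood: sigma^2 draws must reproduce the hyperprior."""
        adj = AdjacencyStructure.from_edges(
            ["a", "b", "c", "d"], [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        )
        data = ModelData(
            y=np.zeros(0), X=np.zeros((0, 0)), tract_index=np.zeros(0, int), adjacency=adj
        )
        spec = BYMModelSpec(
            alpha_prior_mean=0.0, alpha_prior_var=1.0,
            tau_u_shape=3.0, tau_u_rate=2.0, tau_v_shape=3.0, tau_v_rate=2.0,
            covariates=(),
        )
        draws = sample_posterior(data, spec, n_chains=1, n_iter=4000, burn_in=500, seed=8)
        tau_v = 1.0 / draws.stacked("sigma2_v")
        tau_u = 1.0 / draws.stacked("sigma2_u")
        # Gamma(3, 2): mean 1.5, sd sqrt(3)/2
        for tau in (tau_u, tau_v):
            assert tau.mean() == pytest.approx(1.5, abs=0.15)
            assert tau.std() == pytest.approx(np.sqrt(3.0) / 2.0, abs=0.15)
        alpha = draws.stacked("alpha")
        assert alpha.mean() == pytest.approx(0.0, abs=0.1)
        assert alpha.std() == pytest.approx(1.0, abs=0.1)

    def test_island_tract_effect_pinned_at_zero(self):
        """A degree-0 tract forms its own component; sum-to-zero pins u to 0."""
        adj = AdjacencyStructure.from_edges(
            ["a", "b", "c", "iso"], [("a", "b"), ("b", "c")]
        )
        rng = np.random.default_rng(0)
        n = 120
        records = pd.DataFrame(
            {
                "msa_id": "M",
                "tract_geoid": rng.choice(["a", "b", "c", "iso"], size=n),
                "sex_female": rng.integers(0, 2, n),
                "lti": np.exp(rng.normal(0.7, 0.3, n)),
                "denied": rng.integers(0, 2, n),
            }
        )
        data = ModelData.from_records(records, adj)
        draws = sample_posterior(data, BYMModelSpec(), n_chains=1, n_iter=300, burn_in=100, seed=4)
        iso_idx = adj.ids.index("iso")
        assert np.abs(draws.stacked("u")[:, iso_idx]).max() < 1e-8

    def test_spatial_off_reduces_to_random_intercept_model(self):
        """With u disabled the model is logistic-normal random-intercept; beta
        from the full BYM fit on spatially flat data agrees with it."""
        cfg = SyntheticConfig(
            n_msa=1, grid_rows=3, grid_cols=3, loans_per_tract=60,
            sigma2_u=0.0, sigma2_v=0.15, seed=33,
        )
        ds = generate(cfg)
        msa = ds.geometry.msas[0]
        data = ModelData.from_records(ds.loans, ds.adjacency[msa])
        full = sample_posterior(
            data, BYMModelSpec(), n_chains=1, n_iter=1500, burn_in=500, seed=5
        )
        reduced = sample_posterior(
            data,
            BYMModelSpec(include_spatial=False),
            n_chains=1, n_iter=1500, burn_in=500, seed=5,
        )
        assert (reduced.stacked("sigma2_u") == 0).all()
        np.testing.assert_allclose(
            full.stacked("beta").mean(axis=0),
            reduced.stacked("beta").mean(axis=0),
            atol=0.1,
        )

    def test_fit_msa_rejects_mixed_or_sparse_msas(self, fitted_small):
        ds, _, _ = fitted_small
        mixed = ds.loans.copy()
        mixed.loc[mixed.index[:5], "msa_id"] = "other"
        with pytest.raises(ValueError, match="one MSA"):
            fit_msa(mixed, ds.adjacency[ds.geometry.msas[0]])
        one_tract = ds.loans[ds.loans["tract_geoid"] == ds.geometry.geoids[0]]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_msa(one_tract, ds.adjacency[ds.geometry.msas[0]])

    def test_records_with_unknown_tract_rejected(self, fitted_small):
        ds, _, _ = fitted_small
        bad = ds.loans.copy()
        bad.loc[bad.index[0], "tract_geoid"] = "99999999999"
        with pytest.raises(ValueError, match="absent from adjacency"):
            ModelData.from_records(bad, ds.adjacency[ds.geometry.msas[0]])

    def test_burn_in_must_be_smaller_than_iterations(self, fitted_small):
        _, data, _ = fitted_small
        with pytest.raises(ValueError, match="burn_in"):
            sample_posterior(data, BYMModelSpec(), n_iter=100, burn_in=100, seed=0)
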