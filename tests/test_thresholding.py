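import numpy as np
import pytest
from scipy.stats import norm

from schurdle import (
    build_prior,
    fit_gene_map,
    fit_omnibus_mixture,
    posterior_signal_prob,
    threshold_gene,
    threshold_table,
)
from schurdle.thresholding import _map_objective, _responsibilities


@pytest.fixture(scope="module")
def bimodal_omnibus():
    rng = np.random.default_rng(0)
    x = np.r_[rng.normal(0.5, 0.5, 1000), rng.normal(8, 1, 1000)]
    return fit_omnibus_mixture(x)


class TestOmnibusMLE:
    def test_recovers_generating_parameters(self, bimodal_omnibus):
        f = bimodal_omnibus
        assert abs(f.mu_noise - 0.5) < 0.1 and abs(f.mu_signal - 8.0) < 0.1
        assert abs(f.pi_signal - 0.5) < 0.03

    def test_agrees_with_independent_em_implementation(self, bimodal_omnibus):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0.5, 0.5, 1000), rng.normal(8, 1, 1000)]
        gm = GaussianMixture(2, random_state=0, tol=1e-8, max_iter=500).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(
            [bimodal_omnibus.mu_noise, bimodal_omnibus.mu_signal],
            gm.means_.ravel()[order], atol=1e-3,
        )
        np.testing.assert_allclose(
            bimodal_omnibus.pi_signal, gm.weights_[order][1], atol=1e-3
        )

    def test_single_gaussian_collapses_or_flags(self):
        rng = np.random.default_rng(4)
        f = fit_omnibus_mixture(rng.normal(5, 1, 200))
        assert max(f.pi_signal, 1 - f.pi_signal) >= 0.95 or not f.converged

    def test_perfectly_separated_deltas_recover_exact_fraction(self, rng):
        x = np.r_[rng.normal(0, 1e-3, 40), 10 + rng.normal(0, 1e-3, 60)]
        f = fit_omnibus_mixture(x)
        assert round(f.pi_signal, 3) == 0.6

    @pytest.mark.parametrize("bad", [np.ones(50), np.arange(5)])
    def test_degenerate_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            fit_omnibus_mixture(bad)

    def test_relabeling_invariant_over_seeds(self):
        for seed in range(8):
            r = np.random.default_rng(seed)
            x = np.r_[r.normal(r.uniform(0, 2), 0.5, 120), r.normal(r.uniform(5, 9), 1, 80)]
            f = fit_omnibus_mixture(x)
            assert f.mu_noise <= f.mu_signal


class TestPrior:
    def test_direct_construction_from_hyperparameters(self, bimodal_omnibus):
        prior = build_prior(bimodal_omnibus)
        assert prior.mean_locations == (bimodal_omnibus.mu_noise, bimodal_omnibus.mu_signal)
        assert prior.mean_strength == 15.0  # kappa=3 x Nt=5
        assert prior.mix_a == prior.mix_b == 5.0

    def test_beta_prior_weighs_ten_observations(self, bimodal_omnibus):
        prior = build_prior(bimodal_omnibus, mix_weight=5)
        assert prior.mix_a + prior.mix_b == 10.0

    def test_variance_prior_mode_matches_omnibus(self, bimodal_omnibus):
        prior = build_prior(bimodal_omnibus)
        for scale, shape, v in zip(
            prior.var_scale, prior.var_shape,
            (bimodal_omnibus.var_noise, bimodal_omnibus.var_signal),
        ):
            assert np.isclose(scale / (shape + 1.0), v)

    @pytest.mark.parametrize("kw", [dict(kappa=0), dict(nt=-1), dict(mix_weight=0)])
    def test_nonpositive_hyperparameters_raise(self, bimodal_omnibus, kw):
        with pytest.raises(ValueError):
            build_prior(bimodal_omnibus, **kw)


class TestGeneMAP:
    def test_recovery_at_prior_centers(self, bimodal_omnibus, rng):
        prior = build_prior(bimodal_omnibus)
        x = np.r_[rng.normal(0.5, 0.5, 150), rng.normal(8, 1, 150)]
        f = fit_gene_map(x, prior)
        assert abs(f.mu_noise - 0.5) < 0.2 and abs(f.mu_signal - 8.0) < 0.25
        assert abs(f.pi_signal - 0.5) < 0.05

    def test_prior_prevents_cluster_collapse_on_high_only_gene(self, bimodal_omnibus):
        prior = build_prior(bimodal_omnibus)
        x = np.array([7.8, 8.1, 8.4, 7.9, 8.2])
        f = fit_gene_map(x, prior)
        # noise cluster survives at the prior center with prior-only weight
        assert abs(f.mu_noise - bimodal_omnibus.mu_noise) < 0.5
        assert np.isclose(f.pi_signal, (5 + 4) / (5 + 8))

    def test_map_is_local_mode_of_posterior_objective(self, bimodal_omnibus, rng):
        prior = build_prior(bimodal_omnibus)
        x = np.array([7.8, 8.1, 8.4, 7.9, 8.2])
        f = fit_gene_map(x, prior)
        mu = np.array([f.mu_noise, f.mu_signal])
        var = np.array([f.var_noise, f.var_signal])
        pi = np.array([1 - f.pi_signal, f.pi_signal])
        at_fit = _map_objective(x, mu, var, pi, prior)
        for _ in range(200):
            d_mu = mu + rng.normal(0, 0.02, 2)
            d_var = var * np.exp(rng.normal(0, 0.02, 2))
            d_pi1 = np.clip(pi[1] + rng.normal(0, 0.01), 1e-4, 1 - 1e-4)
            perturbed = _map_objective(
                x, d_mu, d_var, np.array([1 - d_pi1, d_pi1]), prior
            )
            assert perturbed <= at_fit + 1e-9

    def test_large_kappa_pins_means_to_omnibus(self, bimodal_omnibus, rng):
        prior = build_prior(bimodal_omnibus, kappa=1e6)
        f = fit_gene_map(rng.normal(6, 1, 50), prior)
        assert abs(f.mu_noise - bimodal_omnibus.mu_noise) < 1e-2
        assert abs(f.mu_signal - bimodal_omnibus.mu_signal) < 1e-2

    def test_three_identical_values_dominated_by_prior(self, bimodal_omnibus):
        prior = build_prior(bimodal_omnibus)
        f = fit_gene_map(np.array([2.0, 2.0, 2.0]), prior)
        assert np.isfinite(f.loglik) and f.var_noise > 0 and f.var_signal > 0

    def test_mixing_proportion_obeys_beta_map_update(self, bimodal_omnibus):
        prior = build_prior(bimodal_omnibus)
        x = np.array([0.5, 0.7, 8.0, 8.3])
        f = fit_gene_map(x, prior)
        w = _responsibilities(
            x,
            np.array([f.mu_noise, f.mu_signal]),
            np.array([f.var_noise, f.var_signal]),
            np.array([1 - f.pi_signal, f.pi_signal]),
            x == 0.0,
        )
        assert np.isclose(f.pi_signal, (w[1].sum() + 4) / (len(x) + 8))


class TestPosteriorAndThreshold:
    def _symmetric_fit(self):
        from schurdle import MixtureFit

        return MixtureFit(
            mu_noise=1.0, mu_signal=7.0, var_noise=1.0, var_signal=1.0,
            pi_signal=0.5, loglik=0.0, n_obs=100,
        )

    def test_midpoint_of_symmetric_fit_is_half(self):
        assert np.isclose(posterior_signal_prob(4.0, self._symmetric_fit()), 0.5)

    def test_deep_noise_tail_saturates(self):
        f = self._symmetric_fit()
        assert posterior_signal_prob(f.mu_noise - 10.0, f) < 1e-6

    def test_matches_bruteforce_density_ratio_on_grid(self, bimodal_omnibus):
        f = bimodal_omnibus
        grid = np.linspace(-2, 12, 100)
        direct = (
            f.pi_signal * norm.pdf(grid, f.mu_signal, np.sqrt(f.var_signal))
        ) / (
            f.pi_signal * norm.pdf(grid, f.mu_signal, np.sqrt(f.var_signal))
            + (1 - f.pi_signal) * norm.pdf(grid, f.mu_noise, np.sqrt(f.var_noise))
        )
        np.testing.assert_allclose(posterior_signal_prob(grid, f), direct, atol=1e-12)

    def test_clear_cut_classification(self):
        f = self._symmetric_fit()
        np.testing.assert_array_equal(threshold_gene([0.2, 9.1], f), [0.0, 9.1])

    def test_exact_boundary_is_kept(self):
        f = self._symmetric_fit()
        assert threshold_gene([4.0], f)[0] == 4.0  # truncate only strictly > .5

    def test_kept_values_equal_input_and_zero_fraction_matches_posterior(
        self, bimodal_omnibus, rng
    ):
        x = np.r_[rng.normal(0.5, 0.5, 300), rng.normal(8, 1, 300)]
        et = threshold_gene(x, bimodal_omnibus)
        kept = et > 0
        np.testing.assert_array_equal(et[kept], x[kept])
        frac_noise = ((1 - posterior_signal_prob(x, bimodal_omnibus)) > 0.5).mean()
        assert np.isclose((et == 0).mean(), frac_noise)

    def test_six_sd_separation_classifies_99_percent(self, rng):
        labels = rng.random(2000) < 0.6
        x = np.where(labels, rng.normal(8, 1, 2000), rng.normal(2, 1, 2000))
        fit = fit_omnibus_mixture(x)
        et = threshold_gene(x, fit)
        assert ((et > 0) == labels).mean() >= 0.99


def test_threshold_table_thresholds_every_gene(small_table):
    table, truth = small_table
    out, fits = threshold_table(table, value="lcount")
    assert set(fits) == set(table.genes)
    df = out.df
    assert (df["et"] >= 0).all()
    kept = df["et"] > 0
    np.testing.assert_array_equal(df.loc[kept, "et"], df.loc[kept, "lcount"])
    # mixture classification should agree closely with the generating labels
    agree = ((df["et"] > 0) == (truth.cluster_label == "signal")).mean()
    assert agree > 0.97
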