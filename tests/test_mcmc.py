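"""Correctness of the Gibbs sampler against exact posteriors."""

import math

import numpy as np
import pytest

import ketosynth as ks
from ketosynth.study_data import EvidenceMatrix

from _oracles import exact_cell_mean_summary, exact_posterior_mixture


def sparse_matrix(cells):
    """5x4 grid with only the given {(i, j): (y, sd)} cells observed."""
    y = np.full((5, 4), np.nan)
    sd = np.full((5, 4), np.nan)
    for (i, j), (val, err) in cells.items():
        y[i, j], sd[i, j] = val, err
    return EvidenceMatrix(y, sd)


def diag_prior(name="toy", var_alpha=1.0, var_gamma=1.0, mu=0.0):
    return ks.PriorSpec(
        name=name,
        mu_alpha=np.full(5, mu),
        R_alpha=var_alpha * np.eye(5),
        mu_gamma=np.full(4, mu),
        R_gamma=var_gamma * np.eye(4),
    )


class TestConjugateExactness:
    def test_single_cell_flat_prior_recovers_datum(self):
        """One observed cell, near-flat effect priors, no potency noise:
        the posterior of theta collapses to N(y, c^2)."""
        data = sparse_matrix({(0, 0): (0.5, 0.2)})
        prior = diag_prior(var_alpha=1e6, var_gamma=1e6)
        res = ks.run_mcmc(
            data, prior, ks.MCMCConfig.fast(seed=4, sigma_fixed=0.0)
        )
        th = res.theta[:, 0, 0]
        assert th.mean() == pytest.approx(0.5, abs=0.01)
        assert th.var() == pytest.approx(0.04, rel=0.1)

    def test_two_by_two_matches_closed_form(self):
        """With sigma fixed the model is linear-Gaussian; MCMC moments of
        alpha, gamma and theta must match the exact MVN posterior."""
        cells = {
            (0, 0): (0.40, 0.15),
            (0, 1): (0.10, 0.25),
            (1, 0): (0.30, 0.10),
            (1, 1): (0.55, 0.20),
        }
        data = sparse_matrix(cells)
        prior = diag_prior(var_alpha=2.0, var_gamma=1.5, mu=0.1)
        sigma = 0.3
        res = ks.run_mcmc(
            data, prior, ks.MCMCConfig.fast(seed=9, sigma_fixed=sigma)
        )
        w, means, covs, _ = exact_posterior_mixture(prior, data, sigma_fixed=sigma)
        m_exact, C_exact = means[0], covs[0]
        n_eff = res.n_draws  # draws are nearly independent for this block
        for k in range(9):
            mcse = math.sqrt(C_exact[k, k] / n_eff)
            sample = np.concatenate([res.alpha, res.gamma], axis=1)[:, k]
            assert sample.mean() == pytest.approx(m_exact[k], abs=4 * mcse)
            assert sample.var() == pytest.approx(C_exact[k, k], rel=0.1)
        # theta for an observed cell: precision-weighted blend of y and
        # alpha+gamma plus conjugate noise
        i, j = 0, 0
        y, c = cells[(i, j)]
        prec = 1 / c**2 + 1 / sigma**2
        lam = (1 / c**2) / prec
        mu_sum = m_exact[i] + m_exact[5 + j]
        var_sum = C_exact[i, i] + C_exact[5 + j, 5 + j] + 2 * C_exact[i, 5 + j]
        th_mean = lam * y + (1 - lam) * mu_sum
        th_var = 1 / prec + (1 - lam) ** 2 * var_sum
        th = res.theta[:, i, j]
        assert th.mean() == pytest.approx(th_mean, abs=4 * math.sqrt(th_var / n_eff))
        assert th.var() == pytest.approx(th_var, rel=0.1)

    def test_study_grid_matches_quadrature_oracle(self, table2, paper_fits):
        """Full fit on the real grid, sigma free: summaries agree with the
        sigma-quadrature oracle."""
        res = paper_fits["SP2"]
        exact = exact_cell_mean_summary(ks.make_prior("SP2"), table2)
        got = res.summarize("Humans")
        for j in range(4):
            assert got.loc[j, "median_mr"] == pytest.approx(
                exact[j]["median_mr"], abs=0.03
            )
            assert got.loc[j, "cri_low"] == pytest.approx(exact[j]["cri_low"], abs=0.08)
            assert got.loc[j, "cri_high"] == pytest.approx(
                exact[j]["cri_high"], abs=0.15
            )
            assert got.loc[j, "p_gt_1"] == pytest.approx(exact[j]["p_gt_1"], abs=0.02)


class TestPriorRecovery:
    def test_no_data_returns_the_prior(self):
        """With every cell missing the chain must sample the prior."""
        empty = EvidenceMatrix(np.full((5, 4), np.nan), np.full((5, 4), np.nan))
        prior = ks.make_prior("SP2")
        res = ks.run_mcmc(empty, prior, ks.MCMCConfig.fast(seed=21))
        assert res.alpha.mean() == pytest.approx(0.0, abs=0.05)
        assert res.alpha.std() == pytest.approx(1.0, abs=0.05)
        assert res.gamma.std() == pytest.approx(1.0, abs=0.05)
        # sigma prior N(0.5, 0.1^2) truncated at 0: truncation is negligible
        assert np.median(res.sigma) == pytest.approx(0.5, abs=0.01)
        assert res.sigma.std() == pytest.approx(0.1, abs=0.01)


class TestChainBehaviour:
    def test_two_seeds_agree_at_default_lengths(self, table2, paper_fits):
        """Independent chains agree to within 2% on every reported median
        (relative scale — the medians are ratios between 1.3 and 1.8)."""
        res_a = paper_fits["SP1"]
        res_b = ks.run_mcmc(table2, ks.make_prior("SP1"), ks.MCMCConfig(seed=99))
        med_a = res_a.summarize("Humans")["median_mr"]
        med_b = res_b.summarize("Humans")["median_mr"]
        assert np.all(np.abs(np.log(med_a) - np.log(med_b)) < 0.02)

    def test_identical_seed_is_bitwise_reproducible(self, table2):
        cfg = ks.MCMCConfig.fast(seed=7)
        a = ks.run_mcmc(table2, ks.make_prior("EP"), cfg)
        b = ks.run_mcmc(table2, ks.make_prior("EP"), cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_missing_cell_interval_wider_than_observed(self, paper_fits):
        """Humans/CR carries no data; its credible interval must be at
        least as wide (log scale) as the observed Humans/CR+ cell's."""
        s = paper_fits["SP1"].summarize("Humans").set_index("intervention")
        width = lambda iv: math.log(s.loc[iv, "cri_high"] / s.loc[iv, "cri_low"])
        assert width("CR") >= width("CR+")

    def test_non_psd_prior_rejected(self):
        with pytest.raises(ValueError):
            ks.PriorSpec(
                name="bad",
                mu_alpha=np.zeros(5),
                R_alpha=np.eye(5) - 0.5,
                mu_gamma=np.zeros(4),
                R_gamma=np.eye(4),
            )


class TestSummaries:
    def _degenerate_result(self, theta_value):
        n = 2000
        theta = np.full((n, 5, 4), theta_value)
        return ks.PosteriorResult(
            theta=theta,
            theta_pred=theta.copy(),
            alpha=np.full((n, 5), theta_value / 2),
            gamma=np.full((n, 4), theta_value / 2),
            sigma=np.full(n, 0.4),
            deviance=np.zeros(n),
            prior=ks.make_prior("SP2"),
            config=ks.MCMCConfig.fast(),
            accept_rate=0.3,
        )

    def test_point_mass_draws(self):
        tab = ks.summarize(self._degenerate_result(0.0), "Humans")
        assert (tab["median_mr"] == 1.0).all()
        assert (tab["p_gt_1"] == 0.0).all()

    def test_symmetric_draws_give_half_probability(self):
        rng = np.random.default_rng(0)
        res = self._degenerate_result(0.0)
        res.alpha = rng.standard_normal(res.alpha.shape)
        res.gamma = rng.standard_normal(res.gamma.shape)
        tab = ks.summarize(res, "Humans")
        assert np.allclose(tab["p_gt_1"], 0.5, atol=0.05)

    def test_unknown_species_rejected(self, paper_fits):
        with pytest.raises(KeyError):
            ks.summarize(paper_fits["SP1"], "Mice")

    def test_quantile_ordering(self, paper_fits):
        for level in ("mean", "predictive", "latent"):
            tab = paper_fits["SP2"].summarize("Humans", level=level)
            assert (tab["cri_low"] <= tab["median_mr"]).all()
            assert (tab["median_mr"] <= tab["cri_high"]).all()


class TestSigmaPriorSweep:
    def test_sweep_properties(self, table2):
        specs = [(0.5, 0.01), (0.75, 0.01), (0.5, 1e-6)]
        tab = ks.sigma_prior_sweep(
            table2, ks.make_prior("SP2"), specs, ks.MCMCConfig.toy(seed=2)
        )
        assert len(tab) == 12  # 3 sweeps x 4 interventions
        by_spec = tab.groupby(["sigma_prior_mean", "sigma_prior_var"])[
            "sigma_median"
        ].first()
        # posterior sigma pulled below the prior mean by the data
        assert by_spec[(0.5, 0.01)] < 0.5
        assert by_spec[(0.75, 0.01)] < 0.75
        # near-degenerate prior dominates the likelihood
        assert by_spec[(0.5, 1e-6)] == pytest.approx(0.5, abs=0.005)

    def test_default_entry_consistent_with_plain_fit(self, table2, paper_fits):
        tab = ks.sigma_prior_sweep(
            table2, ks.make_prior("SP2"), [(0.5, 0.01)], ks.MCMCConfig.fast(seed=31)
        )
        main = paper_fits["SP2"].summarize("Humans")
        assert np.allclose(tab["median_mr"], main["median_mr"], atol=0.05)

    def test_invalid_variance_rejected(self, table2):
        with pytest.raises(ValueError):
            ks.sigma_prior_sweep(
                table2, ks.make_prior("SP2"), [(0.5, -1.0)], ks.MCMCConfig.toy()
            )
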