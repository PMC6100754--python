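"""Independent reference computations used only by the test suite.

Each oracle takes a route disjoint from the implementation it checks:
the hierarchical-model oracle marginalises the latent cell effects
analytically and integrates sigma by one-dimensional quadrature; the
pooling oracle integrates the overall mean analytically and the
between-study scale with adaptive quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from ketosynth.priors import PriorSpec
from ketosynth.study_data import EvidenceMatrix


def exact_posterior_mixture(
    prior: PriorSpec,
    data: EvidenceMatrix,
    sigma_grid: np.ndarray | None = None,
    sigma_fixed: float | None = None,
):
    """Exact posterior of (alpha, gamma) as a normal mixture over sigma.

    Conditional on sigma the latent effects integrate out and the model
    is the linear-Gaussian regression y = X (alpha, gamma) + eps with
    Var eps = c^2 + sigma^2, so the (alpha, gamma) posterior is an
    explicit 9-dimensional normal. sigma is handled by quadrature over
    ``sigma_grid`` with weights proportional to prior times marginal
    likelihood. Returns (weights, means, covariances).
    """
    mask = data.mask
    y = data.y[mask]
    c2 = data.sd[mask] ** 2
    ii, jj = np.where(mask)
    X = np.zeros((len(y), 9))
    X[np.arange(len(y)), ii] = 1.0
    X[np.arange(len(y)), 5 + jj] = 1.0

    mu0 = np.concatenate([prior.mu_alpha, prior.mu_gamma])
    R0 = np.zeros((9, 9))
    R0[:5, :5] = prior.R_alpha
    R0[5:, 5:] = prior.R_gamma
    R0_inv = np.linalg.inv(R0)

    if sigma_fixed is not None:
        sigma_grid = np.array([sigma_fixed])
    elif sigma_grid is None:
        sigma_grid = np.linspace(0.02, 1.2, 300)

    logw, means, covs = [], [], []
    for s in sigma_grid:
        v = c2 + s * s
        V_inv = np.diag(1.0 / v)
        P = R0_inv + X.T @ V_inv @ X
        C = np.linalg.inv(P)
        m = C @ (R0_inv @ mu0 + X.T @ V_inv @ y)
        S = X @ R0 @ X.T + np.diag(v)
        ll = stats.multivariate_normal.logpdf(y, X @ mu0, S)
        lp = (
            0.0
            if sigma_fixed is not None
            else stats.norm.logpdf(s, prior.sigma_prior_mean, np.sqrt(prior.sigma_prior_var))
        )
        logw.append(ll + lp)
        means.append(m)
        covs.append(C)
    logw = np.asarray(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return w, np.asarray(means), np.asarray(covs), sigma_grid


def exact_cell_mean_summary(
    prior: PriorSpec, data: EvidenceMatrix, species_index: int = 0
):
    """Exact median / 95% interval / P(>1) of exp(alpha_i + gamma_j)."""
    w, means, covs, _ = exact_posterior_mixture(prior, data)
    rows = []
    grid = np.linspace(-4, 5, 6001)
    for j in range(4):
        m = means[:, species_index] + means[:, 5 + j]
        v = (
            covs[:, species_index, species_index]
            + covs[:, 5 + j, 5 + j]
            + 2 * covs[:, species_index, 5 + j]
        )
        cdf = np.sum(
            w[:, None] * stats.norm.cdf((grid[None, :] - m[:, None]) / np.sqrt(v)[:, None]),
            axis=0,
        )
        med = np.interp(0.5, cdf, grid)
        lo = np.interp(0.025, cdf, grid)
        hi = np.interp(0.975, cdf, grid)
        p = 1.0 - np.interp(0.0, grid, cdf)
        rows.append(
            {
                "median_mr": float(np.exp(med)),
                "cri_low": float(np.exp(lo)),
                "cri_high": float(np.exp(hi)),
                "p_gt_1": float(p),
            }
        )
    return rows


def pool_oracle(values, sds, log_tau_prior, tau_hi):
    """Posterior mean/SD of the overall effect, mu integrated analytically.

    Given tau, the conditional posterior of the pooled mean under a flat
    prior is N(mu_hat(tau), V(tau)) with an explicit marginal
    likelihood; tau is integrated by adaptive quadrature. Independent of
    the trapezoid-grid engine.
    """
    y = np.asarray(values, float)
    s2 = np.asarray(sds, float) ** 2

    def parts(tau):
        v = s2 + tau * tau
        w = 1.0 / v
        mu_hat = np.sum(w * y) / np.sum(w)
        V = 1.0 / np.sum(w)
        # marginal likelihood of y given tau with mu integrated out
        ll = (
            -0.5 * np.sum(np.log(2 * np.pi * v))
            + 0.5 * np.log(2 * np.pi * V)
            - 0.5 * (np.sum(w * y * y) - mu_hat**2 / V)
        )
        return mu_hat, V, np.exp(ll + log_tau_prior(tau))

    z = integrate.quad(lambda t: parts(t)[2], 0, tau_hi, limit=200)[0]
    mean = integrate.quad(lambda t: parts(t)[0] * parts(t)[2], 0, tau_hi, limit=200)[0] / z
    second = (
        integrate.quad(
            lambda t: (parts(t)[1] + parts(t)[0] ** 2) * parts(t)[2], 0, tau_hi, limit=200
        )[0]
        / z
    )
    return mean, float(np.sqrt(max(second - mean**2, 0.0)))
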