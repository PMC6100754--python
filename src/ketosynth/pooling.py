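"""Bayesian random-effects pooling of several study estimates into one cell.

Model: study estimate ``y_k ~ N(mu, sd_k^2 + tau^2)`` with a flat
improper prior on the overall mean ``mu`` and a named prior on the
between-study standard deviation ``tau``:

* ``uniform`` — tau ~ U(0, 5 * max sd_k);
* ``half_normal`` — tau ~ HN(scale = max sd_k);
* ``dumouchel`` — p(tau) = s0 / (s0 + tau)^2 with
  s0 = sqrt(harmonic mean of sd_k^2), truncated at its 99% prior
  quantile tau = 99 * s0. The truncation is part of the model: with the
  flat mu prior the un-truncated DuMouchel posterior SD of mu diverges
  (logarithmically for two studies), so a stated finite domain is the
  only way to make "pooled SD" well defined.

Inference is deterministic quadrature: conditional on tau the posterior
of mu is an explicit normal (mean = inverse-variance-weighted average,
variance = 1 / sum of weights) with a closed-form marginal likelihood,
and tau is integrated by the trapezoid rule on a 2001-point grid —
uniform in tau for the light-tailed priors, uniform in the prior CDF
u = tau/(s0+tau) for DuMouchel so that both the sharp likelihood region
near zero and the heavy tail are resolved. No Monte Carlo anywhere;
results are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - circular at runtime only
    from .study_data import CellEstimate

__all__ = ["PoolingSpec", "pool_random_effects"]

_PRIORS = ("uniform", "half_normal", "dumouchel")
_GRID = 2001


@dataclass(frozen=True)
class PoolingSpec:
    """Between-study prior choice and optional scale override.

    ``prior_scale`` is the uniform upper bound, half-normal scale or
    DuMouchel s0 respectively; ``None`` applies the automatic rules
    above.
    """

    tau_prior: str = "half_normal"
    prior_scale: float | None = None

    def __post_init__(self) -> None:
        if self.tau_prior not in _PRIORS:
            raise ValueError(
                f"unknown tau prior {self.tau_prior!r}; choose from {_PRIORS}"
            )
        if self.prior_scale is not None and self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")


def _tau_grid_and_logprior(spec: PoolingSpec, sds: np.ndarray):
    """Quadrature nodes, trapezoid weights, and log prior density."""
    if spec.tau_prior == "uniform":
        hi = spec.prior_scale if spec.prior_scale else 5.0 * float(sds.max())
        tau = np.linspace(0.0, hi, _GRID)
        w = np.full(_GRID, tau[1] - tau[0])
        w[0] = w[-1] = w[0] / 2
        logp = np.zeros(_GRID)
    elif spec.tau_prior == "half_normal":
        scale = spec.prior_scale if spec.prior_scale else float(sds.max())
        tau = np.linspace(0.0, 6.0 * scale, _GRID)
        w = np.full(_GRID, tau[1] - tau[0])
        w[0] = w[-1] = w[0] / 2
        logp = -0.5 * (tau / scale) ** 2
    else:  # dumouchel, truncated at the 99% prior quantile
        s0 = (
            spec.prior_scale
            if spec.prior_scale
            else math.sqrt(len(sds) / float(np.sum(1.0 / sds**2)))
        )
        u = np.linspace(0.0, 0.99, _GRID)  # u = tau/(s0+tau), prior CDF
        tau = s0 * u / (1.0 - u)
        du = u[1] - u[0]
        # d tau = s0 / (1-u)^2 du; fold the Jacobian into the weights
        w = s0 / (1.0 - u) ** 2 * du
        w[0], w[-1] = w[0] / 2, w[-1] / 2
        logp = math.log(s0) - 2.0 * np.log(s0 + tau)
    return tau, w, logp


def pool_random_effects(
    estimates: Sequence["CellEstimate"], spec: PoolingSpec | None = None
) -> "CellEstimate":
    """Posterior mean ± SD of the overall effect across studies.

    A single estimate is returned unchanged (pooling of one is the
    identity).
    """
    from .study_data import CellEstimate

    if len(estimates) == 0:
        raise ValueError("need at least one estimate to pool")
    y = np.array([e.ln_mr for e in estimates], dtype=float)
    sds = np.array([e.sd for e in estimates], dtype=float)
    if np.any(sds <= 0):
        raise ValueError("all standard deviations must be positive")
    if len(estimates) == 1:
        return CellEstimate(float(y[0]), float(sds[0]))
    if spec is None:
        spec = PoolingSpec()

    tau, w, logp = _tau_grid_and_logprior(spec, sds)
    v = sds[None, :] ** 2 + tau[:, None] ** 2  # (grid, k)
    wt = 1.0 / v
    wt_sum = wt.sum(axis=1)
    mu_hat = (wt * y[None, :]).sum(axis=1) / wt_sum
    V = 1.0 / wt_sum
    # log marginal likelihood of y given tau, mu integrated under a flat prior
    ll = (
        -0.5 * np.log(2 * np.pi * v).sum(axis=1)
        + 0.5 * np.log(2 * np.pi * V)
        - 0.5 * ((wt * y[None, :] ** 2).sum(axis=1) - mu_hat**2 / V)
    )
    logw = ll + logp
    post = w * np.exp(logw - logw.max())
    z = post.sum()
    mean = float((mu_hat * post).sum() / z)
    second = float(((V + mu_hat**2) * post).sum() / z)
    return CellEstimate(mean, math.sqrt(max(second - mean**2, 0.0)))
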