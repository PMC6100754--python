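"""Catalogue of prior specifications for the species × intervention model.

Each prior is a pair of mean vectors and covariance matrices — one for
the five species effects (alpha) and one for the four intervention
effects (gamma) — plus the common prior on the equal-relative-potency
scale sigma, N(0.5, 0.01 variance) truncated to sigma > 0. Scalar
normal notation N(a, b) is read as mean/variance throughout: this is
what makes sigma's prior imply a 68% potency-deviation band of
exp(0.4) to exp(0.6), and what matches the squared diagonals of the
enthusiastic covariance matrix.

Eleven named specifications span the belief spectrum:

* ``SP1`` / ``SP2`` — skeptical, independent effects with variance 10
  (vague) or 1 (weakly informative), zero means.
* ``FSP`` — fundamentalist-skeptical: means −0.35 on both sides
  (expected halving of survival under ketogenic therapy), variance 1.
* ``RP1``–``RP3`` — relational: correlation 0.9 between KD and CR and
  between KD+ and CR+ (similar metabolic effects); 0.9995 among the
  three mouse strains; RP2 adds mouse–rat correlation 0.9; RP3 adds a
  weak 0.3 human–animal correlation.
* ``MP1`` / ``MP2`` — mechanistic: combination treatments boosted by a
  synergy term eta ~ N(0.3, 0.3) on top of unit-variance monotherapy
  effects (gamma means 0, 0.3, 0, 0.3); MP2 adds the KD–CR
  correlations.
* ``EP`` — enthusiastic: human effect N(0.336, 0.378^2) from published
  case reports, mouse effects N(0.117, 0.08^2) from a meta-analysis of
  mouse survival, correlated 0.0063 across strains; rats N(0, 1).
* ``EP_MP1`` / ``EP_MP2`` — EP's species side with MP1/MP2's
  intervention side.

Where the combination leaves one side unstated (MP's species side, EP's
intervention side) a weakly informative N(0, 1) diagonal is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .study_data import INTERVENTIONS, SPECIES

__all__ = [
    "PRIOR_NAMES",
    "PriorSpec",
    "make_prior",
    "validate_psd",
    "ep_constants",
]

PRIOR_NAMES = (
    "SP1",
    "SP2",
    "FSP",
    "RP1",
    "RP2",
    "RP3",
    "MP1",
    "MP2",
    "EP",
    "EP_MP1",
    "EP_MP2",
)

#: Sigma prior: mean 0.5, variance 0.01 (SD 0.1), truncated to sigma > 0.
SIGMA_PRIOR_MEAN = 0.5
SIGMA_PRIOR_VAR = 0.01


@dataclass(frozen=True)
class PriorSpec:
    """Mean vectors and covariance matrices for one named prior."""

    name: str
    mu_alpha: np.ndarray
    R_alpha: np.ndarray
    mu_gamma: np.ndarray
    R_gamma: np.ndarray
    sigma_prior_mean: float = SIGMA_PRIOR_MEAN
    sigma_prior_var: float = SIGMA_PRIOR_VAR

    def __post_init__(self) -> None:
        mu_a = np.asarray(self.mu_alpha, dtype=float)
        mu_g = np.asarray(self.mu_gamma, dtype=float)
        Ra = np.asarray(self.R_alpha, dtype=float)
        Rg = np.asarray(self.R_gamma, dtype=float)
        if mu_a.shape != (5,) or Ra.shape != (5, 5):
            raise ValueError("species side must be a 5-vector and 5x5 matrix")
        if mu_g.shape != (4,) or Rg.shape != (4, 4):
            raise ValueError("intervention side must be a 4-vector and 4x4 matrix")
        for label, m in (("R_alpha", Ra), ("R_gamma", Rg)):
            ok, lam = validate_psd(m)
            if not ok:
                raise ValueError(f"{label} not positive semidefinite (min eig {lam:.3g})")
            if np.any(np.diag(m) <= 0):
                raise ValueError(f"{label} must have positive diagonal")
        if self.sigma_prior_var <= 0:
            raise ValueError("sigma prior variance must be positive")
        object.__setattr__(self, "mu_alpha", mu_a)
        object.__setattr__(self, "mu_gamma", mu_g)
        object.__setattr__(self, "R_alpha", Ra)
        object.__setattr__(self, "R_gamma", Rg)

    def with_sigma_prior(self, mean: float, var: float) -> "PriorSpec":
        return PriorSpec(
            name=f"{self.name}(sigma~N({mean},{var}))",
            mu_alpha=self.mu_alpha,
            R_alpha=self.R_alpha,
            mu_gamma=self.mu_gamma,
            R_gamma=self.R_gamma,
            sigma_prior_mean=mean,
            sigma_prior_var=var,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(SPECIES),
            "interventions": list(INTERVENTIONS),
            "mu_alpha": self.mu_alpha.tolist(),
            "R_alpha": self.R_alpha.tolist(),
            "mu_gamma": self.mu_gamma.tolist(),
            "R_gamma": self.R_gamma.tolist(),
            "sigma_prior_mean": self.sigma_prior_mean,
            "sigma_prior_var": self.sigma_prior_var,
        }


def validate_psd(matrix: np.ndarray, tol: float = 1e-10) -> tuple[bool, float]:
    """Check symmetric positive semidefiniteness; returns (ok, min eigenvalue)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    lam = float(np.linalg.eigvalsh(m).min())
    return lam >= -tol, lam


def ep_constants() -> tuple[float, float, float, float]:
    """The enthusiastic prior's elicited constants.

    Returns (human mean, human SD, mouse mean, mouse SD) on the ln(MR)
    scale. The human side encodes an expected 40% survival prolongation
    (mean ln 1.4 = 0.336) with 42.9% probability that the MR lies in
    [1.1, 2], giving SD [ln 2 − ln 1.1]/(2 × 0.79) = 0.378. The mouse
    side translates a mouse-survival meta-analysis to mean
    ln(1.124) = 0.117 and SD 0.080.
    """
    human_mean = math.log(1.4)
    human_sd = (math.log(2) - math.log(1.1)) / (2 * 0.79)
    mouse_mean = math.log(1.124)
    mouse_sd = 0.080
    return human_mean, human_sd, mouse_mean, mouse_sd


def _rgamma_relational(v: float = 10.0, c: float = 9.0) -> np.ndarray:
    # KD<->CR and KD+<->CR+ correlated (order: KD, KD+, CR, CR+)
    m = np.diag(np.full(4, v))
    m[0, 2] = m[2, 0] = c
    m[1, 3] = m[3, 1] = c
    return m


def _ralpha_rp(level: int) -> np.ndarray:
    m = np.diag(np.full(5, 10.0))
    mice = [1, 2, 3]
    for a in mice:
        for b in mice:
            if a != b:
                m[a, b] = 9.995
    if level >= 2:  # mice <-> rats correlation 0.9
        for a in mice:
            m[a, 4] = m[4, a] = 9.0
    if level >= 3:  # humans <-> all animals correlation 0.3
        for a in (1, 2, 3, 4):
            m[0, a] = m[a, 0] = 3.0
    return m


def _rgamma_mp1() -> np.ndarray:
    # gamma_2 = gamma_1 + eta, gamma_4 = gamma_3 + eta with eta ~ N(0.3, 0.3)
    return np.diag([1.0, 1.3, 1.0, 1.3])


def _rgamma_mp2() -> np.ndarray:
    m = _rgamma_mp1()
    m[0, 2] = m[2, 0] = 0.99
    m[1, 3] = m[3, 1] = 1.287
    return m


def _ralpha_ep() -> np.ndarray:
    m = np.diag([0.378**2, 0.08**2, 0.08**2, 0.08**2, 1.0])
    for a in (1, 2, 3):
        for b in (1, 2, 3):
            if a != b:
                m[a, b] = 0.0063
    return m


def _mu_alpha_ep() -> np.ndarray:
    return np.array([0.336, 0.117, 0.117, 0.117, 0.0])


_MU_GAMMA_MP = np.array([0.0, 0.3, 0.0, 0.3])


def make_prior(name: str) -> PriorSpec:
    """Build one of the eleven catalogue priors by name."""
    z5, z4 = np.zeros(5), np.zeros(4)
    if name == "SP1":
        return PriorSpec(name, z5, 10.0 * np.eye(5), z4, 10.0 * np.eye(4))
    if name == "SP2":
        return PriorSpec(name, z5, np.eye(5), z4, np.eye(4))
    if name == "FSP":
        return PriorSpec(
            name, np.full(5, -0.35), np.eye(5), np.full(4, -0.35), np.eye(4)
        )
    if name == "RP1":
        return PriorSpec(name, z5, _ralpha_rp(1), z4, _rgamma_relational())
    if name == "RP2":
        return PriorSpec(name, z5, _ralpha_rp(2), z4, _rgamma_relational())
    if name == "RP3":
        return PriorSpec(name, z5, _ralpha_rp(3), z4, _rgamma_relational())
    if name == "MP1":
        return PriorSpec(name, z5, np.eye(5), _MU_GAMMA_MP.copy(), _rgamma_mp1())
    if name == "MP2":
        return PriorSpec(name, z5, np.eye(5), _MU_GAMMA_MP.copy(), _rgamma_mp2())
    if name == "EP":
        return PriorSpec(name, _mu_alpha_ep(), _ralpha_ep(), z4, np.eye(4))
    if name == "EP_MP1":
        return PriorSpec(name, _mu_alpha_ep(), _ralpha_ep(), _MU_GAMMA_MP.copy(), _rgamma_mp1())
    if name == "EP_MP2":
        return PriorSpec(name, _mu_alpha_ep(), _ralpha_ep(), _MU_GAMMA_MP.copy(), _rgamma_mp2())
    raise KeyError(f"unknown prior {name!r}; choose from {PRIOR_NAMES}")
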