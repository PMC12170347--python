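"""Small-area geospatial prevalence model.

Prevalence in each fine areal unit is modelled on the logit scale, for the
youngest (0-9) and oldest (15-19) age groups separately, as

    logit p_i = beta0 + beta_ses * (decile_i - 5.5) + gamma[rem_i] + u_i

with a shared zero-mean Gaussian spatial field u under an exponential
(Matern nu=1/2) covariance sigma_u^2 * exp(-d_ij / rho), and sum-to-zero
remoteness effects gamma.  The middle age group (10-14) is a logit-scale
mixture of the two: eta_mid = w * eta_young + (1 - w) * eta_old, with the
mixing weight w a free parameter.  Counts are binomial in the stated-response
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .hierarchy import AGE_GROUPS, Hierarchy

__all__ = [
    "ModelParams",
    "PriorSpec",
    "gp_covariance",
    "linear_predictor",
    "mixture_predictor",
    "log_joint",
]

_JITTER = 1e-8


@dataclass
class ModelParams:
    """Parameters of the prevalence model.

    gamma is stored as 4 free coordinates; the fifth remoteness effect is
    -sum(free), so sum-to-zero holds by construction.  sigma_u and rho are
    log-parameterised, w logit-parameterised, keeping every coordinate
    unconstrained for sampling.
    """

    beta0_young: float
    beta0_old: float
    beta_ses: float
    gamma_free: np.ndarray  # shape (4,)
    u: np.ndarray  # shape (n_fine,)
    log_sigma_u: float
    log_rho: float
    logit_w: float

    @property
    def gamma(self) -> np.ndarray:
        g = np.asarray(self.gamma_free, dtype=float)
        return np.concatenate([g, [-g.sum()]])

    @property
    def sigma_u(self) -> float:
        return float(np.exp(self.log_sigma_u))

    @property
    def rho(self) -> float:
        return float(np.exp(self.log_rho))

    @property
    def w(self) -> float:
        return float(expit(self.logit_w))

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.beta0_young,
            self.beta0_old,
            self.beta_ses,
            np.array(self.gamma_free, dtype=float),
            np.array(self.u, dtype=float),
            self.log_sigma_u,
            self.log_rho,
            self.logit_w,
        )


@dataclass
class PriorSpec:
    """Normal priors on the unconstrained scalars; uniform on the mix weight.

    Means/sds are on the parameterisation scale (logit for intercepts and
    effects, log for the field hyperparameters, km for the range).
    """

    beta0_young: tuple[float, float] = (0.0, 2.0)
    beta0_old: tuple[float, float] = (0.0, 2.0)
    beta_ses: tuple[float, float] = (0.0, 2.0)
    gamma: tuple[float, float] = (0.0, 2.0)
    log_sigma_u: tuple[float, float] = (0.0, 1.0)
    log_rho: tuple[float, float] = (float(np.log(50.0)), 1.0)

    def __post_init__(self) -> None:
        for name in ("beta0_young", "beta0_old", "beta_ses", "gamma",
                     "log_sigma_u", "log_rho"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"prior sd for {name} must be positive")

    def log_prior_scalars(self, params: ModelParams) -> float:
        """Log prior density of all scalar parameters (w uniform on (0,1))."""

        def _norm(x, m, s):
            return -0.5 * ((x - m) / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)

        lp = 0.0
        for name in ("beta0_young", "beta0_old", "beta_ses"):
            m, s = getattr(self, name)
            lp += _norm(getattr(params, name), m, s)
        m, s = self.gamma
        lp += _norm(np.asarray(params.gamma_free), m, s).sum()
        m, s = self.log_sigma_u
        lp += _norm(params.log_sigma_u, m, s)
        m, s = self.log_rho
        lp += _norm(params.log_rho, m, s)
        w = params.w
        if not (0.0 < w < 1.0):
            return float("-inf")
        return float(lp)

    def prior_means(self) -> dict[str, float]:
        return {
            "beta0_young": self.beta0_young[0],
            "beta0_old": self.beta0_old[0],
            "beta_ses": self.beta_ses[0],
            "gamma": self.gamma[0],
            "log_sigma_u": self.log_sigma_u[0],
            "log_rho": self.log_rho[0],
        }


def gp_covariance(distances: np.ndarray, sigma_u: float, rho: float) -> np.ndarray:
    """Exponential covariance sigma_u^2 exp(-d/rho) with diagonal jitter.

    The jitter (1e-8 * sigma_u^2) keeps the Cholesky factorisation stable
    for near-duplicate centroids.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distances must be a symmetric square matrix")
    cov = sigma_u**2 * np.exp(-d / rho)
    cov[np.diag_indices_from(cov)] += _JITTER * sigma_u**2
    return cov


def linear_predictor(params: ModelParams, h: Hierarchy, age_model: str) -> np.ndarray:
    """Logit prevalence per fine unit for the young or old age model."""
    if age_model == "young":
        b0 = params.beta0_young
    elif age_model == "old":
        b0 = params.beta0_old
    else:
        raise ValueError("age_model must be 'young' or 'old'")
    gamma = params.gamma
    return (
        b0
        + params.beta_ses * (h.ses_decile - 5.5)
        + gamma[h.remoteness_codes]
        + params.u
    )


def mixture_predictor(
    eta_young: np.ndarray, eta_old: np.ndarray, w: float
) -> np.ndarray:
    """Middle-age logit prevalence: convex combination on the logit scale."""
    if not (0.0 < w < 1.0):
        raise ValueError("w must be in (0, 1)")
    return w * np.asarray(eta_young) + (1.0 - w) * np.asarray(eta_old)


def eta_by_age(params: ModelParams, h: Hierarchy) -> np.ndarray:
    """Stacked (n_fine, 3) logit prevalences in AGE_GROUPS order."""
    ey = linear_predictor(params, h, "young")
    eo = linear_predictor(params, h, "old")
    em = params.w * ey + (1.0 - params.w) * eo
    return np.column_stack([ey, em, eo])


def log_joint(
    params: ModelParams,
    y: np.ndarray,
    n_stated: np.ndarray,
    h: Hierarchy,
    priors: PriorSpec,
) -> float:
    """Log joint density of counts, field and scalar parameters.

    Sum of the binomial log-likelihood of the latent counts over fine units
    and age groups, the Gaussian-process log density of the field u, and the
    scalar priors.  y and n_stated are (n_fine, 3) in AGE_GROUPS order.
    """
    y = np.asarray(y)
    n = np.asarray(n_stated)
    if (y < 0).any() or (y > n).any():
        raise ValueError("need 0 <= y <= n_stated elementwise")
    eta = eta_by_age(params, h)
    p = expit(eta)
    ll = float(stats.binom.logpmf(y, n, p).sum())

    cov = gp_covariance(h.distances(), params.sigma_u, params.rho)
    c, lower = cho_factor(cov, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    alpha = cho_solve((c, lower), params.u)
    n_fine = h.n_fine
    ll += -0.5 * (
        n_fine * np.log(2 * np.pi) + logdet + float(params.u @ alpha)
    )
    ll += priors.log_prior_scalars(params)
    return ll
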