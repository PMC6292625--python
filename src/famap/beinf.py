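"""Zero-and-one-inflated beta distribution (BEINF) primitives.

A proportion y in [0, 1] with point masses at the endpoints is modelled
by a mixed discrete-continuous distribution with four parameters
(mu, sigma, nu, tau):

* interior values 0 < y < 1 follow Beta(alpha, beta) with
  alpha = mu (1 - sigma^2) / sigma^2 and
  beta = (1 - mu)(1 - sigma^2) / sigma^2, so mu is the beta mean and
  sigma in (0, 1) is a dispersion parameter;
* the endpoint masses are P0 = nu / (1 + nu + tau) at y = 0 and
  P1 = tau / (1 + nu + tau) at y = 1, with nu, tau >= 0;
* the expectation is E(y) = (tau + mu) / (1 + nu + tau).

The zero-inflated-only variant (``beinf0``) fixes tau = 0 and is used
when the sample contains no or very few exact ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["InflatedBetaParams", "beinf_shape", "beinf_probs",
           "beinf_expectation", "beinf_loglik", "beinf_rvs"]


def beinf_shape(mu, sigma):
    """Beta shape parameters (alpha, beta) from the (mu, sigma) pair."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1) or np.any(sigma <= 0) or np.any(sigma >= 1):
        raise ValueError("mu and sigma must lie strictly in (0, 1)")
    s2 = sigma ** 2
    alpha = mu * (1.0 - s2) / s2
    beta = (1.0 - mu) * (1.0 - s2) / s2
    return alpha, beta


def beinf_probs(nu, tau):
    """Endpoint masses (P0, P1) from the inflation parameters (nu, tau)."""
    nu = np.asarray(nu, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(nu < 0) or np.any(tau < 0):
        raise ValueError("nu and tau must be non-negative")
    denom = 1.0 + nu + tau
    return nu / denom, tau / denom


def beinf_expectation(mu, nu, tau):
    """E(y) = (tau + mu) / (1 + nu + tau)."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must lie strictly in (0, 1)")
    nu = np.asarray(nu, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(nu < 0) or np.any(tau < 0):
        raise ValueError("nu and tau must be non-negative")
    return (tau + mu) / (1.0 + nu + tau)


@dataclass
class InflatedBetaParams:
    """Per-observation parameters with their derived quantities."""
    mu: float
    sigma: float
    nu: float
    tau: float = 0.0

    @property
    def alpha(self) -> float:
        return float(beinf_shape(self.mu, self.sigma)[0])

    @property
    def beta(self) -> float:
        return float(beinf_shape(self.mu, self.sigma)[1])

    @property
    def p0(self) -> float:
        return float(beinf_probs(self.nu, self.tau)[0])

    @property
    def p1(self) -> float:
        return float(beinf_probs(self.nu, self.tau)[1])

    @property
    def mean(self) -> float:
        return float(beinf_expectation(self.mu, self.nu, self.tau))


def beinf_loglik(y, mu, sigma, nu, tau=0.0, family: str = "beinf") -> float:
    """Total log-likelihood of observations under per-observation parameters.

    ``family`` is ``"beinf"`` (both endpoint masses) or ``"beinf0"``
    (tau fixed at 0; exact ones in the data are an error because the
    model assigns them probability zero).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("observations must lie in [0, 1]")
    if family not in ("beinf", "beinf0"):
        raise ValueError(f"unknown family {family!r}")
    if family == "beinf0":
        if np.any(y == 1.0):
            raise ValueError("family 'beinf0' cannot score y == 1")
        tau = 0.0
    mu, sigma, nu, tau = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu, sigma, nu, tau)))
    mu, sigma, nu, tau = (np.broadcast_to(a, y.shape)
                          for a in (mu, sigma, nu, tau))

    p0, p1 = beinf_probs(nu, tau)
    ll = np.empty_like(y)
    at0 = y == 0.0
    at1 = y == 1.0
    mid = ~(at0 | at1)
    with np.errstate(divide="ignore"):
        ll[at0] = np.log(p0[at0])
        ll[at1] = np.log(p1[at1])
    if np.any(mid):
        alpha, beta = beinf_shape(mu[mid], sigma[mid])
        ll[mid] = np.log1p(-(p0[mid] + p1[mid])) \
            + stats.beta.logpdf(y[mid], alpha, beta)
    return float(np.sum(ll))


def beinf_rvs(mu, sigma, nu, tau, size=None,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw from the mixture: 0 w.p. P0, 1 w.p. P1, else Beta(alpha, beta)."""
    rng = rng if rng is not None else np.random.default_rng()
    mu, sigma, nu, tau = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu, sigma, nu, tau)))
    if size is None:
        size = mu.shape if mu.shape else (1,)
    mu, sigma, nu, tau = (np.broadcast_to(a, size) for a in (mu, sigma, nu, tau))
    p0, p1 = beinf_probs(nu, tau)
    u = rng.uniform(size=size)
    alpha, beta = beinf_shape(mu, sigma)
    y = rng.beta(alpha, beta, size=size)
    y = np.where(u < p0, 0.0, y)
    y = np.where(u >= 1.0 - p1, 1.0, y)
    return y
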