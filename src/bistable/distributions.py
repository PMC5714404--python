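"""Inverse-Gaussian and Normal-Inverse-Gaussian primitives.

Dominance times of a drift-diffusion (Brownian motion with drift ``nu``
between absorbing borders ``+-b``) are Inverse Gaussian (IG) distributed.
This module carries the IG in the behavioural ``(mu, sigma)``
(mean, standard deviation) parameterization used for data description, the
mechanistic ``(b, nu)`` barrier/drift parameterization, and the exact
conversions between the two:

    mu = 2 b / nu,        sigma^2 = 2 b / nu^3
    b  = (1/2) sqrt(mu^3 / sigma^2),   nu = sqrt(mu) / sigma

so that the coefficient of variation is ``CV = sigma/mu = 1/sqrt(2 b nu)``.

The Normal Inverse Gaussian (NIG) law arises as the position of an
independent Brownian motion evaluated at an IG-distributed random time; it
governs the marginal state-transition probabilities of the hierarchical
model (module :mod:`bistable.hbm`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IGParams",
    "BarrierDriftParams",
    "NIGSpec",
    "ig_pdf",
    "ig_logpdf",
    "ig_sample",
    "ig_loglik",
    "ig_mle",
    "ig_to_barrier",
    "barrier_to_ig",
    "nig_cdf",
    "normal_cdf",
]


class ParameterError(ValueError):
    """Invalid distribution parameters."""


class DomainError(ValueError):
    """Evaluation point outside the support."""


class DegenerateSampleError(ValueError):
    """Sample admits only a degenerate (sigma = 0) IG fit."""


@dataclass(frozen=True)
class IGParams:
    """Inverse Gaussian law in (mean, standard deviation) form.

    Parameters
    ----------
    mu : float
        Mean dominance time in seconds, > 0.
    sigma : float
        Standard deviation of dominance times in seconds, > 0.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ParameterError(f"mu must be positive and finite, got {self.mu}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ParameterError(f"sigma must be positive and finite, got {self.sigma}")

    @property
    def cv(self) -> float:
        """Coefficient of variation sigma/mu."""
        return self.sigma / self.mu

    @property
    def lam(self) -> float:
        """Classical IG shape parameter lambda = mu^3/sigma^2."""
        return self.mu**3 / self.sigma**2


@dataclass(frozen=True)
class BarrierDriftParams:
    """Drift-diffusion parameters: border half-distance ``b`` and drift ``nu``.

    ``b`` is in (dimensionless) activity units, ``nu`` in activity units per
    second; the implied mean first-passage time is ``2 b / nu``.
    """

    b: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.b > 0 and math.isfinite(self.b)):
            raise ParameterError(f"b must be positive and finite, got {self.b}")
        if not (self.nu > 0 and math.isfinite(self.nu)):
            raise ParameterError(f"nu must be positive and finite, got {self.nu}")

    @property
    def cv(self) -> float:
        """CV of the first-passage-time law, 1/sqrt(2 b nu)."""
        return 1.0 / math.sqrt(2.0 * self.b * self.nu)


@dataclass(frozen=True)
class NIGSpec:
    """Normal Inverse Gaussian in (loc, alpha, beta, delta) form.

    alpha is the tail steepness, beta the asymmetry (|beta| < alpha) and
    delta the scale.  For the position of a Brownian motion with drift
    ``beta`` at an independent IG(2*border/drift, ...) time, the tuple is
    ``(0, sqrt(drift^2 + beta^2), beta, 2*border)``.
    """

    loc: float
    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.alpha > abs(self.beta)):
            raise ParameterError(
                f"need alpha > |beta|, got alpha={self.alpha}, beta={self.beta}"
            )
        if not (self.delta > 0):
            raise ParameterError(f"delta must be positive, got {self.delta}")


def _ig_frozen(params: IGParams):
    lam = params.lam
    return stats.invgauss(params.mu / lam, scale=lam)


def ig_pdf(x, params: IGParams):
    """IG(mu, sigma) density at ``x`` (1/s).

    Raises :class:`DomainError` for any ``x <= 0``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("ig_pdf requires x > 0")
    return _ig_frozen(params).pdf(x)


def ig_logpdf(x, params: IGParams):
    """Log-density of IG(mu, sigma), vectorized; requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("ig_logpdf requires x > 0")
    mu, sig2 = params.mu, params.sigma**2
    return 0.5 * (
        np.log(mu**3 / (2.0 * np.pi * sig2 * x**3))
        - (mu / sig2) * (x - mu) ** 2 / x
    )


def ig_loglik(d, params: IGParams) -> float:
    """Total IG log-likelihood of the sample ``d``."""
    return float(np.sum(ig_logpdf(d, params)))


def ig_sample(params: IGParams, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. IG(mu, sigma) variates.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = params.lam
    # numpy's wald sampler is IG(mean, lambda)
    return rng.wald(params.mu, lam, size=n)


def ig_mle(d) -> IGParams:
    """Maximum-likelihood IG fit: mu_hat = sample mean, and

    sigma_hat = sqrt( mu_hat^3 * (1/n) * sum(1/d_i - 1/mu_hat) ).

    Raises :class:`DegenerateSampleError` when the reciprocal spread
    vanishes (all observations equal), :class:`DomainError` for
    non-positive observations.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-d sample with n >= 2")
    if np.any(d <= 0):
        raise DomainError("dominance times must be positive")
    mu = float(d.mean())
    recip_spread = float(np.mean(1.0 / d) - 1.0 / mu)
    if recip_spread <= 0:
        raise DegenerateSampleError(
            "sample has no reciprocal spread (all values equal); sigma_hat = 0"
        )
    sigma = math.sqrt(mu**3 * recip_spread)
    return IGParams(mu=mu, sigma=sigma)


def ig_to_barrier(params: IGParams) -> BarrierDriftParams:
    """Convert (mu, sigma) to the barrier/drift form.

    b = (1/2) sqrt(mu^3/sigma^2), nu = sqrt(mu)/sigma; exact inverse of
    :func:`barrier_to_ig`.
    """
    b = 0.5 * math.sqrt(params.mu**3 / params.sigma**2)
    nu = math.sqrt(params.mu) / params.sigma
    return BarrierDriftParams(b=b, nu=nu)


def barrier_to_ig(params: BarrierDriftParams) -> IGParams:
    """Convert (b, nu) to (mu, sigma): mu = 2b/nu, sigma = sqrt(2b/nu^3)."""
    mu = 2.0 * params.b / params.nu
    sigma = math.sqrt(2.0 * params.b / params.nu**3)
    return IGParams(mu=mu, sigma=sigma)


def _nig_frozen(spec: NIGSpec):
    # scipy's norminvgauss uses a = alpha*delta, b = beta*delta, scale = delta
    return stats.norminvgauss(
        spec.alpha * spec.delta, spec.beta * spec.delta, loc=spec.loc, scale=spec.delta
    )


def nig_cdf(x, spec: NIGSpec):
    """NIG distribution function at ``x``."""
    return _nig_frozen(spec).cdf(np.asarray(x, dtype=float))


def normal_cdf(x, mean: float, var: float):
    """Distribution function Phi_{mean, var}(x) of the normal law."""
    if not var > 0:
        raise ParameterError(f"variance must be positive, got {var}")
    from scipy.special import ndtr

    return ndtr((np.asarray(x, dtype=float) - mean) / math.sqrt(var))
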