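"""Skew-Gaussian distribution used as the prior for SNP dominance effects.

The parameterization is the additive (Sahu-type) stochastic
representation

    X = lam * |Z0| + sigma * Z1,      Z0, Z1 iid N(0, 1),

whose latent half-normal |Z0| is exactly the per-SNP auxiliary variable
the Gibbs sampler introduces.  lam = 0 recovers N(0, sigma2); the mean is
lam*sqrt(2/pi) and the variance sigma2 + lam2*(1 - 2/pi).  This family
coincides with the common (Azzalini) skew normal under
omega2 = sigma2 + lam2, alpha = lam/sigma, which provides an independent
cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

__all__ = [
    "SkewNormalParams",
    "sn_pdf",
    "sn_mean",
    "sn_variance",
    "sn_sample",
    "truncnorm_nonneg_sample",
]


@dataclass(frozen=True)
class SkewNormalParams:
    """Asymmetry lam (trait units per auxiliary unit) and scale variance sigma2."""

    lam: float
    sigma2: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")


def sn_pdf(x, params: SkewNormalParams):
    """Density f(x) = 2 phi(x; 0, s2+lam2) Phi(lam x / (s sqrt(s2+lam2)))."""
    lam, s2 = params.lam, params.sigma2
    omega2 = s2 + lam * lam
    x = np.asarray(x, dtype=float)
    return (
        2.0
        * stats.norm.pdf(x, scale=sqrt(omega2))
        * stats.norm.cdf(lam * x / (sqrt(s2) * sqrt(omega2)))
    )


def sn_mean(params: SkewNormalParams) -> float:
    return params.lam * sqrt(2.0 / np.pi)


def sn_variance(params: SkewNormalParams) -> float:
    """Full variance of the distribution (not the scale parameter sigma2)."""
    return params.sigma2 + params.lam**2 * (1.0 - 2.0 / np.pi)


def sn_sample(n: int, params: SkewNormalParams, rng: np.random.Generator):
    """Draw n variates via the half-normal representation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    return params.lam * np.abs(z0) + sqrt(params.sigma2) * z1


def truncnorm_nonneg_sample(mean, var, rng: np.random.Generator, size=None):
    """Draw from N(mean, var) restricted to [0, inf), stable for mean << 0.

    Uses scipy's truncated normal (inverse-CDF based), which remains
    accurate far into the lower tail where naive rejection would stall
    and naive CDF inversion would underflow.
    """
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("var must be > 0")
    sd = np.sqrt(var)
    a = (0.0 - np.asarray(mean, dtype=float)) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
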