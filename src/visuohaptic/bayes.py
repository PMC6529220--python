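"""Scaled JZS (Jeffreys-Zellner-Siow) Bayes factors for t-tests and regression.

The default-prior Bayes factor places a Cauchy prior with scale ``r`` on the
standardized effect size (equivalently, a normal prior whose variance ``g``
has an inverse-gamma(1/2, r^2/2) mixing distribution) and Jeffreys priors on
nuisance parameters. Marginalizing analytically over everything but ``g``
leaves a one-dimensional integral,

    BF10 = int_0^inf (1 + N g)^(-1/2)
           [1 + t^2 / ((1 + N g) nu)]^(-(nu+1)/2) pi(g) dg
           / [1 + t^2 / nu]^(-(nu+1)/2),

with ``N`` the (effective) sample size and ``nu`` the degrees of freedom:
N = n, nu = n - 1 for one-sample/paired; N = n1 n2/(n1+n2), nu = n1+n2-2 for
two-sample. For regression with ``p`` covariates and coefficient of
determination R^2, the Zellner-Siow mixture-of-g form (Liang et al.) is

    BF10 = int_0^inf (1 + g)^((n-1-p)/2) [1 + g (1 - R^2)]^(-(n-1)/2)
           pi_n(g) dg,

with pi_n an inverse-gamma(1/2, n/2) prior on g.

Integrals are evaluated by adaptive quadrature after the change of variables
g = u/(1-u) mapping (0, inf) to (0, 1), at absolute tolerance 1e-8. The
default scale is sqrt(2)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, pi

import numpy as np
from scipy import integrate

from .exceptions import DataError, IntegrationError

DEFAULT_SCALE = float(np.sqrt(2.0) / 2.0)
_QUAD_TOL = 1e-8


@dataclass(frozen=True)
class BFResult:
    bf10: float
    scale_r: float
    t: float
    method: str  # one_sample | paired | two_sample | regression
    n: float  # effective sample size (or n for regression)
    df: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def _invgamma_half_logpdf(g, scale_sq):
    # InverseGamma(shape=1/2, scale=scale_sq/2) density, log form
    return (
        0.5 * log(scale_sq / 2.0)
        - lgamma(0.5)
        - 1.5 * np.log(g)
        - scale_sq / (2.0 * g)
    )


def _quad_unit(f) -> float:
    """Integrate f(g) over (0, inf) via g = u/(1-u)."""
    def h(u):
        g = u / (1.0 - u)
        return f(g) / (1.0 - u) ** 2

    val, err = integrate.quad(h, 0.0, 1.0, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200)
    if not np.isfinite(val) or (val > 0 and err > max(_QUAD_TOL, 1e-6 * abs(val))):
        raise IntegrationError(f"quadrature did not converge (value={val}, err={err})")
    return val


def _jzs_bf_from_t(t: float, n_eff: float, nu: float, scale_r: float) -> float:
    t2 = float(t) ** 2
    log_null = -(nu + 1.0) / 2.0 * np.log1p(t2 / nu)

    def integrand(g):
        if g <= 0:
            return 0.0
        log_alt = (
            -0.5 * np.log1p(n_eff * g)
            - (nu + 1.0) / 2.0 * np.log1p(t2 / ((1.0 + n_eff * g) * nu))
        )
        return np.exp(log_alt - log_null + _invgamma_half_logpdf(g, scale_r**2))

    return _quad_unit(integrand)


def jzs_bf_one_sample(
    t: float, n: int, scale_r: float = DEFAULT_SCALE, paired: bool = False
) -> BFResult:
    """JZS Bayes factor for a one-sample (or paired-difference) t statistic."""
    if n < 2:
        raise DataError("need n >= 2")
    if not np.isfinite(t):
        raise DataError("t must be finite")
    bf = _jzs_bf_from_t(t, float(n), float(n - 1), scale_r)
    return BFResult(bf, scale_r, float(t), "paired" if paired else "one_sample", n, n - 1)


def jzs_bf_two_sample(
    t: float, n1: int, n2: int, scale_r: float = DEFAULT_SCALE
) -> BFResult:
    """JZS Bayes factor for an independent two-sample t statistic, with
    effective sample size n1*n2/(n1+n2)."""
    if n1 < 2 or n2 < 2:
        raise DataError("need n1, n2 >= 2")
    if not np.isfinite(t):
        raise DataError("t must be finite")
    n_eff = n1 * n2 / (n1 + n2)
    bf = _jzs_bf_from_t(t, n_eff, float(n1 + n2 - 2), scale_r)
    return BFResult(bf, scale_r, float(t), "two_sample", n_eff, n1 + n2 - 2)


def jzs_regression_bf(r_squared: float, n: int, n_covariates: int) -> BFResult:
    """Zellner-Siow mixture-of-g Bayes factor for a regression with
    ``n_covariates`` covariates against the intercept-only null."""
    if not 0.0 <= r_squared < 1.0:
        raise DataError("need 0 <= R^2 < 1")
    if n <= n_covariates + 1:
        raise DataError("need n > n_covariates + 1")
    p = n_covariates

    def integrand(g):
        if g <= 0:
            return 0.0
        log_term = (n - 1 - p) / 2.0 * np.log1p(g) - (n - 1) / 2.0 * np.log1p(
            g * (1.0 - r_squared)
        )
        return np.exp(log_term + _invgamma_half_logpdf(g, float(n)))

    bf = _quad_unit(integrand)
    return BFResult(bf, np.nan, np.nan, "regression", float(n), n - 1 - p)
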