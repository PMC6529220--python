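"""The rectified exponential-binomial model of cross-task performance.

Across participants, familiarity accuracy (fraction correct ``f_c = Tc/T``
over ``T`` two-alternative trials) rises with haptic pulling performance
(the Pearson correlation ``rho`` between pulling and breakage forces)
according to a rectified saturating exponential:

    Tc ~ Binomial(P(rho), T)
    P(rho) = beta0                                   if rho <= 0
           = beta1 + (beta0 - beta1) * exp(-rho/lam) if rho > 0

``beta0`` is the baseline accuracy of participants with chance-or-worse
pulling performance, ``beta1`` the asymptotic accuracy as rho -> infinity, and
``lam`` the rate of the rise. The model is phenomenological: it encodes a
common latent cause behind both performances, a baseline independent of rho
for non-learners, and conditional independence of trials.

This module provides maximum-likelihood fitting with multi-start bounded
optimization (:class:`RectifiedExponentialBinomial`), the nested null model of
a constant success probability, the likelihood-ratio test (df=2), Monte-Carlo
profile-likelihood confidence bands around the fitted curve, a Laplace
approximation of the log10 Bayes factor against the null, and the
range-coverage summary (P(1) - P(0)) / 0.5.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from scipy.stats import qmc

from .exceptions import (
    DataError,
    DataMismatchError,
    DegenerateBandError,
    NonConvergenceError,
    NumericalCurvatureError,
)

_EPS_P = 1e-9  # probability clamp before logs
BETA_BOUNDS = (1e-4, 1.0 - 1e-4)
LAM_BOUNDS = (1e-3, 10.0)


@dataclass(frozen=True)
class REFBParams:
    """(beta0, beta1, lam): baseline, asymptote, exponential rate."""

    beta0: float
    beta1: float
    lam: float

    def __post_init__(self):
        if not (0.0 <= self.beta0 <= 1.0 and 0.0 <= self.beta1 <= 1.0):
            raise DataError("beta0 and beta1 must lie in [0, 1]")
        if self.lam <= 0:
            raise DataError("lam must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.lam])


def refb_probability(params, rho):
    """Success probability P(rho); continuous at rho = 0.

    ``params`` may be an :class:`REFBParams` or any (beta0, beta1, lam)
    triple; ``rho`` scalar or array.
    """
    if isinstance(params, REFBParams):
        b0, b1, lam = params.beta0, params.beta1, params.lam
    else:
        b0, b1, lam = params
    rho = np.asarray(rho, dtype=float)
    p = np.where(rho <= 0, b0, b1 + (b0 - b1) * np.exp(-np.maximum(rho, 0.0) / lam))
    return p if p.ndim else float(p)


def _coerce_data(data):
    """Accept a list of (rho, Tc, T) triples, a DataFrame, or an (rho, tc, t)
    array tuple; return float/int arrays."""
    if isinstance(data, pd.DataFrame):
        rho = data["rho"].to_numpy(float)
        tc = data["T_c"].to_numpy(int) if "T_c" in data else data["Tc"].to_numpy(int)
        t = data["T"].to_numpy(int)
    elif isinstance(data, tuple) and len(data) == 3:
        rho, tc, t = (np.asarray(a) for a in data)
    else:
        arr = np.asarray(list(data), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise DataError("data must be (rho, Tc, T) triples")
        rho, tc, t = arr[:, 0], arr[:, 1], arr[:, 2]
    rho = np.asarray(rho, dtype=float)
    tc = np.asarray(tc, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any((tc < 0) | (tc > t)) or np.any(t < 1):
        raise DataError("need 0 <= Tc <= T and T >= 1")
    if np.any(np.round(tc) != tc) or np.any(np.round(t) != t):
        raise DataError("Tc and T must be integer counts")
    return rho, tc, t


def _fingerprint(rho, tc, t) -> str:
    h = hashlib.sha1()
    for a in (rho, tc, t):
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()[:16]


def refb_loglik(params, data) -> float:
    """Binomial log-likelihood of the data under ``params`` (includes the
    binomial coefficient, so absolute marginal-likelihood comparisons are
    well-defined; it cancels in likelihood ratios)."""
    rho, tc, t = _coerce_data(data)
    p = np.clip(refb_probability(params, rho), _EPS_P, 1.0 - _EPS_P)
    coef = gammaln(t + 1) - gammaln(tc + 1) - gammaln(t - tc + 1)
    return float(np.sum(coef + tc * np.log(p) + (t - tc) * np.log1p(-p)))


@dataclass
class CIBand:
    """Pointwise confidence band around the fitted curve."""

    rho_grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    n_samples: int
    df: int
    seed: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rho": self.rho_grid,
                "fit": self.fitted,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class NullREBResults:
    """Closed-form fit of the nested null model: constant success probability
    (beta1 = beta0, lam without effect)."""

    p_hat: float
    llf: float
    hessian: np.ndarray  # 1x1 curvature of the negative log-likelihood
    nobs: int
    data_ref: str
    _data: tuple = field(repr=False, default=None)

    @property
    def df_model(self) -> int:
        return 1


class RectifiedExponentialBinomial:
    """Model object tying (rho_i, Tc_i, T_i) data to the rectified
    exponential-binomial likelihood.

    Parameters
    ----------
    rho : array-like
        Per-participant pulling correlation, in [-1, 1].
    successes, trials : array-like of int
        Correct and total familiarity-trial counts per participant.

    Examples
    --------
    >>> model = RectifiedExponentialBinomial.from_triples(data)
    >>> res = model.fit(seed=0)
    >>> res.params.beta1, res.lr_test()[2], res.range_coverage()
    """

    def __init__(self, rho, successes, trials):
        self.rho, self.tc, self.t = _coerce_data((rho, successes, trials))
        if len(self.rho) < 1:
            raise DataError("need at least one participant")
        self.nobs = len(self.rho)
        self.data_ref = _fingerprint(self.rho, self.tc, self.t)
        self._coef = float(
            np.sum(gammaln(self.t + 1) - gammaln(self.tc + 1) - gammaln(self.t - self.tc + 1))
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_triples(cls, data) -> "RectifiedExponentialBinomial":
        rho, tc, t = _coerce_data(data)
        return cls(rho, tc, t)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, rho_col="rho", successes_col="T_c", trials_col="T"
    ) -> "RectifiedExponentialBinomial":
        return cls(df[rho_col], df[successes_col], df[trials_col])

    # -- likelihood --------------------------------------------------------

    def loglike(self, params) -> float:
        p = np.clip(refb_probability(params, self.rho), _EPS_P, 1.0 - _EPS_P)
        return self._coef + float(
            np.sum(self.tc * np.log(p) + (self.t - self.tc) * np.log1p(-p))
        )

    def _negll_and_grad(self, x):
        b0, b1, lam = x
        pos = self.rho > 0
        e = np.exp(-np.where(pos, self.rho, 0.0) / lam)
        p = np.where(pos, b1 + (b0 - b1) * e, b0)
        p = np.clip(p, _EPS_P, 1.0 - _EPS_P)
        ll = self._coef + float(
            np.sum(self.tc * np.log(p) + (self.t - self.tc) * np.log1p(-p))
        )
        dldp = self.tc / p - (self.t - self.tc) / (1.0 - p)
        dpdb0 = np.where(pos, e, 1.0)
        dpdb1 = np.where(pos, 1.0 - e, 0.0)
        dpdlam = np.where(pos, (b0 - b1) * e * self.rho / lam**2, 0.0)
        grad = -np.array(
            [np.sum(dldp * dpdb0), np.sum(dldp * dpdb1), np.sum(dldp * dpdlam)]
        )
        return -ll, grad

    # -- fitting -----------------------------------------------------------

    def _moment_start(self) -> np.ndarray:
        neg = self.rho <= 0
        if neg.any():
            b0 = np.clip(self.tc[neg].sum() / self.t[neg].sum(), *BETA_BOUNDS)
        else:
            b0 = np.clip(self.tc.sum() / self.t.sum(), *BETA_BOUNDS)
        hi = self.rho >= np.quantile(self.rho, 0.75)
        b1 = np.clip(self.tc[hi].sum() / self.t[hi].sum(), *BETA_BOUNDS)
        return np.array([b0, b1, 0.3])

    def fit(self, n_starts: int = 20, seed: int = 0) -> "REBResults":
        """Maximum-likelihood fit via bounded quasi-Newton (L-BFGS-B) from
        ``n_starts`` Latin-hypercube starts plus a moment-based start; ties
        broken by highest log-likelihood then smallest lam."""
        if self.nobs < 3:
            raise DataError("fitting the full model needs at least 3 participants")
        if np.ptp(self.rho) == 0:
            warnings.warn("degenerate rho spread: curve parameters weakly identified")
        bounds = [BETA_BOUNDS, BETA_BOUNDS, LAM_BOUNDS]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        sampler = qmc.LatinHypercube(d=3, seed=seed)
        starts = [self._moment_start()]
        starts += list(lo + sampler.random(max(n_starts - 1, 1)) * (hi - lo))
        best = None
        n_ok = 0
        fails = []
        for x0 in starts:
            try:
                res = optimize.minimize(
                    self._negll_and_grad,
                    x0,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                )
            except Exception as err:  # pragma: no cover - defensive
                fails.append(str(err))
                continue
            if not np.isfinite(res.fun):
                fails.append("non-finite objective")
                continue
            n_ok += 1
            cand = (res.fun, res.x[2], res.x, bool(res.success))
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        if best is None or n_ok == 0:
            raise NonConvergenceError(
                "all optimizer starts failed", {"failures": fails}
            )
        negll, _, xhat, success = best
        params = REFBParams(*np.clip(xhat, lo, hi))
        hess = self._numerical_hessian(xhat)
        identifiable = bool(np.any(self.rho > 0))
        at_bounds = bool(np.any(np.isclose(xhat, lo)) or np.any(np.isclose(xhat, hi)))
        if not identifiable:
            warnings.warn(
                "all rho <= 0: lam (and beta1) are unidentifiable; "
                "fit reflects the rectified branch only"
            )
        return REBResults(
            model=self,
            params=params,
            llf=-negll,
            hessian=hess,
            converged=success and n_ok > 0,
            n_starts=len(starts),
            identifiable=identifiable,
            at_bounds=at_bounds,
            data_ref=self.data_ref,
        )

    def fit_null(self) -> NullREBResults:
        """Closed-form fit of the constant-probability null: pooled rate."""
        p_hat = float(np.clip(self.tc.sum() / self.t.sum(), *BETA_BOUNDS))
        llf = self.loglike((p_hat, p_hat, 1.0))
        p = np.clip(p_hat, _EPS_P, 1 - _EPS_P)
        curv = float(np.sum(self.tc / p**2 + (self.t - self.tc) / (1 - p) ** 2))
        return NullREBResults(
            p_hat=p_hat,
            llf=llf,
            hessian=np.array([[curv]]),
            nobs=self.nobs,
            data_ref=self.data_ref,
            _data=(self.rho, self.tc, self.t),
        )

    def _numerical_hessian(self, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central finite-difference Hessian of the negative log-likelihood
        (step relative where the parameter exceeds 1)."""
        f = lambda z: -self.loglike(z)
        n = len(x)
        h = np.array([step * max(1.0, abs(v)) for v in x])
        H = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                if i == j:
                    H[i, i] = (
                        f(_pert(x, i, h[i])) - 2 * f(x) + f(_pert(x, i, -h[i]))
                    ) / h[i] ** 2
                else:
                    fpp = f(_pert(_pert(x, i, h[i]), j, h[j]))
                    fpm = f(_pert(_pert(x, i, h[i]), j, -h[j]))
                    fmp = f(_pert(_pert(x, i, -h[i]), j, h[j]))
                    fmm = f(_pert(_pert(x, i, -h[i]), j, -h[j]))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        return 0.5 * (H + H.T)


def _pert(x, i, d):
    y = np.array(x, dtype=float)
    y[i] += d
    return y


@dataclass
class REBResults:
    """Results of a rectified exponential-binomial maximum-likelihood fit."""

    model: RectifiedExponentialBinomial
    params: REFBParams
    llf: float
    hessian: np.ndarray  # 3x3 curvature of the negative log-likelihood
    converged: bool
    n_starts: int
    identifiable: bool
    at_bounds: bool
    data_ref: str

    # -- predictions -------------------------------------------------------

    def predict(self, rho):
        """Fitted success probability P(rho)."""
        return refb_probability(self.params, rho)

    def range_coverage(self) -> float:
        """Fraction of the possible familiarity range (0.5..1) traversed as
        rho goes from 0 to 1: (P(1) - P(0)) / 0.5."""
        return (self.predict(1.0) - self.predict(0.0)) / 0.5

    # -- inference ---------------------------------------------------------

    def lr_test(self, null: NullREBResults | None = None):
        """Likelihood-ratio test of the constant-probability null.

        Returns (chi2, df, p) with df = 2 (beta1 and lam drop out under the
        null); the statistic is clipped at 0.
        """
        if null is None:
            null = self.model.fit_null()
        if null.data_ref != self.data_ref:
            raise DataMismatchError("full and null fits are not on the same data")
        chi2 = max(0.0, 2.0 * (self.llf - null.llf))
        p = float(stats.chi2.sf(chi2, df=2))
        return chi2, 2, p

    def laplace_log10_bf(self, null: NullREBResults | None = None) -> float:
        """log10 Bayes factor (full vs constant null) by Laplace approximation:
        each marginal likelihood is the maximized likelihood corrected by half
        the log-determinant of the negative log-likelihood Hessian at the
        optimum (constant 2*pi factors cancel or do not scale with the data
        and are ignored)."""
        if null is None:
            null = self.model.fit_null()
        if null.data_ref != self.data_ref:
            raise DataMismatchError("full and null fits are not on the same data")
        for H, label in ((self.hessian, "full"), (null.hessian, "null")):
            if np.any(np.linalg.eigvalsh(H) <= 0):
                raise NumericalCurvatureError(
                    f"{label}-model Hessian is not positive definite"
                )
        _, ld_full = np.linalg.slogdet(self.hessian)
        _, ld_null = np.linalg.slogdet(null.hessian)
        log_ml_full = self.llf - 0.5 * ld_full
        log_ml_null = null.llf - 0.5 * ld_null
        return (log_ml_full - log_ml_null) / np.log(10.0)

    def profile_band(
        self,
        rho_grid=None,
        alpha: float = 0.05,
        df: int = 3,
        n_samples: int = 100_000,
        seed: int = 0,
    ) -> CIBand:
        """Monte-Carlo profile-likelihood band around the fitted curve.

        Parameter sets are sampled from the Laplace approximation (Gaussian at
        the ML point, covariance the inverse of the negative log-likelihood
        Hessian); samples whose log-likelihood falls more than q/2 below the
        maximum are rejected, with q the (1-alpha) quantile of chi2(df). The
        band is the pointwise extrema of P(rho) over the retained samples
        (the ML point is always retained), intersected with [0, 1].
        """
        if rho_grid is None:
            rho_grid = np.linspace(-0.2, 1.0, 121)
        rho_grid = np.asarray(rho_grid, dtype=float)
        H = self.hessian
        try:
            if np.any(np.linalg.eigvalsh(H) <= 0):
                raise np.linalg.LinAlgError
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("Hessian not positive definite; diagonal regularization applied")
            H = H + np.eye(3) * (1e-6 + abs(min(0.0, np.min(np.linalg.eigvalsh(H)))))
            cov = np.linalg.inv(H)
        rng = np.random.default_rng(seed)
        xhat = self.params.as_array()
        draws = rng.multivariate_normal(xhat, cov, size=n_samples, method="cholesky")
        ok = (
            (draws[:, 0] >= 0)
            & (draws[:, 0] <= 1)
            & (draws[:, 1] >= 0)
            & (draws[:, 1] <= 1)
            & (draws[:, 2] > 0)
        )
        draws = draws[ok]
        q = stats.chi2.ppf(1.0 - alpha, df=df)
        lls = _loglik_many(draws, self.model)
        keep = draws[lls >= self.llf - q / 2.0]
        keep = np.vstack([xhat[None, :], keep])  # ML point always retained
        if len(keep) == 0:  # pragma: no cover - ML point guarantees >= 1
            raise DegenerateBandError("no retained samples")
        curves = _probability_many(keep, rho_grid)
        fitted = self.predict(rho_grid)
        lower = np.clip(curves.min(axis=0), 0.0, 1.0)
        upper = np.clip(curves.max(axis=0), 0.0, 1.0)
        return CIBand(
            rho_grid=rho_grid,
            fitted=np.asarray(fitted),
            lower=lower,
            upper=upper,
            alpha=alpha,
            n_samples=n_samples,
            df=df,
            seed=seed,
            n_retained=len(keep),
        )

    # -- presentation ------------------------------------------------------

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the inverse Hessian (NaN where the
        curvature is not positive definite)."""
        try:
            cov = np.linalg.inv(self.hessian)
            d = np.diag(cov)
            return np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            return np.full(3, np.nan)

    def summary(self) -> str:
        chi2, df, p = self.lr_test()
        try:
            bf = self.laplace_log10_bf()
            bf_s = f"{bf:.2f}"
        except NumericalCurvatureError:
            bf_s = "n/a (curvature)"
        se = self.bse
        lines = [
            "Rectified exponential-binomial model",
            "=" * 56,
            f"No. participants: {self.model.nobs:>6}    converged: {self.converged}",
            f"Log-likelihood:   {self.llf:>12.3f}    starts: {self.n_starts}",
            "-" * 56,
            f"{'param':>8} {'estimate':>10} {'std err':>10}",
            f"{'beta0':>8} {self.params.beta0:>10.4f} {se[0]:>10.4f}",
            f"{'beta1':>8} {self.params.beta1:>10.4f} {se[1]:>10.4f}",
            f"{'lambda':>8} {self.params.lam:>10.4f} {se[2]:>10.4f}",
            "-" * 56,
            f"LR test vs constant: chi2({df}) = {chi2:.2f}, p = {p:.3g}",
            f"log10 Bayes factor (Laplace): {bf_s}",
            f"Range coverage (P(1)-P(0))/0.5: {self.range_coverage():.3f}",
            "=" * 56,
        ]
        if not self.identifiable:
            lines.insert(-1, "WARNING: all rho <= 0; beta1/lambda unidentifiable")
        if self.at_bounds:
            lines.insert(-1, "NOTE: optimum on a parameter bound")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        chi2, df, p = self.lr_test()
        try:
            bf = float(self.laplace_log10_bf())
        except NumericalCurvatureError:
            bf = None
        return {
            "beta0": self.params.beta0,
            "beta1": self.params.beta1,
            "lambda": self.params.lam,
            "loglik": self.llf,
            "chi2": chi2,
            "df": df,
            "p": p,
            "log10_bf_laplace": bf,
            "range_coverage": self.range_coverage(),
            "converged": self.converged,
            "data_ref": self.data_ref,
        }


def _loglik_many(draws: np.ndarray, model: RectifiedExponentialBinomial) -> np.ndarray:
    """Log-likelihood of each parameter draw (rows of ``draws``), vectorized."""
    b0 = draws[:, 0:1]
    b1 = draws[:, 1:2]
    lam = draws[:, 2:3]
    rho = model.rho[None, :]
    pos = rho > 0
    p = np.where(pos, b1 + (b0 - b1) * np.exp(-np.maximum(rho, 0) / lam), b0)
    p = np.clip(p, _EPS_P, 1 - _EPS_P)
    return model._coef + np.sum(
        model.tc[None, :] * np.log(p) + (model.t - model.tc)[None, :] * np.log1p(-p),
        axis=1,
    )


def _probability_many(draws: np.ndarray, rho_grid: np.ndarray) -> np.ndarray:
    b0 = draws[:, 0:1]
    b1 = draws[:, 1:2]
    lam = draws[:, 2:3]
    rho = rho_grid[None, :]
    return np.where(
        rho <= 0, b0, b1 + (b0 - b1) * np.exp(-np.maximum(rho, 0) / lam)
    )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_refb(data, n_starts: int = 20, seed: int = 0) -> REBResults:
    """Fit the model to (rho, Tc, T) triples; see
    :meth:`RectifiedExponentialBinomial.fit`."""
    return RectifiedExponentialBinomial.from_triples(data).fit(n_starts=n_starts, seed=seed)


def fit_null(data) -> NullREBResults:
    return RectifiedExponentialBinomial.from_triples(data).fit_null()


def lr_test(full: REBResults, null: NullREBResults):
    return full.lr_test(null)


def profile_ci_band(fit: REBResults, rho_grid=None, alpha=0.05, df=3, n_samples=100_000, seed=0):
    return fit.profile_band(rho_grid, alpha=alpha, df=df, n_samples=n_samples, seed=seed)


def laplace_log10_bf(full: REBResults, null: NullREBResults) -> float:
    return full.laplace_log10_bf(null)


def range_coverage(params: REFBParams) -> float:
    """(P(1) - P(0)) / 0.5 for arbitrary parameters."""
    return (refb_probability(params, 1.0) - refb_probability(params, 0.0)) / 0.5
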