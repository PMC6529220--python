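"""Rectified exponential-binomial model: likelihood correctness against
longhand oracles, fitting and recovery, likelihood-ratio test, profile bands,
and the Laplace Bayes factor against a dense grid integral."""

import math

import numpy as np
import pytest

from visuohaptic.cohort import simulate_from_refb
from visuohaptic.exceptions import DataError, DataMismatchError
from visuohaptic.reb import (
    REFBParams,
    RectifiedExponentialBinomial,
    _loglik_many,
    fit_null,
    fit_refb,
    range_coverage,
    refb_loglik,
    refb_probability,
)

PARAMS = REFBParams(0.55, 0.95, 0.3)


# ---------------------------------------------------------------------------
# probability curve
# ---------------------------------------------------------------------------


def test_probability_rectified_branch():
    p = REFBParams(0.6, 0.9, 0.3)
    assert refb_probability(p, -0.5) == pytest.approx(0.6)
    assert refb_probability(p, 0.0) == pytest.approx(0.6)  # continuity at 0
    assert refb_probability(p, 1e-12) == pytest.approx(0.6, abs=1e-9)


def test_probability_null_degeneracy():
    p = REFBParams(0.6, 0.6, 1.7)
    for rho in (-1, -0.2, 0.0, 0.3, 1.0):
        assert refb_probability(p, rho) == pytest.approx(0.6)


def test_probability_direct_evaluation():
    # 1 - 0.5 * exp(-1), evaluated longhand
    p = REFBParams(0.5, 1.0, 0.25)
    assert refb_probability(p, 0.25) == pytest.approx(1 - 0.5 * math.exp(-1), abs=1e-12)


def test_probability_monotone_when_beta1_above_beta0():
    grid = np.linspace(-1, 1, 201)
    vals = refb_probability(PARAMS, grid)
    assert np.all(np.diff(vals) >= -1e-12)


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------


def test_loglik_against_longhand_bernoulli(rng):
    """Matches log C(T,Tc) plus a per-trial Bernoulli product, both computed
    longhand with math functions."""
    data = [(0.3, 40, 72), (-0.2, 30, 72), (0.8, 68, 72)]
    got = refb_loglik(PARAMS, data)
    expected = 0.0
    for rho, tc, t in data:
        p = (
            PARAMS.beta0
            if rho <= 0
            else PARAMS.beta1 + (PARAMS.beta0 - PARAMS.beta1) * math.exp(-rho / PARAMS.lam)
        )
        expected += math.lgamma(t + 1) - math.lgamma(tc + 1) - math.lgamma(t - tc + 1)
        expected += sum(math.log(p) for _ in range(tc))
        expected += sum(math.log(1 - p) for _ in range(t - tc))
    assert got == pytest.approx(expected, rel=1e-12)


def test_loglik_saturated_case():
    # a single all-correct participant: loglik -> 0 from below as P -> 1
    ll = refb_loglik(REFBParams(0.5, 1.0 - 1e-7, 1e-3), [(1.0, 20, 20)])
    assert -1e-4 < ll < 0


def test_loglik_null_reduction():
    data = [(0.3, 10, 20), (-0.5, 15, 20)]
    pooled = 25 / 40
    ll_null = refb_loglik(REFBParams(pooled, pooled, 1.0), data)
    from scipy.stats import binom

    expected = sum(binom.logpmf(tc, t, pooled) for _, tc, t in data)
    assert ll_null == pytest.approx(expected, rel=1e-12)


def test_invalid_counts_rejected():
    with pytest.raises(DataError):
        refb_loglik(PARAMS, [(0.3, 30, 20)])
    with pytest.raises(DataError):
        REFBParams(0.5, 1.2, 0.3)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _fit(data, seed=0):
    return RectifiedExponentialBinomial.from_triples(data).fit(seed=seed)


def test_fit_deterministic():
    data = simulate_from_refb(PARAMS, 20, 72, seed=3)
    a, b = _fit(data, seed=5), _fit(data, seed=5)
    assert a.params == b.params
    assert a.llf == b.llf


def test_fit_recovery_large_n():
    data = simulate_from_refb(PARAMS, 200, 72, (-0.1, 0.9), seed=1)
    res = _fit(data)
    grid = np.linspace(-0.1, 0.9, 101)
    err = np.max(np.abs(refb_probability(res.params, grid) - refb_probability(PARAMS, grid)))
    assert err <= 0.02
    assert res.converged


def test_fit_flags_unidentifiable_when_all_rho_nonpositive():
    data = simulate_from_refb(REFBParams(0.6, 0.95, 0.3), 30, 50, (-0.9, -0.01), seed=2)
    with pytest.warns(UserWarning, match="unidentifiable"):
        res = _fit(data)
    assert not res.identifiable


def test_null_fit_closed_form():
    null = fit_null([(0.1, 10, 20), (0.5, 15, 20)])
    assert null.p_hat == pytest.approx(25 / 40)
    model = RectifiedExponentialBinomial.from_triples([(0.1, 10, 20), (0.5, 15, 20)])
    assert null.llf == pytest.approx(model.loglike((null.p_hat, null.p_hat, 1.0)))


def test_null_fit_boundary():
    null = fit_null([(0.1, 20, 20), (0.5, 20, 20), (0.9, 20, 20)])
    assert null.p_hat == pytest.approx(1 - 1e-4)


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------


def test_lr_test_zero_when_no_improvement():
    # data at constant rate with no rho information beyond the baseline
    data = [(-0.5, 10, 20), (-0.2, 10, 20), (-0.8, 10, 20)]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _fit(data)
    chi2, df, p = res.lr_test()
    assert chi2 == pytest.approx(0.0, abs=1e-6)
    assert df == 2
    assert p == pytest.approx(1.0, abs=1e-6)


def test_lr_test_data_mismatch():
    res = _fit(simulate_from_refb(PARAMS, 20, 72, seed=1))
    other_null = fit_null(simulate_from_refb(PARAMS, 20, 72, seed=2))
    with pytest.raises(DataMismatchError):
        res.lr_test(other_null)


def test_lr_test_power_under_strong_effect(rng):
    rejections = 0
    n_rep = 60
    for _ in range(n_rep):
        data = simulate_from_refb(
            REFBParams(0.55, 0.95, 0.3), 20, 72, (-0.1, 0.9), seed=int(rng.integers(2**31))
        )
        _, _, p = _fit(data, seed=int(rng.integers(2**31))).lr_test()
        rejections += p < 0.05
    assert rejections / n_rep > 0.9


# ---------------------------------------------------------------------------
# profile-likelihood band
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted():
    data = simulate_from_refb(PARAMS, 40, 72, (-0.1, 0.9), seed=7)
    return RectifiedExponentialBinomial.from_triples(data).fit(seed=0)


def test_band_contains_ml_curve(fitted):
    band = fitted.profile_band(n_samples=5000, seed=0)
    fit_curve = np.asarray(fitted.predict(band.rho_grid))
    assert np.all(band.lower <= fit_curve + 1e-12)
    assert np.all(band.upper >= fit_curve - 1e-12)


def test_band_monotone_in_sample_count(fitted):
    """With a common sample stream, doubling the sample count can only widen
    the pointwise extrema."""
    small = fitted.profile_band(n_samples=2000, seed=3)
    large = fitted.profile_band(n_samples=4000, seed=3)
    assert np.all(large.lower <= small.lower + 1e-12)
    assert np.all(large.upper >= small.upper - 1e-12)


def test_band_matches_grid_profile_oracle():
    """Near-quadratic regime: band endpoints agree with a dense grid-search
    profile-likelihood oracle."""
    data = simulate_from_refb(PARAMS, 400, 72, (-0.1, 0.9), seed=11)
    res = RectifiedExponentialBinomial.from_triples(data).fit(seed=0)
    probe = np.array([0.2, 0.5])
    band = res.profile_band(rho_grid=probe, n_samples=200_000, seed=1)

    # oracle: exhaustive grid over +/- 5 SE around the optimum
    se = res.bse
    x = res.params.as_array()
    axes = [np.linspace(x[i] - 5 * se[i], x[i] + 5 * se[i], 41) for i in range(3)]
    g = np.stack([a.ravel() for a in np.meshgrid(*axes, indexing="ij")], axis=1)
    g = g[(g[:, 0] > 0) & (g[:, 0] < 1) & (g[:, 1] > 0) & (g[:, 1] < 1) & (g[:, 2] > 0)]
    model = res.model
    from scipy.stats import chi2 as chi2_dist

    lls = _loglik_many(g, model)
    keep = g[lls >= res.llf - chi2_dist.ppf(0.95, 3) / 2]
    for j, rho0 in enumerate(probe):
        vals = np.where(
            rho0 <= 0,
            keep[:, 0],
            keep[:, 1] + (keep[:, 0] - keep[:, 1]) * np.exp(-rho0 / keep[:, 2]),
        )
        assert band.lower[j] == pytest.approx(vals.min(), abs=0.015)
        assert band.upper[j] == pytest.approx(vals.max(), abs=0.015)


# ---------------------------------------------------------------------------
# Laplace Bayes factor
# ---------------------------------------------------------------------------


def test_laplace_bf_zero_for_identical_models(fitted):
    class FakeNull:
        pass

    null = FakeNull()
    null.llf = fitted.llf
    null.hessian = fitted.hessian
    null.data_ref = fitted.data_ref
    assert fitted.laplace_log10_bf(null) == pytest.approx(0.0, abs=1e-12)


def test_laplace_bf_large_under_strong_effect(rng):
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        data = simulate_from_refb(
            REFBParams(0.55, 0.95, 0.3), 40, 72, (-0.1, 0.9), seed=int(rng.integers(2**31))
        )
        bf = _fit(data, seed=int(rng.integers(2**31))).laplace_log10_bf()
        hits += bf > 1
    assert hits / n_rep >= 0.95


def test_laplace_bf_against_grid_integration():
    """The Laplace kernel matches a brute-force marginal likelihood by dense
    grid integration with uniform priors over the parameter box, after adding
    back the constant (2 pi)^(d/2) and prior-volume factors the approximation
    deliberately drops."""
    data = simulate_from_refb(PARAMS, 30, 40, (-0.1, 0.9), seed=5)
    model = RectifiedExponentialBinomial.from_triples(data)
    res = model.fit(seed=0)
    null = model.fit_null()
    pkg = res.laplace_log10_bf(null)

    # grid marginal of the full model over the optimizer's box
    b_lo, b_hi = 1e-4, 1 - 1e-4
    l_lo, l_hi = 1e-3, 10.0
    nb, nl = 120, 120
    b0g = np.linspace(b_lo, b_hi, nb)
    b1g = np.linspace(b_lo, b_hi, nb)
    lamg = np.linspace(l_lo, l_hi, nl)
    g = np.stack([a.ravel() for a in np.meshgrid(b0g, b1g, lamg, indexing="ij")], axis=1)
    lls = _loglik_many(g, model)
    m = lls.max()
    db = b0g[1] - b0g[0]
    dl = lamg[1] - lamg[0]
    vol_full = (b_hi - b_lo) ** 2 * (l_hi - l_lo)
    log_ml_full = m + np.log(np.exp(lls - m).sum() * db * db * dl) - np.log(vol_full)

    # null marginal: 1-d integral over the success probability
    pg = np.linspace(b_lo, b_hi, 20001)
    g_null = np.stack([pg, pg, np.ones_like(pg)], axis=1)
    lln = _loglik_many(g_null, model)
    mn = lln.max()
    log_ml_null = mn + np.log(np.exp(lln - mn).sum() * (pg[1] - pg[0])) - np.log(b_hi - b_lo)

    grid_log10_bf = (log_ml_full - log_ml_null) / np.log(10)
    correction = (np.log(2 * np.pi) + np.log(1.0 / vol_full)) / np.log(10)
    assert grid_log10_bf == pytest.approx(pkg + correction, abs=0.2)


# ---------------------------------------------------------------------------
# range coverage
# ---------------------------------------------------------------------------


def test_range_coverage_values():
    assert range_coverage(REFBParams(0.7, 0.7, 1.0)) == pytest.approx(0.0)
    assert range_coverage(REFBParams(0.5, 1.0, 1e-9)) == pytest.approx(1.0)
    assert range_coverage(REFBParams(0.5, 1.0, 1.0)) == pytest.approx(
        1 - math.exp(-1), abs=1e-12
    )


def test_summary_renders(fitted):
    text = fitted.summary()
    assert "beta0" in text and "LR test" in text


def test_wrappers_match_methods():
    data = simulate_from_refb(PARAMS, 20, 72, seed=9)
    res = fit_refb(data, seed=1)
    null = fit_null(data)
    from visuohaptic.reb import laplace_log10_bf, lr_test

    assert lr_test(res, null) == res.lr_test(null)
    assert laplace_log10_bf(res, null) == res.laplace_log10_bf(null)
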