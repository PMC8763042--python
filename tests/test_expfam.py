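"""Exponential-family layer: densities, deviances, truncation corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

import catsreg as cr
from catsreg import expfam


# ---------------------------------------------------------------------------
# log-likelihoods


@pytest.mark.parametrize(
    "family, y, mu, expected",
    [
        # ln pmf values frozen from direct factorial-based evaluation
        (cr.poisson(), [2.0], [3.0], 2 * np.log(3) - 3 - np.log(2)),
        (cr.gaussian(1.0), [0.0], [0.0], -0.5 * np.log(2 * np.pi)),
        (cr.binomial(1), [1.0, 0.0], [0.4, 0.4], np.log(0.4) + np.log(0.6)),
    ],
)
def test_log_likelihood_closed_forms(family, y, mu, expected):
    assert cr.log_likelihood(np.array(y), np.array(mu), family) == pytest.approx(
        expected, abs=1e-12
    )


@pytest.mark.parametrize(
    "family, dist",
    [
        (cr.poisson(), lambda y, mu: stats.poisson.logpmf(y, mu)),
        (cr.negbin(1.7), lambda y, mu: stats.nbinom.logpmf(y, 1.7, 1.7 / (1.7 + mu))),
        (cr.binomial(5), lambda y, mu: stats.binom.logpmf(y, 5, mu / 5)),
        (cr.gaussian(2.5), lambda y, mu: stats.norm.logpdf(y, mu, np.sqrt(2.5))),
    ],
)
def test_log_likelihood_matches_scipy(family, dist, rng):
    mu = rng.uniform(0.5, 4.0, 20)
    if family.name == "binomial":
        y = rng.binomial(5, mu / 5).astype(float)
    elif family.name == "gaussian":
        y = rng.normal(mu)
    else:
        y = rng.poisson(mu).astype(float)
    assert cr.log_likelihood(y, mu, family) == pytest.approx(
        float(dist(y, mu).sum()), rel=1e-12
    )


def test_negbin_approaches_poisson_at_large_theta(rng):
    y = rng.poisson(3.0, 10).astype(float)
    mu = rng.uniform(1.0, 5.0, 10)
    ll_nb = cr.log_likelihood(y, mu, cr.negbin(1e6))
    ll_p = cr.log_likelihood(y, mu, cr.poisson())
    assert ll_nb == pytest.approx(ll_p, abs=1e-3)


def test_truncated_likelihoods_renormalize(rng):
    mu = rng.uniform(0.5, 3.0, 8)
    y = np.maximum(rng.poisson(mu), 1).astype(float)
    base = stats.poisson.logpmf(y, mu) - np.log1p(-np.exp(-mu))
    assert cr.log_likelihood(y, mu, cr.trunc_poisson()) == pytest.approx(
        float(base.sum()), rel=1e-12
    )


def test_domain_errors_name_offending_index():
    with pytest.raises(expfam.DomainError, match="index 1"):
        cr.log_likelihood(np.array([1.0, 2.0]), np.array([2.0, -1.0]), cr.poisson())
    with pytest.raises(expfam.SupportError, match="index 0"):
        cr.log_likelihood(np.array([-1.0]), np.array([2.0]), cr.poisson())
    with pytest.raises(expfam.SupportError, match="zero-truncated"):
        cr.log_likelihood(np.array([0.0, 2.0]), np.array([1.0, 1.0]), cr.trunc_poisson())
    with pytest.raises(expfam.DomainError, match="n=3"):
        cr.log_likelihood(np.array([1.0]), np.array([3.5]), cr.binomial(3))


# ---------------------------------------------------------------------------
# saturated likelihood and deviance


def test_saturated_boundary_conventions():
    assert cr.saturated_loglik(np.array([0.0, 0.0]), cr.poisson()) == 0.0
    assert cr.saturated_loglik(np.array([1.0, 0.0]), cr.binomial(1)) == 0.0
    assert cr.saturated_loglik(np.array([2.0]), cr.poisson()) == pytest.approx(
        cr.log_likelihood(np.array([2.0]), np.array([2.0]), cr.poisson())
    )
    with pytest.raises(expfam.SupportError):
        cr.saturated_loglik(np.array([0.0]), cr.trunc_poisson())


@pytest.mark.parametrize(
    "family, closed_form",
    [
        (
            cr.poisson(),
            lambda y, mu: 2 * np.sum(np.where(y > 0, y * np.log(y / mu), 0) - (y - mu)),
        ),
        (cr.gaussian(1.0), lambda y, mu: np.sum((y - mu) ** 2)),
        (
            cr.binomial(1),
            lambda y, mu: 2
            * np.sum(
                np.where(y > 0, y * np.log(y / mu), 0)
                + np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0)
            ),
        ),
    ],
)
def test_deviance_matches_textbook_closed_forms(family, closed_form, rng):
    mu = rng.uniform(0.2, 0.8, 25) if family.name == "binomial" else rng.uniform(0.5, 6, 25)
    if family.name == "binomial":
        y = rng.binomial(1, mu).astype(float)
    elif family.name == "gaussian":
        y = rng.normal(mu)
    else:
        y = rng.poisson(mu).astype(float)
    assert cr.deviance(y, mu, family) == pytest.approx(
        float(closed_form(y, mu)), abs=1e-10
    )


def test_poisson_unit_deviance_example():
    d = cr.deviance(np.array([2.0]), np.array([3.0]), cr.poisson())
    assert d == pytest.approx(2 * (2 * np.log(2 / 3) + 1), abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    y=st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=10),
    shift=st.floats(min_value=-0.5, max_value=2.0),
)
def test_deviance_nonnegative_zero_iff_full(y, shift):
    y = np.array(y, dtype=float)
    mu = y + 0.5 + max(shift, 0.0)
    assert cr.deviance(y, mu, cr.poisson()) >= 0
    mu_full = np.maximum(y, 1e-8)  # mean domain excludes exact zero
    assert cr.deviance(y, mu_full, cr.poisson()) == pytest.approx(0.0, abs=1e-6)


def test_deviance_is_twice_likelihood_gap(rng):
    y = rng.poisson(4.0, 15).astype(float)
    mu = rng.uniform(2, 6, 15)
    fam = cr.negbin(2.0)
    gap = 2 * (cr.saturated_loglik(y, fam) - cr.log_likelihood(y, mu, fam))
    assert cr.deviance(y, mu, fam) == pytest.approx(gap, rel=1e-14)


# ---------------------------------------------------------------------------
# variance function and truncation


@pytest.mark.parametrize(
    "family, mu, expected",
    [
        (cr.poisson(), [4.0], [4.0]),
        (cr.negbin(1.0), [4.0], [20.0]),
        (cr.tweedie(1.5, 2.0), [4.0], [16.0]),
        (cr.binomial(4), [1.0], [0.75]),
        (cr.gaussian(3.0), [7.0], [3.0]),
    ],
)
def test_variance_function(family, mu, expected):
    np.testing.assert_allclose(
        cr.variance_function(np.array(mu), family), expected, rtol=1e-12
    )


def test_truncation_adjust_values():
    fam = cr.trunc_poisson()
    np.testing.assert_allclose(
        cr.truncation_adjust(np.array([1.0]), fam), [1 / (1 - np.exp(-1))], rtol=1e-12
    )
    np.testing.assert_allclose(
        cr.truncation_adjust(np.array([50.0]), fam), [50.0], rtol=1e-6
    )
    np.testing.assert_allclose(
        cr.truncation_adjust(np.array([1.0]), cr.trunc_negbin(1.0)), [2.0], rtol=1e-12
    )
    with pytest.raises(ValueError, match="zero-truncated"):
        cr.truncation_adjust(np.array([1.0]), cr.poisson())


@pytest.mark.parametrize("family", [cr.trunc_poisson(), cr.trunc_negbin(1.3)])
@pytest.mark.parametrize("mu", [0.2, 1.0, 3.0])
def test_truncation_adjust_is_exact_truncated_mean(family, mu):
    k = np.arange(1, 1001)
    if family.name == "trunc_poisson":
        pmf = stats.poisson.pmf(k, mu)
    else:
        th = family.theta
        pmf = stats.nbinom.pmf(k, th, th / (th + mu))
    brute = float((k * pmf).sum() / pmf.sum())
    assert cr.truncation_adjust(np.array([mu]), family)[0] == pytest.approx(
        brute, abs=1e-8
    )


def test_truncation_adjust_monotone_and_above_one():
    mu = np.linspace(0.05, 10, 50)
    out = cr.truncation_adjust(mu, cr.trunc_poisson())
    assert np.all(np.diff(out) > 0)
    assert np.all(out > np.maximum(mu, 1.0))


# ---------------------------------------------------------------------------
# Tweedie series machinery


def test_tweedie_density_normalizes_and_has_mean_mu():
    p, phi, mu = 1.5, 2.0, 3.0
    dens = lambda t: np.exp(
        expfam._tweedie_log_density(np.array([t]), np.array([mu]), p, phi)[0]
    )
    p0 = np.exp(-(mu ** (2 - p)) / (phi * (2 - p)))
    total, _ = quad(dens, 1e-12, 80, limit=300)
    mean, _ = quad(lambda t: t * dens(t), 1e-12, 80, limit=300)
    assert p0 + total == pytest.approx(1.0, abs=1e-8)
    assert mean == pytest.approx(mu, abs=1e-6)


def test_tweedie_deviance_matches_closed_form(rng):
    p, phi = 1.6, 0.8
    fam = cr.tweedie(p, phi)
    mu = rng.uniform(0.5, 4.0, 10)
    y = np.where(rng.uniform(size=10) < 0.3, 0.0, rng.gamma(2.0, mu / 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = 2 * (
            np.where(y > 0, y * (y ** (1 - p) - mu ** (1 - p)) / (1 - p), 0.0)
            - (y ** (2 - p) - mu ** (2 - p)) / (2 - p)
        )
    assert cr.deviance(y, mu, fam) == pytest.approx(float(unit.sum() / phi), rel=1e-9)


def test_family_validation():
    with pytest.raises(ValueError):
        cr.negbin(-1.0)
    with pytest.raises(ValueError):
        cr.tweedie(2.5)
    with pytest.raises(ValueError):
        cr.binomial(0)
    with pytest.raises(ValueError):
        expfam.Family("beta")
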