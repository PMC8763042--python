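"""KL R2, its conventions, adjustments and variation partitioning."""

import numpy as np
import pytest

import catsreg as cr
from catsreg import expfam, goodness


def _poisson_fixture(rng, S=40, with_offset=False):
    X = rng.normal(size=(S, 2))
    prior = cr.relative_abundances(rng.uniform(0.5, 2.0, S))
    mu = np.exp(1.2 + 0.4 * X[:, 0] + (np.log(prior.pi * S) if with_offset else 0))
    y = rng.poisson(mu).astype(float)
    return y, cr.DesignSpec(X), prior


def test_gaussian_identity_r2_equals_ols(rng):
    S = 30
    X = rng.normal(size=(S, 2))
    y = rng.normal(1.0 + 0.8 * X[:, 0], 1.0)
    fam = cr.gaussian()
    fit = cr.fit_cats(y, cr.DesignSpec(X), family=fam, link="identity")
    null = cr.fit_cats(y, None, family=fam, link="identity")
    res = cr.r2_kl(fit, null)
    # classic least-squares R2, computed independently
    Xc = np.column_stack([np.ones(S), (X - X.mean(0)) / X.std(0)])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    rss = np.sum((y - Xc @ beta) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    assert res.r2_kl == pytest.approx(1 - rss / tss, abs=1e-10)


@pytest.mark.parametrize("family", [cr.poisson(), cr.negbin(1.5), cr.binomial(1)])
@pytest.mark.parametrize("with_offset", [False, True])
def test_deviance_and_likelihood_forms_agree(family, with_offset, rng):
    S = 40
    if family.name == "binomial":
        X = rng.normal(size=(S, 2))
        y = rng.binomial(1, 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        prior = cr.relative_abundances(rng.uniform(0.8, 1.2, S))
        design = cr.DesignSpec(X)
        link = "logit"
        off = cr.OffsetVector(0.1 * rng.normal(size=S), "logit") if with_offset else None
    else:
        y, design, prior = _poisson_fixture(rng, S, with_offset)
        link = "log"
        off = cr.offsets_log(prior) if with_offset else None
    fit = cr.fit_cats(y, design, off, family=family, link=link)
    null = cr.fit_cats(y, None, None, family=family, link=link)
    r2_dev = cr.r2_kl(fit, null).r2_kl
    lfull = expfam.saturated_loglik(y, family)
    r2_ll = (fit.loglik - null.loglik) / (lfull - null.loglik)
    assert r2_dev == pytest.approx(r2_ll, abs=1e-10)


def test_likelihood_ratio_rescaling_identity(rng):
    y, design, _ = _poisson_fixture(rng)
    fam = cr.poisson()
    fit = cr.fit_cats(y, design, family=fam)
    null = cr.fit_cats(y, None, family=fam)
    res = cr.r2_kl(fit, null)
    lfull = expfam.saturated_loglik(y, fam)
    scale = 1 - lfull / null.loglik
    assert res.r2_likelihood / scale == pytest.approx(res.r2_kl, abs=1e-10)


def test_full_model_r2_is_one(rng):
    S = 20
    X = rng.normal(size=(S, 1))
    y = 2.0 + 0.7 * X[:, 0]  # exactly linear: the fit is saturated
    fam = cr.gaussian()
    fit = cr.fit_cats(y, cr.DesignSpec(X), family=fam, link="identity")
    null = cr.fit_cats(y, None, family=fam, link="identity")
    assert cr.r2_kl(fit, null).r2_kl == pytest.approx(1.0, abs=1e-10)


def test_r2_requires_matching_family_and_response(rng):
    y, design, _ = _poisson_fixture(rng)
    fit = cr.fit_cats(y, design, family=cr.poisson())
    null_other = cr.fit_cats(y, None, family=cr.negbin(1.0))
    with pytest.raises(ValueError, match="share the family"):
        cr.r2_kl(fit, null_other)
    with pytest.raises(ValueError, match="null deviance is zero"):
        constant = np.full(10, 3.0)
        f = cr.fit_cats(constant, None, family=cr.poisson())
        cr.r2_kl(f, f)


def test_poisson_shipley_closed_form_equivalence(rng):
    for _ in range(5):
        y, design, _ = _poisson_fixture(rng)
        fam = cr.poisson()
        fit = cr.fit_cats(y, design, family=fam)
        null = cr.fit_cats(y, None, family=fam)
        generic = cr.r2_kl(fit, null).r2_kl
        shipley = cr.r2_poisson_shipley(y, fit.mu, null.mu)
        assert shipley == pytest.approx(generic, abs=1e-10)
    assert cr.r2_poisson_shipley(y, y + 1e-12, null.mu) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError, match="counts"):
        cr.r2_poisson_shipley(np.array([1.5, 2.0]), np.ones(2), np.ones(2))


def test_offset_model_r2_can_be_negative_alternative_stays_positive(rng):
    """A prior anti-correlated with the data drags R2 below zero (Eq-26 form does not)."""
    S = 30
    y = np.sort(rng.poisson(5.0, S))[::-1].astype(float) + 1
    prior = cr.relative_abundances(np.arange(1.0, S + 1.0))  # reversed ranks
    fam = cr.poisson()
    fit = cr.fit_cats(y, None, cr.offsets_log(prior), family=fam)
    null = cr.fit_cats(y, None, family=fam)
    res = cr.r2_kl(fit, null)
    assert res.r2_kl < 0
    alt = cr.r2_alternative(fit, null)
    assert 0.0 <= alt <= 1.0


def test_alternative_r2_matches_classic_without_offset(rng):
    S = 25
    X = rng.normal(size=(S, 1))
    y = rng.normal(0.5 * X[:, 0], 1.0)
    fam = cr.gaussian()
    fit = cr.fit_cats(y, cr.DesignSpec(X), family=fam, link="identity")
    null = cr.fit_cats(y, None, family=fam, link="identity")
    assert cr.r2_alternative(fit, null) == pytest.approx(
        cr.r2_kl(fit, null).r2_kl, abs=1e-10
    )


def test_offset_only_r2_zero_under_offset_null_convention(small_counts):
    y, _, prior = small_counts
    off = cr.offsets_log(prior)
    fit = cr.fit_cats(y, None, off, family=cr.poisson())
    res = cr.r2_kl(fit, fit)
    assert res.r2_kl == pytest.approx(0.0, abs=1e-12)
    assert res.null_convention == "intercept_plus_offset"
    # under the default intercept-only null the same model has nonzero R2
    null = cr.fit_cats(y, None, family=cr.poisson())
    assert abs(cr.r2_kl(fit, null).r2_kl) > 1e-6


def test_adjusted_r2_properties(rng):
    y, design, _ = _poisson_fixture(rng)
    fam = cr.poisson()
    fit = cr.fit_cats(y, design, family=fam)
    null = cr.fit_cats(y, None, family=fam)
    res = cr.r2_kl(fit, null)
    assert cr.r2_adjusted(fit, null) <= res.r2_kl
    assert cr.r2_adjusted(fit, null, k=0) == pytest.approx(res.r2_kl, abs=1e-14)


def test_adjusted_r2_reduces_to_ezekiel_for_gaussian(rng):
    """With sigma2 = RSS/(n-k-1), the deviance adjustment equals Ezekiel's formula."""
    n, k = 20, 3
    X = rng.normal(size=(n, k))
    y = rng.normal(1.0 + X @ np.array([0.5, -0.3, 0.2]), 1.0)
    design = cr.DesignSpec(X)
    fit0 = cr.fit_cats(y, design, family=cr.gaussian(), link="identity")
    rss = float(np.sum((y - fit0.mu) ** 2))
    fam = cr.gaussian(sigma2=rss / (n - k - 1))
    fit = cr.fit_cats(y, design, family=fam, link="identity")
    null = cr.fit_cats(y, None, family=fam, link="identity")
    r2 = cr.r2_kl(fit, null).r2_kl
    ezekiel = 1 - (1 - r2) * (n - 1) / (n - k - 1)
    assert cr.r2_adjusted(fit, null) == pytest.approx(ezekiel, abs=1e-8)


def test_partition_components_sum_to_one(small_counts):
    y, design, prior = small_counts
    for adjusted in (False, True):
        part = cr.partition(y, design, prior, family=cr.poisson(), adjusted=adjusted)
        total = part.pure_trait + part.pure_meta + part.joint + part.unexplained
        assert total == pytest.approx(1.0, abs=1e-12)
        assert part.pure_trait == pytest.approx(part.r2_both - part.r2_offset)
        assert part.pure_meta == pytest.approx(part.r2_both - part.r2_traits)


def test_partition_shares_estimated_dispersion():
    plots = cr.simulate.simulate_example1(n_plots=1, S=200, seed=5)
    p = plots[0]
    prior = cr.relative_abundances(np.full(200, 1.0))
    part = cr.partition(
        p.y, cr.DesignSpec(p.traits), prior, family=cr.negbin(1.0),
        estimate_dispersion=True,
    )
    assert part.family == "negbin"
    total = part.pure_trait + part.pure_meta + part.joint + part.unexplained
    assert total == pytest.approx(1.0, abs=1e-12)


def test_null_traits_have_near_zero_adjusted_components():
    rng = np.random.default_rng(42)
    S, reps = 50, 100
    vals = np.empty(reps)
    uniform = cr.relative_abundances(np.ones(S))
    for r in range(reps):
        y = rng.poisson(8.0, S).astype(float)
        X = rng.normal(size=(S, 2))
        part = cr.partition(y, cr.DesignSpec(X), uniform, family=cr.poisson())
        vals[r] = part.r2_both  # uniform prior + noise traits: nothing to explain
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean()) < 4 * se


def test_shipley_adjust_is_deterministic_given_seed(small_counts):
    y, design, prior = small_counts
    kwargs = dict(family=cr.poisson(), n_random=20, seed=99)
    a = cr.r2_shipley_adjust(y, design, prior, **kwargs)
    b = cr.r2_shipley_adjust(y, design, prior, **kwargs)
    assert a == b
    with pytest.raises(ValueError, match="reshuffle"):
        cr.r2_shipley_adjust(y, None, prior, family=cr.poisson(), n_random=5, seed=1)


def test_shipley_adjusted_numerator_variant_coincides(small_counts):
    # the k-penalty cancels in the numerator difference
    y, design, prior = small_counts
    a = cr.r2_shipley_adjust(y, design, prior, family=cr.poisson(), n_random=10,
                             seed=3, adjusted_numerator=False)
    b = cr.r2_shipley_adjust(y, design, prior, family=cr.poisson(), n_random=10,
                             seed=3, adjusted_numerator=True)
    assert a == pytest.approx(b, abs=1e-12)
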