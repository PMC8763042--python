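"""Model-adequacy diagnostics.

Randomized quantile (Dunn-Smyth) residuals are the workhorse: under a
correctly specified model they are exact draws from a standard normal, for
discrete and continuous families alike, which makes misspecification (most
commonly overdispersion, when a Poisson model is forced onto aggregated
counts) visible as curvature in a QQ plot or as a significant
Anderson-Darling statistic.  A direct AIC comparison of Poisson vs
negative-binomial fits on the same data complements the residual check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import quad

from . import expfam
from .expfam import Family
from .fitting import CATSFit, DesignSpec, estimate_theta, fit_cats

__all__ = [
    "ResidualSet",
    "OverdispersionComparison",
    "dunn_smyth_residuals",
    "overdispersion_compare",
    "qq_data",
    "anderson_darling_normality",
]


@dataclass(frozen=True)
class ResidualSet:
    residuals: np.ndarray
    type: str
    seed: int | None
    fitted: np.ndarray


@dataclass(frozen=True)
class OverdispersionComparison:
    aic_poisson: float
    aic_negbin: float
    preferred: str
    theta: float


def _discrete_cdf(y: np.ndarray, mu: np.ndarray, family: Family):
    """(F(y-1), F(y)) for a discrete family, elementwise."""
    name = family.name
    if name == "poisson":
        return stats.poisson.cdf(y - 1, mu), stats.poisson.cdf(y, mu)
    if name == "negbin":
        th = family.theta
        p = th / (th + mu)
        return stats.nbinom.cdf(y - 1, th, p), stats.nbinom.cdf(y, th, p)
    if name == "binomial":
        n = family.n_trials
        return stats.binom.cdf(y - 1, n, mu / n), stats.binom.cdf(y, n, mu / n)
    if name in ("trunc_poisson", "trunc_negbin"):
        if name == "trunc_poisson":
            base_lo = stats.poisson.cdf(y - 1, mu)
            base_hi = stats.poisson.cdf(y, mu)
            p0 = stats.poisson.cdf(0, mu)
        else:
            th = family.theta
            p = th / (th + mu)
            base_lo = stats.nbinom.cdf(y - 1, th, p)
            base_hi = stats.nbinom.cdf(y, th, p)
            p0 = stats.nbinom.cdf(0, th, p)
        lo = np.clip((base_lo - p0) / (1.0 - p0), 0.0, 1.0)
        hi = np.clip((base_hi - p0) / (1.0 - p0), 0.0, 1.0)
        return lo, hi
    raise ValueError(name)


def _tweedie_cdf_interval(y: np.ndarray, mu: np.ndarray, family: Family):
    """Mixed-type CDF: point mass at zero, continuous density above."""
    p, phi = family.p, family.phi
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    p0 = np.exp(-lam)
    lo = np.empty_like(y)
    hi = np.empty_like(y)
    for i, (yi, mi) in enumerate(zip(y, mu)):
        if yi == 0:
            lo[i], hi[i] = 0.0, p0[i]
        else:
            dens = lambda t: np.exp(
                expfam._tweedie_log_density(np.array([t]), np.array([mi]), p, phi)[0]
            )
            integral, _ = quad(dens, 0.0, yi, limit=200)
            lo[i] = hi[i] = min(p0[i] + integral, 1.0 - 1e-12)
    return lo, hi


def dunn_smyth_residuals(fit: CATSFit, seed: int | None = None) -> ResidualSet:
    """Randomized quantile residuals for a fitted model.

    For discrete families each residual is Phi^{-1}(u) with u uniform on
    (F(y-1), F(y)] at the fitted mean; for continuous families the
    probability-integral transform is deterministic.  Reproducible given
    the seed.
    """
    y = fit.y
    mu = fit.mu
    family = fit.family
    if family.name == "gaussian":
        u = stats.norm.cdf(y, mu, np.sqrt(family.sigma2))
        resid = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        return ResidualSet(resid, "dunn_smyth", seed, mu.copy())
    if family.name == "tweedie":
        lo, hi = _tweedie_cdf_interval(y, mu, family)
    elif family.is_discrete:
        lo, hi = _discrete_cdf(y, mu, family)
    else:
        raise ValueError(f"no cumulative distribution implemented for {family.name}")
    rng = np.random.default_rng(seed)
    u = np.where(hi > lo, lo + rng.uniform(size=len(y)) * (hi - lo), hi)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return ResidualSet(stats.norm.ppf(u), "dunn_smyth", seed, mu.copy())


def overdispersion_compare(y, design: DesignSpec | None = None, offset=None, *,
                           link="log") -> OverdispersionComparison:
    """AIC comparison of Poisson and negative-binomial fits on count data.

    AIC = -2 loglik + 2 (k + 1 + [theta estimated]); ties go to the
    Poisson model (fewer parameters).
    """
    import warnings as _warnings

    fit_p = fit_cats(y, design, offset, family=expfam.poisson(), link=link)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # theta-cap note is expected here
        fit_nb = estimate_theta(y, design, offset, link=link)
    preferred = "poisson" if fit_p.aic <= fit_nb.aic else "negbin"
    return OverdispersionComparison(
        aic_poisson=float(fit_p.aic),
        aic_negbin=float(fit_nb.aic),
        preferred=preferred,
        theta=float(fit_nb.dispersion),
    )


def qq_data(residuals: ResidualSet | np.ndarray):
    """(theoretical, sample) normal quantile pairs for a QQ plot."""
    r = residuals.residuals if isinstance(residuals, ResidualSet) else np.asarray(residuals)
    r = np.sort(r)
    n = len(r)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, r


def anderson_darling_normality(residuals: ResidualSet | np.ndarray,
                               level: float = 5.0):
    """Anderson-Darling statistic against normality of the residuals.

    Returns (statistic, critical value at the given significance level in
    percent; default the conventional 5%).  The statistic exceeding the
    critical value rejects normality — with Dunn-Smyth residuals, evidence
    of model misspecification.
    """
    r = residuals.residuals if isinstance(residuals, ResidualSet) else np.asarray(residuals)
    res = stats.anderson(r, dist="norm")
    idx = int(np.argmin(np.abs(res.significance_level - level)))
    return float(res.statistic), float(res.critical_values[idx])
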