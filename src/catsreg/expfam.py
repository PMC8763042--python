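"""Exponential-family machinery for abundance models.

Every distribution used in CATS regression (Gaussian, Poisson, binomial,
negative binomial, Tweedie with power 1 < p < 2, and the zero-truncated
Poisson / negative binomial used in hurdle models) can be written in
exponential-family form

    f(y; psi, phi) = exp{ [y*psi - b(psi)] / a(phi) + c(y, phi) }

with canonical parameter ``psi``, cumulant ``b``, scale ``a(phi)`` and
normalizer ``c``.  This module implements log-likelihoods, saturated-model
log-likelihoods, scaled deviances, variance functions and the
zero-truncation mean correction on top of that structure.

Auxiliary parameters (negative-binomial dispersion ``theta``, Tweedie power
``p`` and dispersion ``phi``, binomial trial count ``n``, Gaussian variance
``sigma2``) are *fixed constants* of a :class:`Family`; estimating them is
the fitting layer's job.  All deviances returned here are scaled deviances
(already divided by ``a(phi)``); ratios of deviances, which is all the
goodness-of-fit layer consumes, are invariant to that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "Family",
    "DomainError",
    "SupportError",
    "gaussian",
    "poisson",
    "binomial",
    "negbin",
    "tweedie",
    "trunc_poisson",
    "trunc_negbin",
    "log_likelihood",
    "saturated_loglik",
    "deviance",
    "variance_function",
    "truncation_adjust",
    "kl_divergence",
]

_FAMILY_NAMES = {
    "gaussian",
    "poisson",
    "binomial",
    "negbin",
    "tweedie",
    "trunc_poisson",
    "trunc_negbin",
}

_DISCRETE = {"poisson", "binomial", "negbin", "trunc_poisson", "trunc_negbin"}
_TRUNCATED = {"trunc_poisson", "trunc_negbin"}


class DomainError(ValueError):
    """A mean value lies outside the family's mean domain."""


class SupportError(ValueError):
    """An observation lies outside the family's support."""


@dataclass(frozen=True)
class Family:
    """A distribution family with fixed auxiliary parameters.

    Parameters
    ----------
    name:
        One of ``gaussian``, ``poisson``, ``binomial``, ``negbin``,
        ``tweedie``, ``trunc_poisson``, ``trunc_negbin``.
    aux:
        Fixed auxiliary parameters: ``theta`` (> 0) for the negative
        binomial families, ``p`` (1 < p < 2) and ``phi`` (> 0) for Tweedie,
        ``n`` (integer >= 1) for binomial, ``sigma2`` (> 0) for Gaussian.
    """

    name: str
    aux: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _FAMILY_NAMES:
            raise ValueError(f"unknown family {self.name!r}")
        object.__setattr__(self, "aux", dict(self.aux))
        if self.name in ("negbin", "trunc_negbin"):
            theta = self.aux.get("theta")
            if theta is None or not theta > 0:
                raise ValueError("negative-binomial families require theta > 0")
        if self.name == "tweedie":
            p = self.aux.get("p")
            phi = self.aux.get("phi", 1.0)
            if p is None or not 1.0 < p < 2.0:
                raise ValueError("tweedie requires power p with 1 < p < 2")
            if not phi > 0:
                raise ValueError("tweedie requires dispersion phi > 0")
            self.aux.setdefault("phi", 1.0)
        if self.name == "binomial":
            n = self.aux.get("n", 1)
            if n < 1 or int(n) != n:
                raise ValueError("binomial requires integer trial count n >= 1")
            self.aux["n"] = int(n)
        if self.name == "gaussian":
            sigma2 = self.aux.get("sigma2", 1.0)
            if not sigma2 > 0:
                raise ValueError("gaussian requires sigma2 > 0")
            self.aux["sigma2"] = float(sigma2)

    # convenient accessors -------------------------------------------------
    @property
    def theta(self) -> float:
        return float(self.aux["theta"])

    @property
    def p(self) -> float:
        return float(self.aux["p"])

    @property
    def phi(self) -> float:
        return float(self.aux["phi"])

    @property
    def n_trials(self) -> int:
        return int(self.aux.get("n", 1))

    @property
    def sigma2(self) -> float:
        return float(self.aux.get("sigma2", 1.0))

    @property
    def is_discrete(self) -> bool:
        return self.name in _DISCRETE

    @property
    def is_truncated(self) -> bool:
        return self.name in _TRUNCATED

    def scale(self) -> float:
        """The exponential-family scale a(phi): sigma2, phi or 1."""
        if self.name == "gaussian":
            return self.sigma2
        if self.name == "tweedie":
            return self.phi
        return 1.0

    def with_aux(self, **kwargs: float) -> "Family":
        aux = dict(self.aux)
        aux.update(kwargs)
        return Family(self.name, aux)


def gaussian(sigma2: float = 1.0) -> Family:
    return Family("gaussian", {"sigma2": sigma2})


def poisson() -> Family:
    return Family("poisson")


def binomial(n: int = 1) -> Family:
    return Family("binomial", {"n": n})


def negbin(theta: float) -> Family:
    return Family("negbin", {"theta": theta})


def tweedie(p: float = 1.5, phi: float = 1.0) -> Family:
    return Family("tweedie", {"p": p, "phi": phi})


def trunc_poisson() -> Family:
    return Family("trunc_poisson")


def trunc_negbin(theta: float) -> Family:
    return Family("trunc_negbin", {"theta": theta})


# ---------------------------------------------------------------------------
# domain / support validation


def check_support(y: np.ndarray, family: Family) -> np.ndarray:
    """Validate observations against the family support; return y as array."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise SupportError(f"non-finite observation at index {bad}")
    if family.name == "gaussian":
        return y
    if np.any(y < 0):
        bad = int(np.flatnonzero(y < 0)[0])
        raise SupportError(f"negative observation at index {bad} for family {family.name}")
    if family.is_discrete and np.any(y != np.round(y)):
        bad = int(np.flatnonzero(y != np.round(y))[0])
        raise SupportError(f"non-integer count at index {bad} for family {family.name}")
    if family.name == "binomial" and np.any(y > family.n_trials):
        bad = int(np.flatnonzero(y > family.n_trials)[0])
        raise SupportError(f"count exceeds n={family.n_trials} trials at index {bad}")
    if family.is_truncated and np.any(y == 0):
        bad = int(np.flatnonzero(y == 0)[0])
        raise SupportError(f"zero observation at index {bad}: zero-truncated support is y >= 1")
    return y


def check_mean_domain(mu: np.ndarray, family: Family) -> np.ndarray:
    """Validate a mean vector against the family's mean domain."""
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(mu)):
        bad = int(np.flatnonzero(~np.isfinite(mu))[0])
        raise DomainError(f"non-finite mean at index {bad}")
    if family.name == "gaussian":
        return mu
    if np.any(mu <= 0):
        bad = int(np.flatnonzero(mu <= 0)[0])
        raise DomainError(f"non-positive mean at index {bad} for family {family.name}")
    if family.name == "binomial" and np.any(mu >= family.n_trials):
        bad = int(np.flatnonzero(mu >= family.n_trials)[0])
        raise DomainError(f"mean >= n={family.n_trials} at index {bad} for binomial family")
    return mu


# ---------------------------------------------------------------------------
# per-observation log densities


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    # NB2 parameterisation: Var = mu + mu^2/theta
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * (np.log(theta) - np.log(mu + theta))
        + y * (np.log(mu) - np.log(mu + theta))
    )


def _poisson_logpmf(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return y * np.log(mu) - mu - gammaln(y + 1)


def _log_p0(mu: np.ndarray, family: Family) -> np.ndarray:
    """log P(Y=0) of the *untruncated* count distribution at mean mu."""
    base = family.name.removeprefix("trunc_")
    if base == "poisson":
        return -mu
    theta = family.theta
    return theta * (np.log(theta) - np.log(mu + theta))


def _tweedie_log_density(y: np.ndarray, mu: np.ndarray, p: float, phi: float) -> np.ndarray:
    """Compound Poisson-gamma log density for 1 < p < 2.

    P(Y = 0) = exp(-lambda) with lambda = mu^(2-p) / (phi (2-p)); positive
    mass is the Poisson-weighted sum of gamma densities with shape
    j*(2-p)/(p-1) and scale phi (p-1) mu^(p-1), evaluated as a series with
    adaptive truncation at relative tail 1e-15 per term.
    """
    y, mu = np.broadcast_arrays(
        np.asarray(y, dtype=float), np.asarray(mu, dtype=float)
    )
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    gam_shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * mu ** (p - 1.0)

    out = np.empty_like(y)
    zero = y == 0
    out[zero] = -lam[zero]
    idx = np.flatnonzero(~zero)
    for i in idx:
        yi, li, si = float(y[i]), float(lam[i]), float(scale[i])
        # terms: Pois(j; lam) * Gamma(y; j*gam_shape, scale)
        j_hat = max(1.0, yi ** (2.0 - p) / (phi * (2.0 - p)))
        j_hi = int(np.ceil(j_hat)) + 40
        terms = None
        while True:
            j = np.arange(1, j_hi + 1, dtype=float)
            terms = (
                j * np.log(li)
                - li
                - gammaln(j + 1)
                + (j * gam_shape - 1.0) * np.log(yi)
                - j * gam_shape * np.log(si)
                - gammaln(j * gam_shape)
                - yi / si
            )
            if terms[-1] < terms.max() - 40.0 or j_hi > 100000:
                break
            j_hi *= 2
        out[i] = logsumexp(terms)
    return out


def _loglik_terms(y: np.ndarray, mu: np.ndarray, family: Family) -> np.ndarray:
    """Per-observation log density log f(y_i; mu_i)."""
    name = family.name
    if name == "gaussian":
        s2 = family.sigma2
        return -0.5 * (np.log(2.0 * np.pi * s2) + (y - mu) ** 2 / s2)
    if name == "poisson":
        return _poisson_logpmf(y, mu)
    if name == "binomial":
        n = family.n_trials
        return (
            gammaln(n + 1)
            - gammaln(y + 1)
            - gammaln(n - y + 1)
            + y * np.log(mu / n)
            + (n - y) * np.log1p(-mu / n)
        )
    if name == "negbin":
        return _nb_logpmf(y, mu, family.theta)
    if name == "tweedie":
        return _tweedie_log_density(y, mu, family.p, family.phi)
    if name == "trunc_poisson":
        return _poisson_logpmf(y, mu) - np.log1p(-np.exp(_log_p0(mu, family)))
    if name == "trunc_negbin":
        return _nb_logpmf(y, mu, family.theta) - np.log1p(-np.exp(_log_p0(mu, family)))
    raise ValueError(name)


def log_likelihood(y, mu, family: Family, *, validate: bool = True) -> float:
    """Total log-likelihood sum_i log f(y_i; psi(mu_i), phi).

    The canonical parameter is obtained from the mean by inverting
    mu = b'(psi); densities are evaluated in their standard closed forms,
    which are algebraically identical to the exponential-family expression.
    """
    if validate:
        y = check_support(y, family)
        mu = check_mean_domain(mu, family)
    else:
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
    mu = np.broadcast_to(mu, y.shape)
    return float(np.sum(_loglik_terms(y, mu, family)))


def _saturated_mu_truncated(y: np.ndarray, family: Family) -> np.ndarray:
    """ML location for each single truncated observation.

    The per-observation likelihood is maximized where the *truncated* mean
    equals y; for y = 1 the supremum is the boundary mu -> 0+, where the
    truncated distribution degenerates to a point mass at 1.
    """
    from scipy.optimize import brentq

    mu = np.empty_like(y)
    for i, yi in enumerate(y):
        if yi <= 1:
            mu[i] = np.nan  # boundary: handled as exact limit (loglik 0)
            continue
        f = lambda m: truncation_adjust(np.array([m]), family)[0] - yi
        mu[i] = brentq(f, 1e-12, max(yi, 50.0) * 2.0, xtol=1e-12, rtol=1e-14)
    return mu


def saturated_loglik(y, family: Family) -> float:
    """Log-likelihood of the full (saturated) model, mu_full = y.

    Boundary observations (y = 0 for count families, y = 0 or n for
    binomial, y = 1 for zero-truncated families) use the analytic limit,
    under which the term y*ln(y) contributes 0 at y = 0 and the limiting
    density value is 1 where the distribution degenerates.
    """
    y = check_support(y, family)
    name = family.name
    if name == "gaussian":
        return float(-0.5 * len(y) * np.log(2.0 * np.pi * family.sigma2))
    if name == "poisson":
        pos = y > 0
        return float(np.sum(_poisson_logpmf(y[pos], y[pos])))
    if name == "binomial":
        n = family.n_trials
        interior = (y > 0) & (y < n)
        yi = y[interior]
        return float(np.sum(_loglik_terms(yi, yi, family))) if yi.size else 0.0
    if name == "negbin":
        pos = y > 0
        return float(np.sum(_nb_logpmf(y[pos], y[pos], family.theta)))
    if name == "tweedie":
        pos = y > 0
        return float(
            np.sum(_tweedie_log_density(y[pos], y[pos], family.p, family.phi))
        )
    if name in _TRUNCATED:
        interior = y > 1
        mu_sat = _saturated_mu_truncated(y[interior], family)
        return float(np.sum(_loglik_terms(y[interior], mu_sat, family)))
    raise ValueError(name)


def deviance(y, mu, family: Family) -> float:
    """Scaled deviance D* = 2 [ l(mu_full; y) - l(mu; y) ] >= 0.

    Twice the Kullback-Leibler divergence between the data and the fitted
    means, within the family.  Zero iff mu = y elementwise.
    """
    return 2.0 * (saturated_loglik(y, family) - log_likelihood(y, mu, family))


def variance_function(mu, family: Family):
    """Var(y) = a(phi) b''(psi) evaluated at mean mu."""
    mu = check_mean_domain(mu, family)
    name = family.name
    if name == "gaussian":
        return np.full_like(mu, family.sigma2)
    if name == "poisson" or name == "trunc_poisson":
        # for truncated families this is the variance of the *untruncated* base
        return mu.copy()
    if name == "binomial":
        return mu * (1.0 - mu / family.n_trials)
    if name == "negbin" or name == "trunc_negbin":
        return mu + mu**2 / family.theta
    if name == "tweedie":
        return family.phi * mu**family.p
    raise ValueError(name)


def truncation_adjust(mu, family: Family):
    """Expected abundance of the zero-truncated distribution.

    For the Poisson, E[y | y > 0] = mu / (1 - exp(-mu)); for the negative
    binomial the zero probability is ((mu + theta)/theta)^(-theta).
    Strictly greater than max(mu, 1) and monotone increasing in mu.
    """
    if not family.is_truncated:
        raise ValueError(
            f"truncation_adjust applies to zero-truncated families, got {family.name}"
        )
    mu = check_mean_domain(mu, family)
    return mu / (-np.expm1(_log_p0(mu, family)))


def kl_divergence(mu_a, mu_b, family: Family) -> float:
    """K(mu_a; mu_b) = 2 [ l(mu_a; mu_a) - l(mu_b; mu_a) ] via psi/b form.

    Treats ``mu_a`` as (possibly non-integer) pseudo-observations; the
    normalizer c cancels, so only the canonical parameter and cumulant are
    needed.  Not defined for the zero-truncated families, whose cumulant
    mean is the truncated mean rather than mu.
    """
    if family.is_truncated:
        raise ValueError("kl_divergence is not defined for zero-truncated families")
    a = np.asarray(mu_a, dtype=float)
    b = check_mean_domain(mu_b, family)
    name = family.name
    if name == "gaussian":
        return float(np.sum((a - b) ** 2) / family.sigma2)
    if name == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(a > 0, a * np.log(a / b), 0.0)
        return float(2.0 * np.sum(t - (a - b)))
    if name == "binomial":
        n = family.n_trials
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(a > 0, a * np.log(a / b), 0.0)
            t2 = np.where(a < n, (n - a) * np.log((n - a) / (n - b)), 0.0)
        return float(2.0 * np.sum(t1 + t2))
    if name == "negbin":
        th = family.theta
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(a > 0, a * np.log(a / b), 0.0)
        return float(
            2.0 * np.sum(t - (a + th) * np.log((a + th) / (b + th)))
        )
    if name == "tweedie":
        p, phi = family.p, family.phi
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(
                a > 0, a * (a ** (1.0 - p) - b ** (1.0 - p)) / (1.0 - p), 0.0
            )
        t2 = (a ** (2.0 - p) - b ** (2.0 - p)) / (2.0 - p)
        return float(2.0 * np.sum(t1 - t2) / phi)
    raise ValueError(name)
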