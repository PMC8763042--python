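"""Maximum-likelihood fitting of CATS regressions.

A CATS regression models a site's abundance vector y (one entry per
species) as a GLM on species traits, optionally with a meta-community
offset on the link scale:

    h(mu_i) = beta_0 + O_i + sum_j beta_j * t_ij

Fisher scoring (IRLS) with step-halving handles every family/link pair
whose likelihood has the standard exponential-family mean structure.  Two
cases need dedicated treatment and get it here: the log-binomial model
(relative-risk regression), where IRLS can leave the mean domain and fail
to reach the ML estimate, is fitted by constrained optimization keeping
eta < ln n; and the zero-truncated count families, whose likelihood is not
of IRLS form in mu, are fitted by direct quasi-Newton maximization of the
exact truncated likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import expfam
from .expfam import Family
from .links import Link, get_link
from .offsets import OffsetVector

__all__ = [
    "DesignSpec",
    "CATSFit",
    "HurdleFit",
    "FitError",
    "fit_cats",
    "fit_log_binomial",
    "estimate_theta",
    "fit_hurdle",
    "predict_relative_abundance",
]

THETA_CAP = 1.0e6

# family -> links with the standard IRLS mean structure; log is allowed for
# every family (it is the recommended link for offset models even where it
# is not canonical).
_ALLOWED_LINKS = {
    "gaussian": {"identity", "log"},
    "poisson": {"log", "identity"},
    "binomial": {"logit", "log", "identity"},
    "negbin": {"log", "identity"},
    "tweedie": {"log"},
    "trunc_poisson": {"log"},
    "trunc_negbin": {"log"},
}

_CANONICAL = {"gaussian": "identity", "poisson": "log", "binomial": "logit"}


class FitError(RuntimeError):
    """Model fitting failed; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class DesignSpec:
    """Species x trait design.

    ``traits`` is an (S, k) matrix (k = 0 or ``traits=None`` means
    intercept-only).  By default trait columns are centered and scaled so
    slopes are comparable across sites.
    """

    traits: np.ndarray | None = None
    standardize: bool = True
    species_ids: tuple | None = None
    trait_names: tuple | None = None

    def __post_init__(self):
        if self.traits is not None:
            t = np.asarray(self.traits, dtype=float)
            if t.ndim == 1:
                t = t[:, None]
            if t.size and not np.all(np.isfinite(t)):
                raise ValueError("trait matrix contains missing/non-finite values")
            self.traits = t

    @property
    def k(self) -> int:
        return 0 if self.traits is None else self.traits.shape[1]

    def matrix(self) -> np.ndarray | None:
        """Trait matrix after optional column standardization."""
        if self.traits is None or self.traits.shape[1] == 0:
            return None
        t = self.traits
        if not self.standardize:
            return t
        sd = t.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (t - t.mean(axis=0)) / sd


@dataclass
class CATSFit:
    """A fitted CATS regression."""

    family: Family
    link_name: str
    coefficients: np.ndarray          # [beta_0, beta_1 ... beta_k]
    mu: np.ndarray                    # fitted means (location parameter)
    expected_abundance: np.ndarray    # = mu except for truncated families
    loglik: float
    deviance: float
    offset: OffsetVector | None
    k: int
    y: np.ndarray
    X: np.ndarray                     # design incl. intercept column
    converged: bool
    n_iter: int
    cov: np.ndarray | None = None
    dispersion: float | None = None   # estimated theta (negbin) or phi
    dispersion_estimated: bool = False
    boundary: bool = False

    @property
    def se(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    @property
    def n_params(self) -> int:
        return self.k + 1 + (1 if self.dispersion_estimated else 0)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def confint(self, level: float = 0.95) -> np.ndarray:
        """Wald confidence intervals, rows = (lower, upper) per coefficient."""
        from scipy.stats import norm

        if self.cov is None:
            raise ValueError("no covariance available for this fit")
        z = norm.ppf(0.5 + level / 2.0)
        se = self.se
        return np.column_stack(
            [self.coefficients - z * se, self.coefficients + z * se]
        )


@dataclass
class HurdleFit:
    """Two-part hurdle fit: presence model plus truncated-count model."""

    binomial_part: CATSFit
    truncated_part: CATSFit
    expected_abundance: np.ndarray
    presence_prob: np.ndarray

    @property
    def loglik(self) -> float:
        return self.binomial_part.loglik + self.truncated_part.loglik


# ---------------------------------------------------------------------------
# internals


def _design_matrix(S: int, design: DesignSpec | None) -> np.ndarray:
    cols = [np.ones(S)]
    if design is not None:
        m = design.matrix()
        if m is not None:
            if m.shape[0] != S:
                raise ValueError(
                    f"trait matrix has {m.shape[0]} rows but y has {S} species"
                )
            cols.append(m)
    return np.column_stack(cols)


def _offset_values(offset, S: int) -> tuple[np.ndarray, OffsetVector | None]:
    if offset is None:
        return np.zeros(S), None
    if isinstance(offset, OffsetVector):
        vals = np.asarray(offset.values, dtype=float)
        off = offset
    else:
        vals = np.asarray(offset, dtype=float)
        off = OffsetVector(vals, "unspecified")
    if len(vals) != S:
        raise ValueError(f"offset length {len(vals)} != number of species {S}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("offset contains non-finite values")
    return vals, off


def _mu_from_eta(eta: np.ndarray, family: Family, link: Link) -> np.ndarray:
    # binomial/logit works on the proportion scale internally: mu = n*expit(eta)
    if family.name == "binomial" and link.name == "logit":
        return family.n_trials / (1.0 + np.exp(-eta))
    return link.inverse(eta)


def _eta_from_mu(mu: np.ndarray, family: Family, link: Link) -> np.ndarray:
    if family.name == "binomial" and link.name == "logit":
        n = family.n_trials
        return np.log(mu / (n - mu))
    return link.fun(mu)


def _dmu_deta(mu: np.ndarray, family: Family, link: Link) -> np.ndarray:
    if family.name == "binomial" and link.name == "logit":
        return mu * (1.0 - mu / family.n_trials)
    return link.dmu_deta(mu)


def _mu_in_domain(mu: np.ndarray, family: Family) -> bool:
    if not np.all(np.isfinite(mu)):
        return False
    if family.name == "gaussian":
        return True
    if np.any(mu <= 0):
        return False
    if family.name == "binomial" and np.any(mu >= family.n_trials):
        return False
    return True


def _start_mu(y: np.ndarray, family: Family) -> np.ndarray:
    if family.name == "gaussian":
        return y.astype(float)
    if family.name == "binomial":
        n = family.n_trials
        return (y + 0.5) / (n + 1.0) * n
    return y + 0.5


def _irls(y, X, off, family: Family, link: Link, max_iter: int = 200, tol: float = 1e-12):
    """Fisher scoring with step-halving on domain exits / likelihood drops."""
    mu = _start_mu(y, family)
    eta = _eta_from_mu(mu, family, link)
    beta = np.zeros(X.shape[1])
    ll = expfam.log_likelihood(y, mu, family, validate=False)
    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        dmu = _dmu_deta(mu, family, link)
        var = expfam.variance_function(mu, family)
        w = dmu**2 / var
        z = (eta - off) + (y - mu) / dmu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = 1.0
        for _ in range(60):
            b = beta + step * (beta_new - beta)
            eta_try = X @ b + off
            mu_try = _mu_from_eta(eta_try, family, link)
            if _mu_in_domain(mu_try, family):
                ll_try = expfam.log_likelihood(y, mu_try, family, validate=False)
                if np.isfinite(ll_try) and (ll_try >= ll - 1e-10 or it == 1):
                    break
            step /= 2.0
        else:
            raise FitError(
                f"IRLS step-halving failed at iteration {it} "
                f"({family.name}/{link.name})",
                trace,
            )
        beta, eta, mu = b, eta_try, mu_try
        ll_new = expfam.log_likelihood(y, mu, family, validate=False)
        trace.append(ll_new)
        if abs(ll_new - ll) < tol * (1.0 + abs(ll_new)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    # expected-information covariance
    dmu = _dmu_deta(mu, family, link)
    var = expfam.variance_function(mu, family)
    w = dmu**2 / var
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = None
    return beta, mu, ll, converged, len(trace) - 1, cov, trace


def _fit_direct(y, X, off, family: Family, link: Link, beta0: np.ndarray):
    """Quasi-Newton maximization of the exact likelihood (truncated families)."""

    def negll(beta):
        eta = X @ beta + off
        mu = _mu_from_eta(eta, family, link)
        if not _mu_in_domain(mu, family):
            return 1e12
        ll = expfam.log_likelihood(y, mu, family, validate=False)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(negll, beta0, method="BFGS", options={"gtol": 1e-9})
    # polish with Nelder-Mead if BFGS stalled on the penalty plateau
    if not res.success:
        res2 = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if res2.fun <= res.fun:
            res = res2
    beta = res.x
    eta = X @ beta + off
    mu = _mu_from_eta(eta, family, link)
    ll = -res.fun
    # numerical observed-information covariance
    cov = None
    try:
        h = _numeric_hessian(negll, beta)
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        pass
    return beta, mu, ll, bool(np.isfinite(ll)), int(getattr(res, "nit", 0)), cov


def _numeric_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            ) / eps**2
    return h


def _finish(y, X, off_array, offset, family, link, beta, mu, ll, converged, n_iter, cov, boundary=False):
    if family.is_truncated:
        expected = expfam.truncation_adjust(mu, family)
    else:
        expected = mu.copy()
    dev = 2.0 * (expfam.saturated_loglik(y, family) - ll)
    return CATSFit(
        family=family,
        link_name=link.name,
        coefficients=beta,
        mu=mu,
        expected_abundance=expected,
        loglik=ll,
        deviance=dev,
        offset=offset,
        k=X.shape[1] - 1,
        y=y,
        X=X,
        converged=converged,
        n_iter=n_iter,
        cov=cov,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# public API


def fit_cats(y, design: DesignSpec | None = None, offset=None, *, family: Family,
             link: str | Link | None = None) -> CATSFit:
    """Fit a CATS regression of abundance on traits with an optional offset.

    Parameters
    ----------
    y:
        Abundance vector (length S) in the family's support.
    design:
        Trait design; ``None`` fits an intercept-only model.
    offset:
        :class:`~catsreg.offsets.OffsetVector` or plain array on the link
        scale; absent means no meta-community information.
    family:
        A :class:`~catsreg.expfam.Family`.
    link:
        Link name; defaults to the family's canonical link where supported
        (identity for Gaussian, log for counts, logit for binomial).
    """
    family_default = {"gaussian": "identity", "binomial": "logit"}
    if link is None:
        link = family_default.get(family.name, "log")
    link = get_link(link)
    if link.name not in _ALLOWED_LINKS[family.name]:
        raise ValueError(
            f"link {link.name!r} not supported for family {family.name!r}; "
            f"allowed: {sorted(_ALLOWED_LINKS[family.name])}"
        )
    y = expfam.check_support(y, family)
    S = len(y)
    X = _design_matrix(S, design)
    if S <= X.shape[1]:
        raise ValueError(f"need more species ({S}) than parameters ({X.shape[1]})")
    off, off_vec = _offset_values(offset, S)

    if family.name == "binomial" and link.name == "log":
        return fit_log_binomial(y, design, offset, n_trials=family.n_trials)

    if family.is_truncated:
        # warm start from the untruncated counterpart
        base = (
            expfam.poisson()
            if family.name == "trunc_poisson"
            else expfam.negbin(family.theta)
        )
        b0, *_ = _irls(y, X, off, base, get_link("log"))
        beta, mu, ll, converged, n_iter, cov = _fit_direct(
            y, X, off, family, link, b0
        )
        return _finish(y, X, off, off_vec, family, link, beta, mu, ll, converged, n_iter, cov)

    beta, mu, ll, converged, n_iter, cov, _ = _irls(y, X, off, family, link)
    fit = _finish(y, X, off, off_vec, family, link, beta, mu, ll, converged, n_iter, cov)
    if family.name == "binomial" and link.name == "logit":
        eta = X @ beta + off
        if np.any(np.abs(eta) > 15):
            warnings.warn(
                "possible separation in binomial fit: |eta| > 15 for some species",
                UserWarning,
                stacklevel=2,
            )
            fit.boundary = True
    return fit


def fit_log_binomial(y, design: DesignSpec | None, offset=None, n_trials: int = 1) -> CATSFit:
    """Binomial regression with a log link (relative-risk regression).

    IRLS is unreliable here because the ML estimate often lies on or near
    the boundary mu = n of the mean domain.  The likelihood is maximized
    directly under the linear constraints eta_i = beta_0 + O_i + x_i beta
    <= ln(n) - eps, starting from a feasible point derived from the data.
    """
    family = expfam.binomial(n_trials)
    link = get_link("log")
    y = expfam.check_support(y, family)
    S = len(y)
    if np.all(y == 0) or np.all(y == n_trials):
        raise FitError("degenerate binomial response: all observations at the same boundary")
    X = _design_matrix(S, design)
    off, off_vec = _offset_values(offset, S)

    eps = 1e-7
    bound = np.log(n_trials) - eps

    # feasible start: intercept matching the mean presence, slopes zero
    p_bar = np.clip(y.mean() / n_trials, 1e-3, 1.0 - 1e-3)
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(p_bar * n_trials) - off.max()
    if np.max(X @ beta0 + off) > bound:
        beta0[0] -= np.max(X @ beta0 + off) - bound + 0.1

    def negll(beta):
        eta = X @ beta + off
        mu = np.exp(np.minimum(eta, bound))
        ll = expfam.log_likelihood(y, mu, family, validate=False)
        return -ll if np.isfinite(ll) else 1e12

    cons = [
        {
            "type": "ineq",
            "fun": lambda beta: bound - (X @ beta + off),
            "jac": lambda beta: -X,
        }
    ]
    res = optimize.minimize(
        negll, beta0, method="SLSQP", constraints=cons,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success and res.fun >= negll(beta0):
        raise FitError(f"log-binomial fit failed: {res.message}")
    beta = res.x
    eta = X @ beta + off
    mu = np.exp(np.minimum(eta, bound))
    ll = expfam.log_likelihood(y, mu, family, validate=False)
    boundary = bool(np.any(eta > bound - 1e-5))
    if boundary:
        warnings.warn(
            "log-binomial ML estimate lies on the mean-domain boundary (mu -> n)",
            UserWarning,
            stacklevel=2,
        )
    cov = None
    if not boundary:
        try:
            cov = np.linalg.inv(_numeric_hessian(negll, beta))
        except np.linalg.LinAlgError:
            pass
    return _finish(
        y, X, off, off_vec, family, link, beta, mu, ll,
        bool(res.success), res.nit, cov, boundary=boundary,
    )


def estimate_theta(y, design: DesignSpec | None = None, offset=None, *,
                   link: str | Link = "log", theta0: float | None = None,
                   max_iter: int = 50, tol: float = 1e-8) -> CATSFit:
    """Negative-binomial fit with dispersion theta estimated by profile ML.

    Alternates Fisher scoring for the regression coefficients at fixed
    theta with one-dimensional profile maximization of theta at fixed
    means, until the joint likelihood stabilizes.  The theta of the
    evaluated model is stored on the fit and is the value that should be
    reused for saturated/null likelihoods in R2 computations.
    """
    y = np.asarray(y, dtype=float)
    if theta0 is None:
        m, v = y.mean(), y.var(ddof=1)
        theta0 = m**2 / max(v - m, m / 10.0)
        theta0 = float(np.clip(theta0, 1e-3, THETA_CAP))
    theta = theta0
    fit = None
    for _ in range(max_iter):
        fit = fit_cats(y, design, offset, family=expfam.negbin(theta), link=link)

        def neg_profile(log_theta):
            fam = expfam.negbin(float(np.exp(log_theta)))
            return -expfam.log_likelihood(y, fit.mu, fam, validate=False)

        res = optimize.minimize_scalar(
            neg_profile, bounds=(np.log(1e-4), np.log(THETA_CAP)), method="bounded",
            options={"xatol": 1e-10},
        )
        theta_new = float(np.exp(res.x))
        if abs(theta_new - theta) <= tol * (1.0 + theta):
            theta = theta_new
            break
        theta = theta_new
    # the bounded profile search stalls shy of the bound; anything within an
    # order of magnitude of the cap means "no finite optimum"
    capped = theta >= THETA_CAP / 10.0
    if capped:
        theta = THETA_CAP
        warnings.warn(
            "estimated theta at cap 1e6: data show no overdispersion "
            "(Poisson-like); consider a Poisson model",
            UserWarning,
            stacklevel=2,
        )
    fit = fit_cats(y, design, offset, family=expfam.negbin(theta), link=link)
    fit.dispersion = theta
    fit.dispersion_estimated = True
    return fit


def fit_hurdle(y, design: DesignSpec | None = None, offsets=None, *,
               family: Family) -> HurdleFit:
    """Two-part hurdle fit: presence/absence plus zero-truncated counts.

    The binomial part models 1[y > 0] with a log link (so presence offsets
    combine with the prior exactly as in the count case); the truncated
    part models the positive abundances only.  The combined expected
    abundance is P(presence) times the truncated mean.
    """
    if not family.is_truncated:
        raise ValueError("fit_hurdle requires a zero-truncated count family")
    y = np.asarray(y, dtype=float)
    pres = (y > 0).astype(float)
    if pres.sum() == 0:
        raise FitError("degenerate hurdle: no positive abundances (truncated part empty)")
    if pres.sum() == len(y):
        raise FitError("degenerate hurdle: no zeros (binomial part is constant)")
    if offsets is None:
        off_b = off_t = None
    else:
        off_b, off_t = offsets
    fit_b = fit_log_binomial(pres, design, off_b, n_trials=1)

    mask = y > 0
    sub_design = None
    if design is not None and design.traits is not None:
        # keep the full-data standardization so coefficients stay comparable
        sub = DesignSpec(design.matrix()[mask], standardize=False)
        sub_design = sub
    sub_off = None
    if off_t is not None:
        vals = off_t.values if isinstance(off_t, OffsetVector) else np.asarray(off_t)
        sub_off = OffsetVector(np.asarray(vals, dtype=float)[mask], "log")
    fit_t = fit_cats(y[mask], sub_design, sub_off, family=family, link="log")

    # combined expectation over all species
    p = fit_b.mu.copy()
    Xfull = _design_matrix(len(y), design)
    off_t_full = (
        np.asarray(off_t.values if isinstance(off_t, OffsetVector) else off_t, dtype=float)
        if off_t is not None
        else np.zeros(len(y))
    )
    mu_t_full = np.exp(Xfull @ fit_t.coefficients + off_t_full)
    expected = p * expfam.truncation_adjust(mu_t_full, family)
    return HurdleFit(fit_b, fit_t, expected, p)


def predict_relative_abundance(fit) -> np.ndarray:
    """Predicted relative abundances: expected abundance, normalized to 1."""
    ey = np.asarray(fit.expected_abundance, dtype=float)
    tot = ey.sum()
    if tot <= 0:
        raise ValueError("total expected abundance is not positive")
    return ey / tot
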