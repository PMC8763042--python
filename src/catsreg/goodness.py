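"""Kullback-Leibler R2, adjusted R2 and variation partitioning.

For exponential-family models the KL divergence between observations and
fitted means is half the scaled deviance, so

    R2_KL = 1 - K(y; mu) / K(y; mu0) = 1 - D*(mu; y) / D*(mu0; y)

with mu0 the prediction of the *null* model.  The null convention matters
once an offset carries meta-community information:

* ``intercept_only`` (default): mu0 comes from a model with an intercept
  and nothing else, even when the evaluated model has an offset.  An
  offset-only model then has a meaningful, generally nonzero R2 — the
  direct measure of the meta-community effect — and R2 can be *negative*
  when the prior moves predictions away from the data.  Negative values
  are reported, never clipped: they mean the meta-community expectation
  worsens the fit.
* ``intercept_plus_offset``: the null keeps the offset, which forces the
  offset-only model's R2 to zero and leaves no direct measure of the
  meta-community effect.  Available for comparison only.

The deviance-based adjustment subtracts the null expectation of the
deviance drop (approximately chi-square with k degrees of freedom):

    R2_adj = [D*(mu0; y) - D*(mu; y) - k] / D*(mu0; y)

which for a Gaussian model with variance estimated as RSS/(n-k-1) reduces
exactly to the classical Ezekiel adjustment 1 - (1-R2)(n-1)/(n-k-1).

Variation partitioning fits models with traits+offset, traits only and
offset only, all measured against the shared intercept-only null, and
splits explained variation into pure-trait (local selection), pure
meta-community, joint and unexplained components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import expfam
from .expfam import Family
from .fitting import CATSFit, DesignSpec, estimate_theta, fit_cats
from .links import get_link
from .offsets import MetaPrior, OffsetVector, offsets_general, offsets_log

__all__ = [
    "R2Result",
    "VariationPartition",
    "r2_kl",
    "r2_poisson_shipley",
    "r2_alternative",
    "r2_adjusted",
    "r2_shipley_adjust",
    "shipley_components",
    "partition",
]


@dataclass(frozen=True)
class R2Result:
    r2_kl: float
    r2_adjusted: float
    r2_likelihood: float
    method: str
    k: int
    null_convention: str


@dataclass(frozen=True)
class VariationPartition:
    r2_both: float
    r2_traits: float
    r2_offset: float
    pure_trait: float
    pure_meta: float
    joint: float
    unexplained: float
    adjusted: bool
    family: str = ""
    link: str = ""
    k: int = 0
    S: int = 0

    def to_dict(self) -> dict:
        return {
            "r2_both": self.r2_both,
            "r2_traits": self.r2_traits,
            "r2_offset": self.r2_offset,
            "pure_trait": self.pure_trait,
            "pure_meta": self.pure_meta,
            "joint": self.joint,
            "unexplained": self.unexplained,
            "adjusted": self.adjusted,
            "family": self.family,
            "link": self.link,
            "k": self.k,
            "S": self.S,
        }


def _check_pair(fit: CATSFit, null_fit: CATSFit) -> None:
    if fit.family.name != null_fit.family.name or dict(fit.family.aux) != dict(
        null_fit.family.aux
    ):
        raise ValueError(
            "evaluated and null fits must share the family and its auxiliary "
            "parameters (use the dispersion estimated for the evaluated model "
            "in both)"
        )
    if len(fit.y) != len(null_fit.y) or not np.allclose(fit.y, null_fit.y):
        raise ValueError("evaluated and null fits must share the response vector")


def _null_convention(null_fit: CATSFit) -> str:
    return "intercept_plus_offset" if null_fit.offset is not None else "intercept_only"


def r2_kl(fit: CATSFit, null_fit: CATSFit) -> R2Result:
    """Kullback-Leibler R2 of ``fit`` against ``null_fit``.

    Computed from scaled deviances; the equivalent likelihood-gap form
    (l(mu) - l(mu0)) / (l(full) - l(mu0)) agrees by construction since the
    deviances come from the same log-likelihoods.  Also reports the
    McFadden-style likelihood-ratio R2 and the k-penalized adjustment.
    """
    _check_pair(fit, null_fit)
    d0 = null_fit.deviance
    if d0 <= 1e-12:
        raise ValueError(
            "null deviance is zero (constant response fits perfectly); R2 undefined"
        )
    r2 = 1.0 - fit.deviance / d0
    ll0 = null_fit.loglik
    r2_l = 1.0 - fit.loglik / ll0 if ll0 != 0 else np.nan
    k = fit.k
    return R2Result(
        r2_kl=r2,
        r2_adjusted=(d0 - fit.deviance - k) / d0,
        r2_likelihood=r2_l,
        method="kl",
        k=k,
        null_convention=_null_convention(null_fit),
    )


def r2_poisson_shipley(y, mu, mu0) -> float:
    """Poisson KL R2 in Shipley's closed form over relative abundances.

    R2 = 1 - sum(o ln(o/p)) / sum(o ln(o/q)) with o, p, q the observed,
    fitted and null relative abundances.  Equals the generic deviance form
    whenever fitted and null models match the observed total (canonical
    log link with an intercept).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Shipley's Poisson R2 requires nonnegative counts")
    o = y / y.sum()
    p = np.asarray(mu, dtype=float)
    p = p / p.sum()
    q = np.asarray(mu0, dtype=float)
    q = q / q.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.where(o > 0, o * np.log(o / p), 0.0).sum()
        den = np.where(o > 0, o * np.log(o / q), 0.0).sum()
    if den == 0:
        raise ValueError("null KL divergence is zero; R2 undefined")
    return float(1.0 - num / den)


def r2_alternative(fit: CATSFit, null_fit: CATSFit) -> float:
    """Bounded alternative R2 = 1 - K(y;mu) / [K(y;mu) + K(mu;mu0)].

    Always in [0, 1]; coincides with the ordinary definition when there is
    no offset (then K(y;mu0) = K(y;mu) + K(mu;mu0) for Gaussian identity
    models), but never goes negative for offset models.
    """
    _check_pair(fit, null_fit)
    k_y_mu = fit.deviance
    k_mu_mu0 = expfam.kl_divergence(fit.mu, null_fit.mu, fit.family)
    denom = k_y_mu + k_mu_mu0
    if denom <= 0:
        raise ValueError("degenerate divergences; alternative R2 undefined")
    return float(1.0 - k_y_mu / denom)


def r2_adjusted(fit: CATSFit, null_fit: CATSFit, k: int | None = None) -> float:
    """Deviance-based adjusted R2: [D0 - D - k] / D0.

    ``k`` counts trait predictors only (defaults to the fit's k); auxiliary
    parameters such as theta are not counted, since the adjustment removes
    the chi-square(k) null expectation of the deviance drop from *added
    predictors*.
    """
    _check_pair(fit, null_fit)
    if k is None:
        k = fit.k
    if k < 0:
        raise ValueError("k must be nonnegative")
    d0 = null_fit.deviance
    if d0 <= 1e-12:
        raise ValueError("null deviance is zero; adjusted R2 undefined")
    return float((d0 - fit.deviance - k) / d0)


# ---------------------------------------------------------------------------
# randomization adjustment and partitioning


def _resolve_offset(prior_or_offset, y, link) -> OffsetVector:
    if isinstance(prior_or_offset, OffsetVector):
        return prior_or_offset
    if isinstance(prior_or_offset, MetaPrior):
        link = get_link(link)
        if link.name == "log":
            return offsets_log(prior_or_offset)
        return offsets_general(prior_or_offset, float(np.sum(y)), link)
    return OffsetVector(np.asarray(prior_or_offset, dtype=float), "unspecified")


def _r2_from_dev(d, d0, k, adjusted):
    return (d0 - d - (k if adjusted else 0)) / d0


def r2_shipley_adjust(y, design: DesignSpec, offset, *, family: Family,
                      link="log", n_random: int = 100, seed: int,
                      adjusted_numerator: bool = False) -> float:
    """Randomization-adjusted pure meta-community effect.

    [R2(traits; offset) - R2(traits)] / [1 - mean R2(random traits)],
    where the denominator averages the R2 of trait-only fits over
    ``n_random`` joint row permutations of the trait matrix (permuting rows
    keeps the trait covariance structure intact).  With
    ``adjusted_numerator=True`` the numerator uses k-penalized R2 values;
    the penalty cancels in the difference, so both variants coincide —
    both are exposed for transparency.
    """
    if design is None or design.k == 0:
        raise ValueError("randomization adjustment needs at least one trait to reshuffle")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    y = np.asarray(y, dtype=float)
    off = _resolve_offset(offset, y, link)
    null = fit_cats(y, None, None, family=family, link=link)
    d0 = null.deviance
    fit_both = fit_cats(y, design, off, family=family, link=link)
    fit_traits = fit_cats(y, design, None, family=family, link=link)
    k = design.k
    num = _r2_from_dev(fit_both.deviance, d0, k, adjusted_numerator) - _r2_from_dev(
        fit_traits.deviance, d0, k, adjusted_numerator
    )
    rng = np.random.default_rng(seed)
    r2_rand = np.empty(n_random)
    base = design.matrix()
    for b in range(n_random):
        perm = rng.permutation(len(y))
        dperm = DesignSpec(base[perm], standardize=False)
        f = fit_cats(y, dperm, None, family=family, link=link)
        r2_rand[b] = 1.0 - f.deviance / d0
    return float(num / (1.0 - r2_rand.mean()))


def shipley_components(y, design: DesignSpec, offset, *, family: Family,
                       link="log", n_random: int = 100, seed: int) -> dict:
    """Pure components via the randomization adjustment.

    ``pure_meta`` follows the randomized formula exactly; ``pure_trait`` is
    the analogous construction with the offset-only model in the numerator:
    [R2(traits; offset) - R2(offset)] / [1 - mean R2(random traits)].
    """
    if design is None or design.k == 0:
        raise ValueError("randomization adjustment needs at least one trait to reshuffle")
    y = np.asarray(y, dtype=float)
    off = _resolve_offset(offset, y, link)
    null = fit_cats(y, None, None, family=family, link=link)
    d0 = null.deviance
    fb = fit_cats(y, design, off, family=family, link=link)
    ft = fit_cats(y, design, None, family=family, link=link)
    fo = fit_cats(y, None, off, family=family, link=link)
    r2b = 1.0 - fb.deviance / d0
    r2t = 1.0 - ft.deviance / d0
    r2o = 1.0 - fo.deviance / d0
    rng = np.random.default_rng(seed)
    base = design.matrix()
    r2_rand = np.empty(n_random)
    for b in range(n_random):
        perm = rng.permutation(len(y))
        f = fit_cats(y, DesignSpec(base[perm], standardize=False), None,
                     family=family, link=link)
        r2_rand[b] = 1.0 - f.deviance / d0
    denom = 1.0 - r2_rand.mean()
    return {
        "pure_meta": float((r2b - r2t) / denom),
        "pure_trait": float((r2b - r2o) / denom),
        "r2_both": float(r2b),
        "r2_traits": float(r2t),
        "r2_offset": float(r2o),
        "mean_r2_random": float(r2_rand.mean()),
    }


def partition(y, design: DesignSpec, prior, *, family: Family, link="log",
              adjusted: bool = True,
              estimate_dispersion: bool = False) -> VariationPartition:
    """Four-component partition of explained variation.

    Fits traits+offset, traits-only and offset-only models (all compared to
    the shared intercept-only null):

    * pure trait effect  = R2(traits; offset) - R2(offset)
    * pure meta-community effect = R2(traits; offset) - R2(traits)
    * joint = R2(traits) + R2(offset) - R2(traits; offset)
    * unexplained = 1 - R2(traits; offset)

    so the four components sum to 1.  With ``adjusted=True`` each R2 is
    k-penalized with its own predictor count (k for trait models, 0 for the
    offset-only model) before differencing.  If ``estimate_dispersion`` is
    set for a negative-binomial family, theta is estimated once on the
    traits+offset model and reused in every nested fit, so deviances stay
    comparable.
    """
    y = np.asarray(y, dtype=float)
    off = _resolve_offset(prior, y, link)
    k = design.k if design is not None else 0

    if estimate_dispersion:
        if family.name != "negbin":
            raise ValueError("dispersion estimation is supported for the negbin family")
        full = estimate_theta(y, design, off, link=link)
        family = full.family
        fits = {"both": full}
    else:
        fits = {"both": _try_fit("traits+offset", y, design, off, family, link)}
    fits["traits"] = _try_fit("traits-only", y, design, None, family, link)
    fits["offset"] = _try_fit("offset-only", y, None, off, family, link)
    null = _try_fit("intercept-only", y, None, None, family, link)
    d0 = null.deviance
    if d0 <= 1e-12:
        raise ValueError("null deviance is zero; partition undefined")

    r2b = _r2_from_dev(fits["both"].deviance, d0, k, adjusted)
    r2t = _r2_from_dev(fits["traits"].deviance, d0, k, adjusted)
    r2o = _r2_from_dev(fits["offset"].deviance, d0, 0, adjusted)
    return VariationPartition(
        r2_both=float(r2b),
        r2_traits=float(r2t),
        r2_offset=float(r2o),
        pure_trait=float(r2b - r2o),
        pure_meta=float(r2b - r2t),
        joint=float(r2t + r2o - r2b),
        unexplained=float(1.0 - r2b),
        adjusted=adjusted,
        family=family.name,
        link=get_link(link).name,
        k=k,
        S=len(y),
    )


def _try_fit(label, y, design, off, family, link) -> CATSFit:
    from .fitting import FitError

    try:
        return fit_cats(y, design, off, family=family, link=link)
    except (FitError, ValueError) as exc:
        raise RuntimeError(f"partition failed while fitting the {label} model: {exc}") from exc
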