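"""Synthetic community generators.

Three generators cover the study conditions every other module is tested
against:

* :func:`simulate_example1` — overdispersed single-plot communities:
  abundances of S species follow a negative binomial with log-mean
  proportional to a normally distributed trait (slope 0.5, theta = 1,
  trait ~ N(10, 3), 20 species, 50 replicate plots by default).
* :func:`simulate_example3` — Poisson communities combining a
  meta-community prior with trait selection of strength s, with the
  intercept chosen so the expected community size is exactly A
  regardless of s (A = 2500, S = 50, standard-normal traits by default).
* :func:`simulate_presence_absence_fixture` — a synthetic presence/absence
  site-by-species matrix with right-skewed occupancy (97 species, 52
  sites), shaped so that some species-site combinations violate the
  logit-offset domain condition pi_i * y_tot < 1, the failure mode that
  motivates the log-link recommendation.

Every generator takes an explicit seed and returns the generating
parameters alongside the draws so tests can use them as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .offsets import MetaPrior, relative_abundances

__all__ = [
    "PlotSim",
    "Example3Sim",
    "simulate_example1",
    "simulate_example3",
    "simulate_presence_absence_fixture",
]


@dataclass(frozen=True)
class PlotSim:
    traits: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    slope: float
    theta: float


@dataclass(frozen=True)
class Example3Sim:
    y: np.ndarray
    lam: np.ndarray
    traits: np.ndarray
    prior: MetaPrior
    intercept: float
    s: float
    A: float


def simulate_example1(n_plots: int = 50, S: int = 20, slope: float = 0.5,
                      theta: float = 1.0, trait_mean: float = 10.0,
                      trait_sd: float = 3.0, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> list[PlotSim]:
    """Replicate plots of overdispersed counts driven by one trait.

    y_i ~ NegBin(mu_i = exp(slope * x_i), theta), x_i ~ N(trait_mean,
    trait_sd), drawn fresh per plot.
    """
    if S < 2:
        raise ValueError("need at least 2 species")
    if n_plots < 1:
        raise ValueError("need at least one plot")
    if theta <= 0 or trait_sd <= 0:
        raise ValueError("theta and trait_sd must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    plots = []
    for _ in range(n_plots):
        x = rng.normal(trait_mean, trait_sd, size=S)
        mu = np.exp(slope * x)
        y = rng.negative_binomial(theta, theta / (theta + mu))
        plots.append(PlotSim(x, y.astype(float), mu, slope, theta))
    return plots


def simulate_example3(S: int = 50, A: float = 2500.0, s: float = 0.0,
                      prior: MetaPrior | None = None,
                      traits: np.ndarray | None = None,
                      prior_kind: str = "dirichlet",
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> Example3Sim:
    """Poisson community with trait selection against a meta-community prior.

    y_i ~ Poisson(lambda_i), log lambda_i = a + log pi_i + s t_i, with the
    intercept a = log A - log sum_i pi_i exp(s t_i) so that the expected
    community size sum(lambda) equals A exactly for any selection strength.

    The prior defaults to a flat Dirichlet draw over the S species
    (``prior_kind="lognormal"`` uses normalized log-normal weights
    instead); traits default to standard normal.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if A <= 0:
        raise ValueError("expected community size A must be positive")
    if prior is None:
        if prior_kind == "dirichlet":
            w = rng.dirichlet(np.ones(S))
        elif prior_kind == "lognormal":
            w = rng.lognormal(0.0, 1.0, size=S)
            w = w / w.sum()
        else:
            raise ValueError(f"unknown prior_kind {prior_kind!r}")
        prior = relative_abundances(w)
    else:
        S = len(prior)
    if traits is None:
        traits = rng.normal(size=S)
    else:
        traits = np.asarray(traits, dtype=float)
        if len(traits) != S:
            raise ValueError("traits length must match the species pool")
    weights = prior.pi * np.exp(s * traits)
    lam = A * weights / weights.sum()
    a = float(np.log(A) - np.log(weights.sum()))
    y = rng.poisson(lam).astype(float)
    return Example3Sim(y, lam, traits, prior, a, float(s), float(A))


def simulate_presence_absence_fixture(S: int = 97, n_sites: int = 52,
                                      seed: int | None = None,
                                      rng: np.random.Generator | None = None):
    """Synthetic presence/absence matrix with right-skewed occupancy.

    Stands in for a field dataset of individual counts reduced to
    presence/absence: most species are rare, a few near-ubiquitous, and
    site "quality" scales richness, so common species at rich sites push
    pi_i * y_tot past 1 and exercise the logit-offset failure path.

    Returns a dict with the binary ``matrix`` (n_sites x S), per-species
    occurrence counts ``meta_counts`` and the derived prior ``pi``.
    """
    if S < 2 or n_sites < 2:
        raise ValueError("need at least 2 species and 2 sites")
    if rng is None:
        rng = np.random.default_rng(seed)
    occ = rng.beta(0.35, 1.3, size=S)
    n_common = max(3, S // 25)
    common = rng.choice(S, size=n_common, replace=False)
    occ[common] = rng.uniform(0.85, 0.97, size=n_common)
    site_quality = rng.lognormal(0.0, 0.45, size=n_sites)
    p = np.clip(occ[None, :] * site_quality[:, None], 0.0, 0.99)
    matrix = (rng.uniform(size=(n_sites, S)) < p).astype(int)
    meta_counts = matrix.sum(axis=0)
    pi = meta_counts / meta_counts.sum() if meta_counts.sum() else np.zeros(S)
    return {"matrix": matrix, "meta_counts": meta_counts, "pi": pi}
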