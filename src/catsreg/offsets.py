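"""Offset construction: encoding the meta-community prior in a GLM.

The meta-community expectation enters a CATS regression as a fixed offset
on the link scale.  With a log link the offset is simply ln(pi_i) (any
additive constant is absorbed by the intercept).  For a general link h the
offsets must instead be built as

    O_i = h(pi_i * y_tot) - h(pi_1 * y_tot) + O_1,

which requires pi_i * y_tot to lie inside the link's domain — the reason a
log link is recommended even where it is not canonical (for a logit link
the construction fails whenever pi_i * y_tot >= 1).

For hurdle (two-part) models the prior enters twice: presence frequencies
give the offsets of the binomial part, and the truncated-count part needs
the *untruncated* location m~ recovered by inverting the truncated-mean
relation m+ = m~ / (1 - exp(-m~)) (Poisson; negative-binomial analogue with
known theta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .expfam import Family, truncation_adjust
from .links import Link, get_link

__all__ = [
    "MetaPrior",
    "OffsetVector",
    "OffsetDomainError",
    "relative_abundances",
    "offsets_log",
    "offsets_general",
    "solve_untruncated_mean",
    "hurdle_offsets",
]


class OffsetDomainError(ValueError):
    """Prior values fall outside the link's domain.

    Attributes
    ----------
    species : list
        Identifiers (or indices) of the offending species.
    """

    def __init__(self, message: str, species):
        super().__init__(message)
        self.species = list(species)


@dataclass(frozen=True)
class MetaPrior:
    """Meta-community mean abundances and derived relative abundances.

    ``pi`` is the normalized mean-abundance vector; species with zero prior
    abundance are flagged in ``zero_prior`` rather than silently carried
    into a model they cannot enter (a log offset would be -inf).
    """

    mean_abundance: np.ndarray
    pi: np.ndarray
    species_ids: tuple = field(default=None)

    @property
    def zero_prior(self) -> np.ndarray:
        """Boolean mask of species with pi_i = 0."""
        return self.pi == 0

    def __len__(self) -> int:
        return len(self.pi)


@dataclass(frozen=True)
class OffsetVector:
    """Per-species offsets on the link scale."""

    values: np.ndarray
    link_name: str

    def __len__(self) -> int:
        return len(self.values)

    def __add__(self, const: float) -> "OffsetVector":
        return OffsetVector(self.values + float(const), self.link_name)


def relative_abundances(mean_abundance, species_ids=None) -> MetaPrior:
    """Normalize meta-community mean abundances: pi_i = m_i / sum(m)."""
    m = np.asarray(mean_abundance, dtype=float)
    if m.ndim != 1 or len(m) < 2:
        raise ValueError("mean_abundance must be a vector of length >= 2")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("mean abundances must be finite and nonnegative")
    tot = m.sum()
    if tot <= 0:
        raise ValueError("degenerate prior: all meta-community abundances are zero")
    ids = tuple(species_ids) if species_ids is not None else None
    return MetaPrior(m, m / tot, ids)


def _zero_species(prior: MetaPrior):
    if prior.species_ids is not None:
        return [prior.species_ids[i] for i in np.flatnonzero(prior.zero_prior)]
    return list(np.flatnonzero(prior.zero_prior))


def offsets_log(prior: MetaPrior) -> OffsetVector:
    """Log-link offsets O_i = ln(pi_i).

    Using ln(mean_abundance) instead would shift every offset by the same
    constant and yield identical fitted means, since only ratios of prior
    relative abundances enter the model.
    """
    if np.any(prior.zero_prior):
        raise OffsetDomainError(
            f"zero prior relative abundance for species {_zero_species(prior)}; "
            "exclude them before building log offsets",
            _zero_species(prior),
        )
    return OffsetVector(np.log(prior.pi), "log")


def offsets_general(
    prior: MetaPrior,
    y_tot: float,
    link,
    O1: float | None = None,
    fallback: str = "error",
) -> OffsetVector:
    """Offsets for an arbitrary link: O_i = h(pi_i * y_tot) - h(pi_1 * y_tot) + O_1.

    By default ``O1 = h(pi_1 * y_tot)``, so the formula simplifies to
    ``O_i = h(pi_i * y_tot)``; for the log link this is ``ln(pi_i) +
    ln(y_tot)``, equivalent to :func:`offsets_log` up to a constant.

    An intercept-only GLM fit with these offsets and the *canonical* link of
    its family reproduces mu_i = pi_i * y_tot, hence predicted relative
    abundances equal to pi.

    Parameters
    ----------
    y_tot:
        Local total abundance (use the observed total of the site).
    fallback:
        ``"error"`` (default) raises :class:`OffsetDomainError` when some
        ``pi_i * y_tot`` lies outside the link domain; ``"log-prior"``
        instead returns ln(pi_i) offsets with a warning — the pragmatic
        choice for presence/absence data, but prior reproduction is then
        guaranteed only under a log link.
    """
    link = get_link(link)
    if y_tot <= 0:
        raise ValueError("y_tot must be positive")
    if np.any(prior.zero_prior):
        raise OffsetDomainError(
            f"zero prior relative abundance for species {_zero_species(prior)}",
            _zero_species(prior),
        )
    target = prior.pi * y_tot
    ok = link.domain(target)
    if not np.all(ok):
        bad = np.flatnonzero(~ok)
        ids = (
            [prior.species_ids[i] for i in bad]
            if prior.species_ids is not None
            else list(bad)
        )
        if fallback == "log-prior":
            warnings.warn(
                f"{len(bad)} species have pi_i * y_tot outside the {link.name} "
                "domain; falling back to ln(pi) offsets. Prior reproduction "
                f"(predicted relative abundances = pi) is then only guaranteed "
                "with a log link.",
                UserWarning,
                stacklevel=2,
            )
            return OffsetVector(np.log(prior.pi), link.name)
        raise OffsetDomainError(
            f"{len(bad)} species have pi_i * y_tot outside the domain of the "
            f"{link.name} link: {ids}",
            ids,
        )
    values = link(target)
    if O1 is not None:
        values = values - values[0] + float(O1)
    return OffsetVector(values, link.name)


def solve_untruncated_mean(mean_when_present: float, family: Family) -> float:
    """Invert the truncated-mean relation: find m~ with E[y | y>0; m~] = m+.

    The truncated mean of a count family always exceeds 1, so no solution
    exists for ``mean_when_present <= 1``.  The relation is strictly
    monotone; a bracketed root search achieves absolute tolerance ~1e-12.
    """
    if not family.is_truncated:
        raise ValueError(
            f"solve_untruncated_mean requires a zero-truncated family, got {family.name}"
        )
    m_plus = float(mean_when_present)
    if m_plus <= 1.0:
        raise ValueError(
            f"infeasible mean-when-present {m_plus}: the truncated mean is always > 1"
        )

    def f(m):
        return float(truncation_adjust(np.array([m]), family)[0]) - m_plus

    lo, hi = 1e-12, max(m_plus, 50.0)
    while f(hi) < 0:  # truncated mean < target: widen bracket
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)


def hurdle_offsets(presence_fraction, mean_when_present, family: Family):
    """Offsets for the two parts of a hurdle model.

    The binomial (presence) part gets log offsets from the relative
    presence frequencies; the truncated-count part gets ln(m~_i), with m~
    recovered from the meta-community mean abundance when present.

    Species never present in the meta-community cannot inform either part;
    they are assigned NaN offsets with a warning and should be dropped from
    the fit.

    Returns
    -------
    (OffsetVector, OffsetVector)
        Offsets for the binomial part and for the truncated part.
    """
    pf = np.asarray(presence_fraction, dtype=float)
    mp = np.asarray(mean_when_present, dtype=float)
    if pf.shape != mp.shape:
        raise ValueError("presence_fraction and mean_when_present must align")
    if np.any((pf < 0) | (pf > 1)):
        raise ValueError("presence fractions must lie in [0, 1]")
    never = pf == 0
    if np.any(never):
        warnings.warn(
            f"{int(never.sum())} species never present in the meta-community; "
            "their hurdle offsets are NaN and they must be excluded from fitting",
            UserWarning,
            stacklevel=2,
        )
    present = ~never
    binom = np.full_like(pf, np.nan)
    binom[present] = np.log(pf[present] / pf[present].sum())
    trunc = np.full_like(pf, np.nan)
    for i in np.flatnonzero(present):
        trunc[i] = np.log(solve_untruncated_mean(mp[i], family))
    return OffsetVector(binom, "log"), OffsetVector(trunc, "log")
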