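"""Link functions used by the fitting and offset layers.

Only the three links the method needs: log (recommended for every family,
since it makes prior relative abundances enter the model exactly through an
additive offset), identity (canonical for Gaussian) and logit (canonical
for binomial).  Each link knows its mean-domain so offsets constructed on
the link scale can be validated before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["Link", "get_link", "LOG", "IDENTITY", "LOGIT"]


@dataclass(frozen=True)
class Link:
    name: str
    fun: Callable[[np.ndarray], np.ndarray]        # h(mu) -> eta
    inverse: Callable[[np.ndarray], np.ndarray]    # h^{-1}(eta) -> mu
    # d mu / d eta, as a function of mu (used in Fisher scoring)
    dmu_deta: Callable[[np.ndarray], np.ndarray]
    domain: Callable[[np.ndarray], np.ndarray]     # boolean mask: mu in domain

    def __call__(self, mu):
        return self.fun(np.asarray(mu, dtype=float))


def _logit(mu):
    return np.log(mu / (1.0 - mu))


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-eta))


LOG = Link(
    "log",
    fun=np.log,
    inverse=np.exp,
    dmu_deta=lambda mu: mu,
    domain=lambda mu: mu > 0,
)

IDENTITY = Link(
    "identity",
    fun=lambda mu: np.asarray(mu, dtype=float),
    inverse=lambda eta: np.asarray(eta, dtype=float),
    dmu_deta=lambda mu: np.ones_like(mu),
    domain=lambda mu: np.isfinite(np.asarray(mu, dtype=float)),
)

# logit on the (0, 1) proportion scale; binomial means are handled as mu/n
LOGIT = Link(
    "logit",
    fun=_logit,
    inverse=_expit,
    dmu_deta=lambda mu: mu * (1.0 - mu),
    domain=lambda mu: (mu > 0) & (mu < 1),
)

_LINKS = {"log": LOG, "identity": IDENTITY, "logit": LOGIT}


def get_link(link) -> Link:
    if isinstance(link, Link):
        return link
    try:
        return _LINKS[link]
    except KeyError:
        raise ValueError(
            f"unknown link {link!r}; available: {sorted(_LINKS)}"
        ) from None
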