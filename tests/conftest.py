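import numpy as np
import pytest

import catsreg as cr


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_counts(rng):
    """A 12-species count community with a mild trait effect and a prior."""
    S = 12
    traits = rng.normal(size=(S, 2))
    mu = np.exp(1.0 + 0.4 * traits[:, 0])
    y = rng.poisson(mu).astype(float)
    y[y.argmin()] = max(y[y.argmin()], 1.0)  # keep the null deviance positive
    prior = cr.relative_abundances(rng.uniform(0.5, 2.0, S))
    return y, cr.DesignSpec(traits), prior
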