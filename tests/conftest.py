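import numpy as np
import pandas as pd
import pytest

import dietrrr as d


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced default cohort (n=250) shared across read-only tests."""
    cfg = d.default_config(seed=11, n_participants=250)
    return d.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def random_xy(rng):
    """A generic random standardized instance (n=80, p=6, q=4)."""
    n, p, q = 80, 6, 4
    X = rng.standard_normal((n, p))
    W = rng.standard_normal((p, q)) * 0.4
    Y = X @ W + rng.standard_normal((n, q))
    Xdf = pd.DataFrame(X, columns=[f"food_{i}" for i in range(p)])
    Ydf = pd.DataFrame(Y, columns=[f"resp_{i}" for i in range(q)])
    return d.standardize(Xdf), d.standardize(Ydf)
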