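import numpy as np
import pandas as pd
import pytest

from nrtmodel import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default 31-subject synthetic cohort, shared across tests."""
    return generate_cohort(default_config(), seed=42)


@pytest.fixture(scope="session")
def small_lmm_data():
    """A small grouped regression dataset with a real random intercept."""
    rng = np.random.default_rng(7)
    n_g, n_i = 6, 8
    groups = np.repeat([f"g{i}" for i in range(n_g)], n_i)
    x1 = rng.normal(size=n_g * n_i)
    x2 = rng.normal(size=n_g * n_i)
    b = np.repeat(rng.normal(0.0, 1.5, n_g), n_i)
    y = 1.0 + 2.0 * x1 - 0.5 * x2 + b + rng.normal(0.0, 0.7, n_g * n_i)
    X = pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2})
    return y, X, groups
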