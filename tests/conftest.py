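import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import whalebrain as wb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_tree():
    """Three-tip tree with hand-traceable covariance."""
    return wb.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def star_tree():
    return wb.parse_newick("(" + ",".join(f"x{i}:1" for i in range(10)) + "):0;")


@pytest.fixture(scope="session")
def cavity_table():
    return wb.load_cavity_measurements()


@pytest.fixture(scope="session")
def eocene_table():
    return wb.load_eocene_archaeocetes()


@pytest.fixture(scope="session")
def registry():
    return wb.default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_loglog_pairs(rng):
    x = rng.uniform(1.0, 500.0, size=10)
    y = 2.5 * x**1.8 * np.exp(rng.normal(0.0, 0.2, size=10))
    return list(zip(x, y))


@pytest.fixture
def specimen_records():
    return pd.DataFrame({
        "taxon": ["Aa", "Aa", "Aa", "Bb", "Bb", "Cc"],
        "maturity": ["adult", "adult", "subadult", "adult", "unknown", "subadult"],
        "ocw_mm": [100.0, 200.0, 80.0, 150.0, 140.0, np.nan],
        "body_mass_kg": [500.0, 700.0, 300.0, np.nan, 800.0, 400.0],
    })
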