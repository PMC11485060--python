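import numpy as np
import pytest

from addint.data import ORAL_CANCER, CountTable
from addint.model_fit import fit_constrained, fit_unconstrained


@pytest.fixture(scope="session")
def oral():
    """Smoking x alcohol x oral-cancer case-control counts (458 subjects)."""
    return ORAL_CANCER


@pytest.fixture(scope="session")
def oral_unconstrained(oral):
    return fit_unconstrained(oral)


@pytest.fixture(scope="session")
def oral_constrained(oral):
    return fit_constrained(oral)


def random_tables(n_tables, seed, min_cell=5, max_cell=200):
    """Well-populated random 2x4 tables for property checks."""
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        cells = rng.integers(min_cell, max_cell, size=8)
        yield CountTable(cases=tuple(cells[:4]), controls=tuple(cells[4:]))
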