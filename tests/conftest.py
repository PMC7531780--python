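import numpy as np
import pytest

from carmine.synthetic import SyntheticSpec, generate_cohort
from carmine.transactions import Item, build_db


def random_db(rng: np.random.Generator, n: int, m: int, density: float = 0.5):
    """A random binary transaction database over items a0..a{m-1}."""
    matrix = rng.random((n, m)) < density
    pool = [Item(f"a{j}", 1) for j in range(m)]
    return build_db(
        [{pool[j] for j in np.flatnonzero(row)} for row in matrix]
    )


@pytest.fixture(scope="session")
def toy_db():
    """Three subjects: {a=1}, {a=1, b=2}, {b=2}."""
    return build_db([{Item("a", 1)}, {Item("a", 1), Item("b", 2)}, {Item("b", 2)}])


@pytest.fixture(scope="session")
def cohort():
    """A study-sized planted cohort (full adherence, 3-noise-sd signatures)."""
    return generate_cohort(SyntheticSpec(), seed=7)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced expression matrix for I/O-heavy tests."""
    return SyntheticSpec(n_probes=800, n_low_variance=600)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, seed=11)
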