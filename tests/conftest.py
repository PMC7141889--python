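import numpy as np
import pytest

from dbalance import CompositionTable, replace_zeros, simulate_counts, six_part_example
from dbalance.synthdata import SimulationSpec


@pytest.fixture(scope="session")
def toy():
    """Six-feature worked example: (table, full SBP)."""
    return six_part_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_table(rng):
    """Strictly positive 12-sample x 8-feature table (lognormal)."""
    return CompositionTable(rng.lognormal(0.0, 1.0, size=(12, 8)))


@pytest.fixture()
def labeled_table(rng):
    """Positive table with balanced binary labels."""
    values = rng.lognormal(0.0, 1.0, size=(20, 6))
    labels = np.array(["a"] * 10 + ["b"] * 10)
    return CompositionTable(values, labels=labels)


@pytest.fixture(scope="session")
def planted_table():
    """Simulated counts with three planted discriminative ratios,
    zero-replaced so every transform applies."""
    spec = SimulationSpec(
        planted_pairs=[(0, 1, 2.0), (2, 3, 2.0), (4, 5, 2.0)], seed=202
    )
    table, truth = simulate_counts(spec)
    return replace_zeros(table), truth
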