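import numpy as np
import pandas as pd
import pytest

from irgpi import GeneSet, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_expr():
    """4 genes x 5 samples with a clear ordering structure."""
    return pd.DataFrame(
        [
            [1.0, 5.0, 2.0, 9.0, 3.0],
            [2.0, 4.0, 2.0, 1.0, 8.0],
            [7.0, 1.0, 6.0, 4.0, 4.0],
            [0.5, 8.0, 6.0, 2.0, 1.0],
        ],
        index=["GA", "GB", "GC", "GD"],
        columns=[f"s{i}" for i in range(5)],
    )


@pytest.fixture
def toy_surv():
    return pd.DataFrame(
        {"time": [12.0, 5.0, 30.0, 18.0, 7.0], "event": [1, 1, 0, 1, 0]},
        index=pd.Index([f"s{i}" for i in range(5)], name="sample"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for unit tests: 150 samples, 40 genes, 4 true pairs."""
    return simulate_cohort(
        SimulationConfig(n_samples=150, n_genes=40, n_true_pairs=4, seed=7)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The standard recovery scenario (600 samples, 150 genes, 8 true pairs)."""
    return simulate_cohort(SimulationConfig(seed=11))


def random_survival(rng, n, tie_heavy=True):
    """Small random censored survival table for oracle comparisons."""
    if tie_heavy:
        time = rng.integers(1, 10, size=n).astype(float)
    else:
        time = np.round(rng.exponential(10.0, size=n), 3) + 0.05
    event = rng.integers(0, 2, size=n)
    return pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index([f"r{i}" for i in range(n)], name="sample")
    )
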