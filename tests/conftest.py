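import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from scgnorm import (
    AbundanceTable,
    GenomeContentMatrix,
    MarkerSet,
    Stage,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        {
            "S1": [1.0, 3.0, 0.0],
            "S2": [2.0, 2.0, 4.0],
        },
        index=["K00001", "K00002", "K00003"],
    )
    return AbundanceTable(data=data, stage=Stage.length_normalized)


@pytest.fixture
def tiny_content():
    # 10 genomes x 3 KOs: A universal single-copy, B present 9/10,
    # C universal but mean copy 1.2
    copies = pd.DataFrame(
        {
            "KO_A": [1] * 10,
            "KO_B": [1] * 9 + [0],
            "KO_C": [1] * 8 + [2, 2],
        },
        index=[f"g{i}" for i in range(10)],
    )
    return GenomeContentMatrix(copies=copies)


@pytest.fixture(scope="session")
def sim():
    """A small simulated study reused by unit tests (not the benchmark run)."""
    return simulate_dataset(n_samples=6, n_reads=30_000, n_kos=200, seed=42)
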