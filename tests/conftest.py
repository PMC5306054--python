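import numpy as np
import pandas as pd
import pytest

from asmpipe.data_io import Dataset
from asmpipe.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_tables():
    """Three transects, five species, two traits — hand-checkable."""
    abundance = pd.DataFrame(
        {
            "spA": [3, 0, 1],
            "spB": [2, 5, 0],
            "spC": [0, 1, 4],
            "spD": [1, 1, 1],
            "spE": [0, 0, 2],
        },
        index=pd.Index(["t1", "t2", "t3"], name="transect_id"),
    )
    traits = pd.DataFrame(
        {
            "length": [1.0, 2.0, 3.0, 4.0, 5.0],
            "gut": [2.0, 1.0, 4.0, 3.0, 6.0],
        },
        index=pd.Index(["spA", "spB", "spC", "spD", "spE"], name="species_id"),
    )
    environment = pd.DataFrame(
        {
            "cluster_id": ["c1", "c1", "c2"],
            "depth": [2.0, 4.0, 8.0],
            "sand": [0.1, 0.5, 0.9],
            "complexity": [1.5, 1.2, 1.0],
        },
        index=pd.Index(["t1", "t2", "t3"], name="transect_id"),
    )
    return abundance, traits, environment


@pytest.fixture
def toy_dataset(toy_tables) -> Dataset:
    abundance, traits, environment = toy_tables
    return Dataset.from_tables(abundance, traits, environment)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small assembled dataset shared across tests (30-species pool)."""
    cfg = SynthConfig(
        n_species_pool=30,
        n_transects=12,
        n_clusters=4,
        richness_range=(12, 18),
        seed=7,
    )
    dataset, truth = generate_dataset(cfg)
    return dataset, truth, cfg
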