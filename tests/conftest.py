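import numpy as np
import pandas as pd
import pytest

from phylosym.datamodel import (
    CountTable, Lineage, SampleMetadata, TaxonomyMap,
)
from phylosym.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_counts() -> CountTable:
    return CountTable(pd.DataFrame(
        [[5, 0], [0, 7], [1, 1]],
        index=["s1", "s2", "s3"], columns=["t1", "t2"],
    ))


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        "t1": Lineage(domain="Bacteria", phylum="Firmicutes",
                      family="Lactobacillaceae", genus="Lactobacillus"),
        "t2": Lineage(domain="Bacteria", phylum="Proteobacteria",
                      genus="Wolbachia"),
    })


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "species": ["F.exsecta", "F.exsecta", "F.lemani"],
        "clade": ["Coptoformica", "Coptoformica", "Serviformica1"],
        "colony": ["c1", "c1", "c2"],
        "run": ["run1", "run1", "run1"],
        "is_control": [False, False, False],
    }, index=["s1", "s2", "s3"]))


@pytest.fixture(scope="session")
def default_dataset():
    """One study-structured synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=11))


def random_count_frame(rng: np.random.Generator, n: int, t: int,
                       low: int = 1, high: int = 80) -> pd.DataFrame:
    """Random strictly-positive-rowsum count table for property tests."""
    counts = rng.integers(low, high, size=(n, t))
    return pd.DataFrame(counts, index=[f"s{i:02d}" for i in range(n)],
                        columns=[f"t{j}" for j in range(t)])
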