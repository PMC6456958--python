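import numpy as np
import pandas as pd
import pytest

from phyllonet import BinaryMatrix, CountMatrix, SpeciesMatrix


def make_counts(values, species, compartment="epiphyte", otus=None):
    """Build a CountMatrix from a dense array and per-sample species labels."""
    values = np.asarray(values)
    samples = [f"s{i + 1}" for i in range(values.shape[0])]
    otus = otus or [f"OTU{j + 1}" for j in range(values.shape[1])]
    meta = pd.DataFrame({
        "plant_species": species,
        "compartment": [compartment] * len(samples),
    }, index=pd.Index(samples, name="sample_id"))
    return CountMatrix(pd.DataFrame(values, index=samples, columns=otus), meta)


def make_species_matrix(values, capacity=8):
    values = np.asarray(values)
    species = [f"plant_{i + 1}" for i in range(values.shape[0])]
    otus = [f"OTU{j + 1}" for j in range(values.shape[1])]
    cap = pd.Series([capacity] * len(species), index=species)
    return SpeciesMatrix(pd.DataFrame(values, index=species, columns=otus),
                         row_capacity=cap)


@pytest.fixture
def small_counts():
    """2 plant species x 2 samples each, 3 OTUs, hand-enumerable."""
    return make_counts(
        [[5, 0, 2],
         [3, 0, 0],
         [0, 7, 1],
         [0, 2, 0]],
        species=["A", "A", "B", "B"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
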