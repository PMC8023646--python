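import numpy as np
import pandas as pd
import pytest

from microrem import AbundanceTable, generate_cohort
from microrem.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (n=110, 44/66, effect fold 2)."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def strong_cohort():
    """A strong-signal cohort (effect fold 4) for classifier checks."""
    return generate_cohort(SimulationConfig(seed=11, effect_fold=4.0))


@pytest.fixture
def toy_relative_table():
    """3 samples x 4 taxa, rows summing to 1."""
    taxa = [
        "p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia",
        "p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Ruminococcus",
        "p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Porphyromonadaceae;g__Parabacteroides",
        "p__Actinobacteria;c__Actinobacteria;o__Bifidobacteriales;f__Bifidobacteriaceae;g__Bifidobacterium",
    ]
    data = pd.DataFrame(
        [[0.25, 0.25, 0.0, 0.5], [0.1, 0.2, 0.3, 0.4], [0.4, 0.4, 0.1, 0.1]],
        index=["A", "B", "C"],
        columns=taxa,
    )
    return AbundanceTable(data=data, normalization="relative")


@pytest.fixture
def toy_count_table():
    taxa = ["g__A", "g__B", "g__C", "g__D"]
    data = pd.DataFrame(
        [[5, 3, 2, 0], [2, 2, 0, 4], [1, 1, 1, 1]],
        index=["A", "B", "C"],
        columns=taxa,
        dtype=float,
    )
    return AbundanceTable(data=data, normalization="raw_counts")


def make_table(values, sample_ids=None, taxa=None, normalization="raw_counts"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    taxa = taxa or [f"g__T{j}" for j in range(p)]
    return AbundanceTable(
        data=pd.DataFrame(values, index=sample_ids, columns=taxa),
        normalization=normalization,
    )
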