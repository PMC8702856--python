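import numpy as np
import pandas as pd
import pytest

from cazytyping import synthetic_data
from cazytyping.annotation_io import GenomeCazymeTable


@pytest.fixture(scope="session")
def default_config():
    """The default (scaled-down) study conditions."""
    return synthetic_data.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_panel(default_config):
    return synthetic_data.simulate_reference_panel(default_config)


@pytest.fixture(scope="session")
def default_cohort(default_config, default_panel):
    return synthetic_data.simulate_cohort(default_config, default_panel)


@pytest.fixture(scope="session")
def tiny_config():
    """A minimal cohort for fast pipeline smoke tests."""
    return synthetic_data.SimulationConfig(
        n_strains=24,
        n_genera=6,
        n_phyla=3,
        families_per_class={"GH": 14, "GT": 8, "CE": 3, "PL": 2, "CBM": 2, "AA": 1},
        n_subjects_per_phenotype=6,
        seed=11,
    )


@pytest.fixture
def toy_table():
    """A hand-built 4-genome, 5-family copy table."""
    counts = pd.DataFrame(
        {
            "GH13": [2, 0, 4, 6],
            "GH2": [1, 1, 0, 0],
            "GT2": [0, 3, 1, 0],
            "PL1": [0, 0, 2, 2],
            "CBM6": [1, 0, 0, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="strain_id"),
    )
    meta = pd.DataFrame(
        {
            "genus": ["Bacteroides", "Bacteroides", "Streptococcus", "Streptococcus"],
            "phylum": ["Bacteroidota", "Bacteroidota", "Firmicutes", "Firmicutes"],
            "genome_size_bp": [5_000_000, 4_200_000, 2_100_000, 2_400_000],
        },
        index=counts.index,
    )
    return GenomeCazymeTable(counts, meta)


def rng(seed=0):
    return np.random.default_rng(seed)
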