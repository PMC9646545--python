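import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from thermomod.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genome_and_binding,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """Default planted-structure dataset: (matrix, metadata, truth)."""
    return simulate_expression(sim_config)


@pytest.fixture(scope="session")
def binding_data(sim_config, sim_data):
    """(genes_bed, coverage, peaks) sharing the session ground truth."""
    _, _, truth = sim_data
    return simulate_genome_and_binding(sim_config, truth), truth


@pytest.fixture()
def toy_matrix():
    """3 genes x 4 samples with hand-checkable values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [0.0, 1.0, 0.0, 1.0]],
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "condition": ["cold", "cold", "heat_shock", "heat_shock"],
            "tissue": ["shoot"] * 4,
            "study": ["toy"] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


def planted_genes(truth):
    return [g for g, c in truth.cluster_of.items() if c != "background"]
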