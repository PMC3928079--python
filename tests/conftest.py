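import numpy as np
import pandas as pd
import pytest

from capra.core import GeneModel, GenomicInterval
from capra.simulate import SimulationConfig, simulate_gene_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=60,
                            genome=(("chr2L", 200_000), ("chrX", 100_000)))


@pytest.fixture(scope="session")
def gene_study(small_config):
    """A small gene-centric simulated study shared across unit tests."""
    return simulate_gene_study(small_config)


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("gA", "gA.t1", "chr2L", 10_000, 13_000, "+",
                  ((10_000, 11_000), (12_000, 13_000))),
        GeneModel("gB", "gB.t1", "chr2L", 30_000, 33_000, "-",
                  ((30_000, 33_000),)),
    ]
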