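import numpy as np
import pytest

from palmflow.genotype_io import GenotypeDataset
from palmflow.synthetic import SimulationConfig, simulate_population


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """4 individuals, 2 loci, one missing call, two stages."""
    return GenotypeDataset(
        ids=["a", "b", "c", "d"],
        stages=["reproductive", "reproductive", "seedling", "seedling"],
        coords=np.array([[0.0, 0.0], [3.0, 4.0], [10.0, 0.0], [10.0, 10.0]]),
        loci=["L1", "L2"],
        genotypes=np.array(
            [
                [[101, 103], [201, 201]],
                [[101, 101], [201, 203]],
                [[103, 103], [0, 0]],
                [[101, 105], [203, 203]],
            ]
        ),
    )


@pytest.fixture(scope="session")
def study_like():
    """One study-scale simulated population (248 plants, 18 loci) with truth."""
    cfg = SimulationConfig(seed=20140000)
    data, truth = simulate_population(cfg)
    return data, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140000)
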