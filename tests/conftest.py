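import numpy as np
import pytest

from phyloniche.popgen import Alignment, PopulationStructure
from phyloniche.raster import PresenceSet, RasterStack
from phyloniche.synthetic import LandscapeSimConfig, simulate_landscape


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four 3-bp sequences with mean pairwise difference 1.5 (π = 0.5)."""
    return Alignment.from_pairs(
        [("s1", "AAA"), ("s2", "AAT"), ("s3", "ATA"), ("s4", "TAA")]
    )


@pytest.fixture
def two_level_structure() -> PopulationStructure:
    """2 groups x 2 populations x 3 individuals."""
    ind_pop = {}
    pop_group = {}
    lat = {}
    for g in ("G1", "G2"):
        for p in ("P1", "P2"):
            pop = f"{g}{p}"
            pop_group[pop] = g
            lat[pop] = 38.0 if p == "P1" else 42.0
            for i in range(3):
                ind_pop[f"{pop}_{i}"] = pop
    return PopulationStructure(ind_pop, pop_group, lat, {})


@pytest.fixture
def small_landscape() -> RasterStack:
    return simulate_landscape(
        LandscapeSimConfig(n_layers=3, rows=60, cols=60, smoothness=2, seed=7)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def presence_from_cells(cells, lineage="test", weights=None) -> PresenceSet:
    return PresenceSet(lineage=lineage, cells=list(cells), weights=weights)
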