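import numpy as np
import pandas as pd
import pytest

from apmap import synthio
from apmap.io_formats import GenotypeMatrix, MarkerMap, PhenotypeMatrix


@pytest.fixture
def small_map() -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1", "chr2"],
                "position": [100, 50_000, 100],
                "cm": [0.0, 10.0, 0.0],
            },
            index=["m1", "m2", "m3"],
        )
    )


@pytest.fixture
def small_genotypes(small_map) -> GenotypeMatrix:
    calls = pd.DataFrame(
        [[0, 0, 1], [0, 1, 0], [1, 0, 1], [1, 1, 0]],
        index=[f"s{i}" for i in range(4)],
        columns=["m1", "m2", "m3"],
        dtype=float,
    )
    return GenotypeMatrix(calls, small_map)


@pytest.fixture(scope="session")
def grid_map() -> MarkerMap:
    return synthio.grid_marker_map()


@pytest.fixture(scope="session")
def cross_1000(grid_map) -> GenotypeMatrix:
    return synthio.simulate_cross(1000, grid_map, seed=11)


def random_phenotypes(n_entities: int, envs, seed: int) -> PhenotypeMatrix:
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_entities, len(envs)))
    return PhenotypeMatrix(
        pd.DataFrame(vals, index=[f"e{i}" for i in range(n_entities)], columns=list(envs))
    )
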