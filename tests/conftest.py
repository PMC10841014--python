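from __future__ import annotations

import numpy as np
import pytest

from liverpare import simdata

#: compact study-shaped dataset shared across tests: the default four-organ
#: x 3-replicate design with planted modules, at a reduced library size
SMALL_CFG = simdata.SimulationConfig(seed=7, library_size=60_000)


@pytest.fixture(scope="session")
def small_dataset() -> simdata.SimulatedDataset:
    return simdata.simulate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def small_profiles(small_dataset):
    from liverpare import degradome as deg

    return {
        organ: deg.map_tags(
            [seq for _, seq in tags], small_dataset.sequences, library_id=organ
        )
        for organ, tags in small_dataset.degradome_libraries.items()
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
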