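import numpy as np
import pytest

from stancekit import PlantParams, pd_critical


@pytest.fixture
def reference_plant() -> PlantParams:
    """Reference system: 50% critical stiffness, 0.14 s delay."""
    return PlantParams()


@pytest.fixture
def reference_critical(reference_plant):
    return pd_critical(reference_plant.S, reference_plant.tau_delay)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231122)
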