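import numpy as np
import pytest

from hypoximap import MURINE_AIF, HUMAN_AIF, PhantomSpec, simulate_phantom


@pytest.fixture
def murine():
    return MURINE_AIF


@pytest.fixture
def human():
    return HUMAN_AIF


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def preclinical_times():
    """10-minute acquisition at the preclinical 14.8 s frame interval."""
    return np.arange(0.0, 600.0, 14.8)


@pytest.fixture
def clinical_times():
    """10-minute acquisition at the clinical 29 s frame interval."""
    return np.arange(0.0, 600.0, 29.0)


@pytest.fixture
def small_phantom():
    """A 24x24 phantom with necrotic core, hypoxic annulus and periphery."""
    return simulate_phantom(PhantomSpec(shape=(24, 24), tumor_radius=9.0, seed=7))
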