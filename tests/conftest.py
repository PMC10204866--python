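import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from layerflow import (
    SemiInfiniteMedium,
    SourceSpec,
    TissueLayer,
    TwoLayerMedium,
    multitau_grid,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the eight probe distances of the simulated instrument (cm)
FD_DISTANCES = np.array([0.8, 1.2, 1.6, 2.0, 2.8, 3.2, 3.6, 4.0])


@pytest.fixture(scope="session")
def fd_source():
    return SourceSpec("FD", modulation_frequency=110e6)


@pytest.fixture(scope="session")
def dcs_source():
    return SourceSpec("DCS", wavelength=785e-7)


@pytest.fixture(scope="session")
def homog_layer():
    return TissueLayer(0.1, 10.0, 1e-8)


@pytest.fixture(scope="session")
def homog_medium(homog_layer):
    """Two-layer medium whose layers are identical (homogeneous limit)."""
    return TwoLayerMedium(homog_layer, homog_layer, thickness=1.2, radius=30.0)


@pytest.fixture(scope="session")
def si_medium(homog_layer):
    return SemiInfiniteMedium(homog_layer)


@pytest.fixture(scope="session")
def layered_medium():
    """Absorbing/flowing contrast between layers, homogeneous scattering."""
    return TwoLayerMedium(
        TissueLayer(0.10, 10.0, 1e-8),
        TissueLayer(0.15, 10.0, 6e-8),
        thickness=1.2, radius=30.0,
    )


@pytest.fixture(scope="session")
def tau_grid():
    return multitau_grid()
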