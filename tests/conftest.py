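import numpy as np
import pytest

from sfx2c.geometry import LYSOZYME_GD_CELL
from sfx2c.simulate import (
    AnomalousScatterer,
    GD_SITES,
    SimConfig,
    desk_geometry,
    make_pseudo_protein,
    simulate_structure_factors,
    simulate_two_colour_image,
    two_colour_beams,
)


@pytest.fixture(scope="session")
def cell():
    return LYSOZYME_GD_CELL


@pytest.fixture(scope="session")
def geom():
    return desk_geometry()


@pytest.fixture(scope="session")
def colours():
    return two_colour_beams()


@pytest.fixture(scope="session")
def scatterer():
    return AnomalousScatterer()


@pytest.fixture(scope="session")
def protein():
    return make_pseudo_protein(300, seed=11)


@pytest.fixture(scope="session")
def sf_set(cell, scatterer, protein, colours):
    """Error-free anomalous structure factors to 3 A, shared across tests."""
    return simulate_structure_factors(cell, GD_SITES, scatterer, protein,
                                      colours, 3.0)


@pytest.fixture(scope="session")
def noise_free_image(cell, geom, colours):
    cfg = SimConfig(seed=7, noise="none", d_min=3.5, colour_ratio_fixed=1.0)
    return simulate_two_colour_image(cell, geom, colours, cfg)


def circular_error_deg(a, b):
    """Absolute circular difference of phase arrays in degrees."""
    return np.degrees(np.abs(np.angle(np.exp(1j * np.radians(
        np.asarray(a, float) - np.asarray(b, float))))))
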