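import numpy as np
import pytest

from trnaflux import (
    CellGeometry2D,
    CompartmentGeometry,
    CytoplasmProfile,
    RateConstants,
)

# Fitted rate constants for the extreme nutritional states; used across
# the suite as realistic parameter sets.
STARVATION = RateConstants(k_in=0.18, k_out=0.06)
FULL_NUTRITION = RateConstants(k_in=0.30, k_out=0.32)
C_STARVATION = 0.055
C_FULL = 0.32


@pytest.fixture
def small_geom() -> CellGeometry2D:
    """Compact imaging geometry (25.6 um field) for fast image tests."""
    return CellGeometry2D(semi_axes=(11.0, 9.0), nucleus_radius=7.0,
                          pixel_size=0.2, shape=(128, 128))


@pytest.fixture
def ring_profile() -> CytoplasmProfile:
    return CytoplasmProfile("peaked-ring", peak_offset=1.0, decay_length=8.0)


@pytest.fixture
def decay_profile() -> CytoplasmProfile:
    return CytoplasmProfile("monotone-decay", decay_length=10.0)


@pytest.fixture
def starvation_geom() -> CompartmentGeometry:
    return CompartmentGeometry.from_composite(C_STARVATION)


def nucleus_center_px(geom: CellGeometry2D) -> tuple[float, float]:
    nuc, _ = geom.masks()
    ys, xs = np.nonzero(nuc)
    return float(ys.mean()), float(xs.mean())
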