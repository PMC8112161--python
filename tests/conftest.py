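"""Shared fixtures: Monte Carlo runs are expensive, so they are produced
once per session and shared across the validation tests."""

import numpy as np
import pytest

import ionct as ic
from ionct.mc import WorldGeometry, simulate_beam


@pytest.fixture(scope="session")
def slab_world():
    return WorldGeometry(shape="slab")


@pytest.fixture(scope="session")
def cylinder_world():
    return WorldGeometry(shape="cylinder")


@pytest.fixture(scope="session")
def proton_strag_tracks(slab_world):
    """Straggling-only 200 MeV protons through the 20 cm slab."""
    return simulate_beam(30_000, 200.0, ic.PROTON, slab_world, seed=1,
                         mcs=False)


@pytest.fixture(scope="session")
def helium_strag_tracks(slab_world):
    return simulate_beam(20_000, 200.0, ic.HELIUM, slab_world, seed=11,
                         mcs=False)


@pytest.fixture(scope="session")
def proton_mcs_tracks(slab_world):
    """MCS-only 200 MeV protons through the 20 cm slab."""
    return simulate_beam(30_000, 200.0, ic.PROTON, slab_world, seed=2,
                         straggling=False)


@pytest.fixture(scope="session")
def proton_pencil_tracks(slab_world):
    """Full-noise pencil beam used for the conditional-spread oracle."""
    return simulate_beam(100_000, 200.0, ic.PROTON, slab_world, seed=3)


@pytest.fixture(scope="session")
def proton_flat_tracks(cylinder_world):
    """Flat-field 200 MeV protons across the cylinder (radiograph noise)."""
    return simulate_beam(150_000, 200.0, ic.PROTON, cylinder_world, seed=5,
                         beam="flat")


@pytest.fixture(scope="session")
def carbon_flat_tracks(cylinder_world):
    return simulate_beam(150_000, 386.9, ic.CARBON, cylinder_world, seed=6,
                         beam="flat")


def smooth_profile(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Moving average with NaNs replaced by the profile mean."""
    filled = np.nan_to_num(values, nan=np.nanmean(values))
    return np.convolve(filled, np.ones(k) / k, mode="same")
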