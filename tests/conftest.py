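import numpy as np
import pytest

from leafspec.synth import (
    GaussianFeature,
    ProfileConfig,
    RedEdge,
    make_class_profiles,
    simulate_informative_bands,
    simulate_spectra,
)


@pytest.fixture(scope="session")
def small_grid() -> np.ndarray:
    """32-band VNIR grid for fast tests (same span as the 256-band default)."""
    return np.linspace(425.0, 965.0, 32)


@pytest.fixture(scope="session")
def small_profiles(small_grid):
    return make_class_profiles(ProfileConfig(wavelengths=small_grid, seed=7))


@pytest.fixture(scope="session")
def small_spectra(small_profiles):
    """One polymer, 3 concentration classes, 40 samples each, 32 bands."""
    return simulate_spectra(small_profiles.restrict("PET"), n_per_class=40, seed=11)


@pytest.fixture(scope="session")
def noiseless_profiles(small_grid):
    return make_class_profiles(ProfileConfig(wavelengths=small_grid, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def planted_spectra():
    """3 informative bands out of 20; ground truth for selector recovery."""
    return simulate_informative_bands(
        n_per_class=30, n_bands=20, informative=(4, 11, 17), effect=0.08,
        noise_sd=0.02, seed=5,
    )


@pytest.fixture
def single_trough_config():
    """One absorption trough at 660 nm, depth 0.30, on a flat 0.45 base."""
    return ProfileConfig(
        wavelengths=np.linspace(600.0, 700.0, 11),
        polymers=("PET",),
        concentrations=(0,),
        base_level=0.45,
        features=(GaussianFeature(660.0, 20.0, -0.30, "trough"),),
        red_edge=RedEdge(amplitude=0.0),
        noise_sd=0.0,
    )
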