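import numpy as np
import pytest

from glidebuoy import CTDProfile, density_profile_from_ctd


@pytest.fixture(scope="session")
def stratified_ctd():
    """A warm-surface, stratified cast down to 600 m (temperate-shelf-like)."""
    depth = np.arange(0.0, 601.0, 50.0)
    temperature = 5.0 + 12.0 * np.exp(-depth / 150.0)
    return CTDProfile(depth=depth, temperature=temperature, salinity=35.0)


@pytest.fixture(scope="session")
def density_profile(stratified_ctd):
    return density_profile_from_ctd(stratified_ctd)


@pytest.fixture(scope="session")
def constant_ocean():
    """Constant-density ocean used where the water column is immaterial."""
    return lambda d: np.full_like(np.asarray(d, dtype=float), 1027.0)
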