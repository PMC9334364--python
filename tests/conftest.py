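import numpy as np
import pytest

from holotrack import OpticalConfig, SimulationConfig


@pytest.fixture
def small_config() -> OpticalConfig:
    """A fast 64×64 grid with the package's default optics."""
    return OpticalConfig(grid_shape=(64, 64))


@pytest.fixture
def small_sim(small_config) -> SimulationConfig:
    return SimulationConfig(optical=small_config, z2=60.0, sample_depth=20.0)


def band_limited_field(config: OpticalConfig, rng: np.random.Generator, fraction: float = 0.4):
    """Random complex field whose spectrum stays well inside the propagating circle.

    Such fields carry no evanescent content, so angular-spectrum
    propagation acts unitarily on them.
    """
    rows, cols = config.grid_shape
    fy = np.fft.fftfreq(rows, d=config.pixel_pitch)
    fx = np.fft.fftfreq(cols, d=config.pixel_pitch)
    k_lat2 = (2 * np.pi * fx[None, :]) ** 2 + (2 * np.pi * fy[:, None]) ** 2
    k = 2 * np.pi * config.medium_index / config.wavelength
    keep = k_lat2 < (fraction * k) ** 2
    spectrum = (rng.normal(size=(rows, cols)) + 1j * rng.normal(size=(rows, cols))) * keep
    return np.fft.ifft2(spectrum)
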