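"""Optical-system configuration shared by the simulator and the tracker.

Units are micrometres throughout the package; the only pixel-typed
quantities are explicitly named so (window sizes, areas).

Coordinate convention: ``x`` runs along columns and ``y`` along rows, both
measured in µm from the centre of the top-left pixel; ``z`` increases from
the light source toward the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of a simple in-line holographic system.

    Parameters
    ----------
    wavelength
        Vacuum wavelength of the (monochromatic, coherent) illumination, µm.
    medium_index
        Real refractive index n0 of the immersion medium (1.33 ≈ water).
    pixel_pitch
        Detector pixel size, µm; pixels are square.
    grid_shape
        (rows, cols) of the sampling grid / detector.
    bpm_slice_thickness
        Axial step dz of the split-step beam propagation, µm.
    """

    wavelength: float = 0.532
    medium_index: float = 1.33
    pixel_pitch: float = 0.4
    grid_shape: tuple[int, int] = (500, 500)
    bpm_slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ConfigError(f"wavelength must be > 0, got {self.wavelength}")
        if self.pixel_pitch <= 0:
            raise ConfigError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")
        if self.bpm_slice_thickness <= 0:
            raise ConfigError(
                f"bpm_slice_thickness must be > 0, got {self.bpm_slice_thickness}"
            )
        rows, cols = self.grid_shape
        if rows < 16 or cols < 16:
            raise ConfigError(f"grid dimensions must be >= 16, got {self.grid_shape}")
        if self.medium_index < 1:
            raise ConfigError(f"medium_index must be >= 1, got {self.medium_index}")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber 2π/λ, rad/µm."""
        return 2.0 * np.pi / self.wavelength

    @property
    def k_medium(self) -> float:
        """Wavenumber in the background medium 2π·n0/λ, rad/µm."""
        return 2.0 * np.pi * self.medium_index / self.wavelength

    @property
    def field_of_view(self) -> tuple[float, float]:
        """Lateral extent (width_x, height_y) of the grid, µm."""
        rows, cols = self.grid_shape
        return (cols * self.pixel_pitch, rows * self.pixel_pitch)

    def pixel_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate vectors of pixel centres, µm."""
        rows, cols = self.grid_shape
        x = np.arange(cols, dtype=float) * self.pixel_pitch
        y = np.arange(rows, dtype=float) * self.pixel_pitch
        return x, y


@dataclass(frozen=True)
class GaussianBackground:
    """Parameters of the Gaussian illumination background B(x, y).

    ``B(x, y) = offset + amplitude · exp(−((x−cx)² + (y−cy)²) / (2·width²))``
    with all lengths in µm.
    """

    amplitude: float = 0.5
    center: tuple[float, float] = (100.0, 100.0)
    width: float = 150.0
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"background width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ConfigError(f"background amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to turn a bead scene into a hologram sequence.

    Parameters
    ----------
    optical
        Shared optical geometry.
    z2
        Distance from the sample exit plane to the detector, µm.
    sample_depth
        Axial thickness z1 of the declared sample volume, µm.
    background
        ``"flat"`` (B ≡ 1) or a :class:`GaussianBackground`.
    snr
        Hologram signal-to-noise ratio; ``inf`` means noise-free.  The
        additive noise is zero-mean white Gaussian with standard deviation
        σ_signal / snr, where σ_signal is the standard deviation of the
        noiseless hologram about its mean.
    seed
        Seed of the noise stream; sequences are bit-reproducible from it.
    hologram_model
        ``"literal"``: H = B·(1 + |u|²) + N with u the total propagated
        field of a unit incident plane wave.  ``"intensity_only"``:
        H = B·|u|² + N, the textbook Gabor intensity.
    pad_factor
        FFT zero-padding factor for the propagation steps (1 = off).
    """

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    z2: float = 150.0
    sample_depth: float = 110.0
    background: GaussianBackground | str = "flat"
    snr: float = float("inf")
    seed: int = 0
    hologram_model: str = "literal"
    pad_factor: int = 1

    def __post_init__(self) -> None:
        if self.z2 <= 0:
            raise ConfigError(f"z2 must be > 0, got {self.z2}")
        if self.sample_depth <= 0:
            raise ConfigError(f"sample_depth must be > 0, got {self.sample_depth}")
        if not self.snr > 0:
            raise ConfigError(f"snr must be > 0 (use inf for noise-free), got {self.snr}")
        if self.hologram_model not in ("literal", "intensity_only"):
            raise ConfigError(f"unknown hologram_model {self.hologram_model!r}")
        if isinstance(self.background, str) and self.background != "flat":
            raise ConfigError(f"background must be 'flat' or GaussianBackground")
        if self.pad_factor < 1 or int(self.pad_factor) != self.pad_factor:
            raise ConfigError(f"pad_factor must be a positive integer")
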