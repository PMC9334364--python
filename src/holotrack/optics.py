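"""Scalar diffraction engine.

Two propagators:

* :func:`angular_spectrum_propagate` — exact free-space propagation of a
  monochromatic scalar field through a homogeneous medium, implemented as
  multiplication of the field's spatial-frequency spectrum by the transfer
  function ``exp(i·z·sqrt(k² − kx² − ky²))`` with ``k = 2π·n0/λ``.
  Evanescent components (kx² + ky² > k²) are zeroed.

* :func:`bpm_propagate` — split-step beam propagation through an
  inhomogeneous (bead-filled) volume: for every slice, multiply by a thin
  phase-and-absorption screen ``exp(i·k0·(n(x,y) − n0)·dz)`` and diffract
  by dz in the homogeneous background.  The sequential composition of
  screens and diffraction steps captures forward multiple scattering.

Both support optional FFT zero-padding (``pad_factor``) against periodic
wrap-around of edge fringes; the default leaves it off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import OpticalConfig
from .errors import ConfigError, DimensionError, GeometryError, InvalidFieldError
from .scene import Bead


@dataclass
class ComplexField:
    """A 2D complex optical field sampled on the configuration grid.

    plane_z is the axial coordinate (µm) of the sampling plane, increasing
    from source toward detector.
    """

    values: np.ndarray
    plane_z: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2:
            raise DimensionError(f"field must be 2D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2


@dataclass
class RefractiveVolume:
    """Voxelized complex refractive index n + iκ, shape (rows, cols, slices)."""

    complex_index: np.ndarray
    slice_thickness: float

    def __post_init__(self) -> None:
        self.complex_index = np.asarray(self.complex_index)
        if self.complex_index.ndim != 3:
            raise DimensionError(
                f"refractive volume must be 3D, got shape {self.complex_index.shape}"
            )
        if self.slice_thickness <= 0:
            raise ConfigError(
                f"slice_thickness must be > 0, got {self.slice_thickness}"
            )

    @property
    def n_slices(self) -> int:
        return self.complex_index.shape[2]

    @property
    def thickness(self) -> float:
        return self.n_slices * self.slice_thickness


def plane_wave(config: OpticalConfig, plane_z: float = 0.0) -> ComplexField:
    """Unit-amplitude plane wave at normal incidence."""
    return ComplexField(np.ones(config.grid_shape, dtype=complex), plane_z)


def _axial_wavenumber(
    shape: tuple[int, int], config: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """kz grid and propagating-wave mask for the given (possibly padded) shape."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=config.pixel_pitch)
    fx = np.fft.fftfreq(cols, d=config.pixel_pitch)
    kx2 = (2.0 * np.pi * fx[None, :]) ** 2
    ky2 = (2.0 * np.pi * fy[:, None]) ** 2
    k = config.k_medium
    arg = k**2 - kx2 - ky2
    mask = arg >= 0.0
    kz = np.sqrt(np.where(mask, arg, 0.0))
    return kz, mask


def _check_field(field: ComplexField, config: OpticalConfig) -> None:
    if not np.all(np.isfinite(field.values)):
        raise InvalidFieldError("field contains non-finite values")
    if field.shape != tuple(config.grid_shape):
        raise DimensionError(
            f"field shape {field.shape} does not match grid {config.grid_shape}"
        )


def angular_spectrum_propagate(
    field: ComplexField,
    distance: float,
    config: OpticalConfig,
    pad_factor: int = 1,
) -> ComplexField:
    """Propagate a field by ``distance`` (µm, may be negative) in free space.

    Returns a new field with ``plane_z`` advanced by ``distance``.
    """
    _check_field(field, config)
    values = field.values
    rows, cols = values.shape
    if pad_factor > 1:
        pr, pc = rows * (pad_factor - 1) // 2, cols * (pad_factor - 1) // 2
        values = np.pad(values, ((pr, pr), (pc, pc)))
    kz, mask = _axial_wavenumber(values.shape, config)
    spectrum = np.fft.fft2(values)
    spectrum *= np.where(mask, np.exp(1j * distance * kz), 0.0)
    out = np.fft.ifft2(spectrum)
    if pad_factor > 1:
        out = out[pr : pr + rows, pc : pc + cols]
    return ComplexField(out, field.plane_z + distance)


def bpm_propagate(
    field: ComplexField,
    volume: RefractiveVolume,
    config: OpticalConfig,
    pad_factor: int = 1,
) -> ComplexField:
    """Split-step propagation through an inhomogeneous volume.

    Per slice: thin-screen multiplication ``exp(i·k0·(n − n0)·dz)`` followed
    by an angular-spectrum diffraction step over dz in the background
    medium.  ``plane_z`` advances by the full volume thickness.
    """
    _check_field(field, config)
    if volume.complex_index.shape[:2] != field.shape:
        raise DimensionError(
            f"volume lateral shape {volume.complex_index.shape[:2]} does not "
            f"match field shape {field.shape}"
        )
    if volume.n_slices < 1:
        raise ConfigError("refractive volume must have at least one slice")
    dz = volume.slice_thickness
    k0 = config.k0
    n0 = config.medium_index
    current = field
    for s in range(volume.n_slices):
        contrast = volume.complex_index[:, :, s] - n0
        if np.any(contrast != 0):
            screened = current.values * np.exp(1j * k0 * contrast * dz)
        else:
            screened = current.values
        current = angular_spectrum_propagate(
            ComplexField(screened, current.plane_z), dz, config, pad_factor
        )
    return current


def rasterize_beads(
    beads: list[Bead],
    config: OpticalConfig,
    volume_depth: float,
) -> RefractiveVolume:
    """Voxelize spherical beads into a refractive-index volume.

    The volume spans the lateral field of view and depth ``[0, volume_depth]``
    with slice thickness ``config.bpm_slice_thickness``; a voxel centre
    falling inside any bead receives that bead's complex index (last writer
    wins on overlap), all others the background index n0.
    """
    if volume_depth <= 0:
        raise ConfigError(f"volume_depth must be > 0, got {volume_depth}")
    rows, cols = config.grid_shape
    dz = config.bpm_slice_thickness
    n_slices = max(1, int(round(volume_depth / dz)))
    vol = np.full((rows, cols, n_slices), config.medium_index, dtype=complex)
    pitch = config.pixel_pitch
    fov_x, fov_y = config.field_of_view
    z_centers = (np.arange(n_slices) + 0.5) * dz
    for i, bead in enumerate(beads):
        cx, cy, cz = bead.center
        r = bead.radius
        if not (0.0 <= cx <= fov_x and 0.0 <= cy <= fov_y):
            raise GeometryError(
                f"bead {i} at ({cx:.2f}, {cy:.2f}, {cz:.2f}) µm lies outside "
                f"the lateral field of view"
            )
        if cz - r < -1e-9 or cz + r > volume_depth + 1e-9:
            raise GeometryError(
                f"bead {i} at depth {cz:.2f} µm (radius {r:.2f}) extends outside "
                f"the axial range [0, {volume_depth:.2f}] µm"
            )
        # restrict to the bead's bounding box for speed
        c0 = max(0, int(np.floor((cx - r) / pitch)))
        c1 = min(cols - 1, int(np.ceil((cx + r) / pitch)))
        r0 = max(0, int(np.floor((cy - r) / pitch)))
        r1 = min(rows - 1, int(np.ceil((cy + r) / pitch)))
        s_in = np.nonzero(np.abs(z_centers - cz) <= r)[0]
        if not s_in.size or c1 < c0 or r1 < r0:
            continue
        xs = np.arange(c0, c1 + 1) * pitch - cx
        ys = np.arange(r0, r1 + 1) * pitch - cy
        lat2 = ys[:, None] ** 2 + xs[None, :] ** 2
        for s in s_in:
            rad2 = bead.radius**2 - (z_centers[s] - cz) ** 2
            inside = lat2 <= rad2
            block = vol[r0 : r1 + 1, c0 : c1 + 1, s]
            block[inside] = bead.complex_index
    return RefractiveVolume(vol, dz)
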