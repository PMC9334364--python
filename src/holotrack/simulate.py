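"""Gabor hologram simulation with multiple scattering.

A single hologram is produced by (1) voxelizing the bead scene into a
refractive-index volume, (2) propagating a unit plane wave through it with
the split-step beam propagation method, (3) angular-spectrum propagation
of the exit field to the detector, and (4) forming the recorded intensity

    H(x, y) = B(x, y) · (1 + |u(x, y)|²) + N(x, y)

where ``u`` is the total propagated field, ``B`` the (Gaussian or flat)
illumination background and ``N`` zero-mean white Gaussian noise whose
standard deviation is σ_signal / SNR (σ_signal = std of the noiseless
hologram about its mean).  The alternative ``intensity_only`` model
H = B·|u|² + N is available through the configuration.

Ground truth is emitted in the tracker's coordinate convention: the axial
coordinate of a bead is its backpropagation distance from the detector,
``z = z2 + (sample_depth − depth_in_sample)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GaussianBackground, OpticalConfig, SimulationConfig
from .errors import GeometryError
from .optics import angular_spectrum_propagate, bpm_propagate, plane_wave, rasterize_beads
from .scene import Bead, TrajectorySet, check_no_overlap

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = ["frame", "bead_id", "x_um", "y_um", "z_um", "diameter_um"]


@dataclass
class HologramFrame:
    """One recorded hologram: non-negative intensity plus its frame index."""

    intensity: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise GeometryError(
                f"hologram must be 2D, got shape {self.intensity.shape}"
            )


def gaussian_background(
    params: GaussianBackground | str, config: OpticalConfig
) -> np.ndarray:
    """Evaluate the background intensity B(x, y) on the pixel grid."""
    if isinstance(params, str):
        if params != "flat":
            raise GeometryError(f"unknown background spec {params!r}")
        return np.ones(config.grid_shape)
    x, y = config.pixel_coordinates()
    cx, cy = params.center
    r2 = (y[:, None] - cy) ** 2 + (x[None, :] - cx) ** 2
    return params.offset + params.amplitude * np.exp(-r2 / (2.0 * params.width**2))


def propagate_scene(
    beads: list[Bead], sim: SimulationConfig
) -> np.ndarray:
    """Return the complex field u at the detector for a single scene.

    The rasterized volume is padded axially by one maximal bead radius on
    each side so spheres centred at the declared volume faces still fit;
    the remaining free-space distance to the detector is covered by a
    single angular-spectrum step.
    """
    config = sim.optical
    dz = config.bpm_slice_thickness
    if beads:
        pad = math.ceil(max(b.radius for b in beads) / dz) * dz
    else:
        pad = 0.0
    if sim.z2 <= pad:
        raise GeometryError(
            f"z2 = {sim.z2} µm must exceed the axial padding {pad} µm"
        )
    depth = sim.sample_depth + 2.0 * pad
    shifted = [
        Bead((b.center[0], b.center[1], b.center[2] + pad), b.diameter, b.complex_index)
        for b in beads
    ]
    field = plane_wave(config)
    if shifted:
        volume = rasterize_beads(shifted, config, depth)
        field = bpm_propagate(field, volume, config, sim.pad_factor)
    remaining = sim.z2 - pad if shifted else sim.z2
    field = angular_spectrum_propagate(field, remaining, config, sim.pad_factor)
    return field.values


def simulate_hologram(
    beads: list[Bead],
    sim: SimulationConfig,
    rng: np.random.Generator | None = None,
    frame_index: int = 0,
) -> HologramFrame:
    """Simulate one Gabor hologram of a static bead scene.

    ``rng`` drives the additive noise; omit it to use ``sim.seed``.
    With ``snr = inf`` the result is deterministic and noise-free.
    """
    if beads:
        pos = np.array([b.center for b in beads])
        dia = np.array([b.diameter for b in beads])
        bad = check_no_overlap(pos, dia)
        if bad.size:
            raise GeometryError(f"beads {bad.tolist()} overlap")
    u = propagate_scene(beads, sim)
    b = gaussian_background(sim.background, sim.optical)
    if sim.hologram_model == "literal":
        clean = b * (1.0 + np.abs(u) ** 2)
    else:
        clean = b * np.abs(u) ** 2
    if np.isinf(sim.snr):
        h = clean
    else:
        if rng is None:
            rng = np.random.default_rng(sim.seed)
        sigma_signal = float(np.std(clean))
        noise = rng.normal(0.0, sigma_signal / sim.snr, size=clean.shape)
        h = clean + noise
        n_neg = int(np.count_nonzero(h < 0))
        if n_neg:
            logger.warning(
                "clipped %d negative intensities to 0 in frame %d", n_neg, frame_index
            )
            h = np.clip(h, 0.0, None)
    return HologramFrame(h, frame_index)


def simulate_sequence(
    traj: TrajectorySet, sim: SimulationConfig
) -> tuple[list[HologramFrame], pd.DataFrame]:
    """Simulate one hologram per trajectory frame plus the ground-truth table.

    Noise is drawn frame by frame from a single stream seeded with
    ``sim.seed``, making the whole sequence bit-reproducible.  The returned
    table has columns ``frame, bead_id, x_um, y_um, z_um, diameter_um``
    with z the backpropagation distance from the detector.
    """
    if abs(traj.volume_dims[2] - sim.sample_depth) > 1e-6:
        raise GeometryError(
            f"trajectory volume depth {traj.volume_dims[2]} µm does not match "
            f"configured sample_depth {sim.sample_depth} µm"
        )
    rng = np.random.default_rng(sim.seed)
    frames: list[HologramFrame] = []
    records = []
    for t in range(traj.n_frames):
        try:
            frames.append(simulate_hologram(traj.beads_at(t), sim, rng, frame_index=t))
        except GeometryError as exc:
            raise GeometryError(f"frame {t}: {exc}") from exc
        for i in range(traj.n_beads):
            x, y, depth = traj.positions[t, i]
            records.append(
                (t, i, x, y, sim.z2 + (sim.sample_depth - depth), traj.diameters[i])
            )
    truth = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    return frames, truth


def volume_for_concentration(
    n_beads: int,
    concentration_per_mm3: float,
    config: OpticalConfig,
) -> tuple[float, float, float]:
    """Sample-volume dimensions giving the requested bead concentration.

    The lateral extent is the full field of view; the depth is chosen so
    that ``n_beads / volume`` equals ``concentration_per_mm3`` (1 mm³ =
    10⁹ µm³).
    """
    fov_x, fov_y = config.field_of_view
    volume_um3 = n_beads / (concentration_per_mm3 * 1e-9)
    depth = volume_um3 / (fov_x * fov_y)
    return (fov_x, fov_y, depth)
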