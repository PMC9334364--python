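"""Scene description: beads and their trajectories.

A scene lives in a rectangular sample volume whose axial coordinate runs
from 0 (illumination-side face) to ``depth`` (detector-side face).  Bead
centres are expressed in that frame; the simulator converts them to
detector-referenced backpropagation distances when emitting ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConcentrationInfeasibleError, GeometryError


@dataclass(frozen=True)
class Bead:
    """A spherical scatterer.

    center is (x, y, z) in µm; z is depth inside the sample volume.
    complex_index is n + iκ with n ≥ 1 and κ ≥ 0 (absorbing convention).
    """

    center: tuple[float, float, float]
    diameter: float = 5.0
    complex_index: complex = 1.59 + 0.0j

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError(f"bead diameter must be > 0, got {self.diameter}")
        if self.complex_index.real < 1:
            raise GeometryError(
                f"bead refractive index must be >= 1, got {self.complex_index}"
            )
        if self.complex_index.imag < 0:
            raise GeometryError(
                f"bead extinction must be >= 0, got {self.complex_index}"
            )

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


def check_no_overlap(
    positions: np.ndarray, diameters: np.ndarray
) -> np.ndarray:
    """Return indices of beads whose surfaces intersect another bead's.

    positions: (n, 3) centres in µm; diameters: (n,) in µm.
    """
    n = len(positions)
    if n < 2:
        return np.empty(0, dtype=int)
    delta = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((delta**2).sum(-1))
    min_sep = 0.5 * (diameters[:, None] + diameters[None, :])
    bad = (dist <= min_sep) & ~np.eye(n, dtype=bool)
    return np.unique(np.nonzero(bad)[0])


@dataclass(frozen=True)
class MotionParams:
    """Reflected Gaussian random walk with optional constant drift.

    step_std is the per-frame, per-axis standard deviation of the random
    displacement (µm); drift is a constant per-frame displacement (µm).
    """

    step_std: float = 1.0
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.step_std < 0:
            raise GeometryError(f"step_std must be >= 0, got {self.step_std}")


@dataclass
class TrajectorySet:
    """Per-bead, per-frame centre positions with static size and index.

    positions: (T, n_beads, 3) array of (x, y, z) µm.
    volume_dims: (Lx, Ly, depth) µm of the declared sample volume.
    """

    positions: np.ndarray
    diameters: np.ndarray
    complex_indices: np.ndarray
    volume_dims: tuple[float, float, float]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.complex_indices = np.asarray(self.complex_indices, dtype=complex)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise GeometryError(
                f"positions must have shape (T, n, 3), got {self.positions.shape}"
            )
        n = self.positions.shape[1]
        if self.diameters.shape != (n,) or self.complex_indices.shape != (n,):
            raise GeometryError("diameters/complex_indices must be per-bead vectors")
        dims = np.asarray(self.volume_dims, dtype=float)
        if np.any(self.positions < -1e-9) or np.any(self.positions > dims + 1e-9):
            raise GeometryError("trajectory positions leave the declared sample volume")
        for t in range(self.n_frames):
            bad = check_no_overlap(self.positions[t], self.diameters)
            if bad.size:
                raise GeometryError(
                    f"beads {bad.tolist()} overlap in frame {t}"
                )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def beads_at(self, frame: int) -> list[Bead]:
        """Materialize the scene of one frame as a list of beads."""
        return [
            Bead(
                center=tuple(self.positions[frame, i]),
                diameter=float(self.diameters[i]),
                complex_index=complex(self.complex_indices[i]),
            )
            for i in range(self.n_beads)
        ]


def generate_random_trajectories(
    n_beads: int,
    volume_dims: tuple[float, float, float],
    motion: MotionParams,
    n_frames: int,
    seed: int,
    diameter: float = 5.0,
    complex_index: complex = 1.59 + 0.0j,
    max_attempts: int = 100_000,
) -> TrajectorySet:
    """Draw a random bead swarm and evolve it as a reflected random walk.

    Initial centres are uniform in the volume, rejection-sampled so that no
    two bead surfaces intersect; each subsequent frame adds a Gaussian step
    (per-axis std ``motion.step_std``) plus ``motion.drift``, reflecting at
    the volume faces.  Steps that would create an overlap are re-drawn for
    the offending beads only.  Fully reproducible from ``seed``.
    """
    if n_beads < 1:
        raise GeometryError(f"n_beads must be >= 1, got {n_beads}")
    dims = np.asarray(volume_dims, dtype=float)
    if np.any(dims <= 0):
        raise GeometryError(f"volume dimensions must be > 0, got {volume_dims}")
    bead_volume = n_beads * (np.pi / 6.0) * diameter**3
    if bead_volume >= 0.2 * float(np.prod(dims)):
        raise ConcentrationInfeasibleError(
            f"total bead volume {bead_volume:.3g} µm³ exceeds 20% of the sample volume"
        )
    rng = np.random.default_rng(seed)
    diameters = np.full(n_beads, float(diameter))
    indices = np.full(n_beads, complex(complex_index))

    pos = rng.uniform(0.0, dims, size=(n_beads, 3))
    attempts = 0
    while True:
        bad = check_no_overlap(pos, diameters)
        if not bad.size:
            break
        attempts += bad.size
        if attempts > max_attempts:
            raise ConcentrationInfeasibleError(
                f"could not place {n_beads} beads without overlap "
                f"after {max_attempts} attempts"
            )
        pos[bad] = rng.uniform(0.0, dims, size=(bad.size, 3))

    frames = np.empty((n_frames, n_beads, 3))
    frames[0] = pos
    drift = np.asarray(motion.drift, dtype=float)
    for t in range(1, n_frames):
        prev = frames[t - 1]
        step = rng.normal(0.0, motion.step_std, size=(n_beads, 3)) + drift
        new = _reflect(prev + step, dims)
        attempts = 0
        while True:
            bad = check_no_overlap(new, diameters)
            if not bad.size:
                break
            attempts += bad.size
            if attempts > max_attempts:
                raise ConcentrationInfeasibleError(
                    f"random walk stuck at frame {t}: cannot resolve overlaps"
                )
            redraw = rng.normal(0.0, motion.step_std, size=(bad.size, 3)) + drift
            new[bad] = _reflect(prev[bad] + redraw, dims)
        frames[t] = new
    return TrajectorySet(
        positions=frames,
        diameters=diameters,
        complex_indices=indices,
        volume_dims=tuple(dims),
    )


def _reflect(pos: np.ndarray, dims: np.ndarray) -> np.ndarray:
    """Reflect positions into [0, dims] (handles multiple bounces)."""
    period = 2.0 * dims
    p = np.mod(pos, period)
    return np.where(p > dims, period - p, p)
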