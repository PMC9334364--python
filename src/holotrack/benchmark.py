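"""Closed-loop accuracy benchmark: simulate → detect → match → RMS.

Reproduces the standard protocol for grading holographic particle
trackers: spherical beads of fixed diameter at a fixed concentration, a
grid of hologram SNR values × bead counts, pooled RMS XY / RMS Z per cell.
All cells share one sample volume (lateral extent = full field of view,
depth set so the reference bead count reaches the nominal concentration),
so crowding — and with it the difficulty — grows with the bead count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import OpticalConfig, SimulationConfig
from .detect import TrackerParams, default_plane_set, detect_frame
from .link import detections_to_frame, match_to_truth, rms_errors
from .scene import MotionParams, generate_random_trajectories
from .simulate import simulate_sequence, volume_for_concentration

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkProtocol:
    """One accuracy-benchmark campaign.

    Defaults mirror the reference conditions: 5 µm polystyrene-like beads
    in one fixed sample volume chosen so that the ``reference_count``-bead
    case sits at ``concentration_per_mm3`` (10 beads at 2270 beads/mm³ →
    ≈ 4.4·10⁻³ mm³; concentration then scales with the bead count), SNR ∈
    {∞, 20, 10, 5} × bead counts {10, 25, 50, 100}, 121 reconstruction
    planes spanning the sample depth.  ``frames`` and ``replicates`` set
    the statistics per cell; the matching gate defaults to twice the bead
    diameter.
    """

    snr_values: tuple[float, ...] = (float("inf"), 20.0, 10.0, 5.0)
    bead_counts: tuple[int, ...] = (10, 25, 50, 100)
    diameter: float = 5.0
    concentration_per_mm3: float = 2270.0
    reference_count: int = 10
    bead_index: complex = 1.59 + 0.0j
    frames: int = 20
    replicates: int = 1
    seed: int = 0
    optical: OpticalConfig = field(default_factory=OpticalConfig)
    z2: float = 150.0
    motion: MotionParams = field(default_factory=MotionParams)
    n_planes: int = 121
    tracker: TrackerParams | None = None
    match_gate: float | None = None  # default: 2 × diameter
    sample_depth: float | None = None  # explicit depth override, µm

    @property
    def sample_volume(self) -> tuple[float, float, float]:
        """The fixed (Lx, Ly, depth) sample volume shared by all cells, µm."""
        if self.sample_depth is not None:
            fov_x, fov_y = self.optical.field_of_view
            return (fov_x, fov_y, self.sample_depth)
        return volume_for_concentration(
            self.reference_count, self.concentration_per_mm3, self.optical
        )


def run_cell(
    protocol: BenchmarkProtocol, snr: float, n_beads: int, seed: int
) -> dict:
    """Simulate and evaluate one (snr, bead count) cell with one replicate seed."""
    volume = protocol.sample_volume
    traj = generate_random_trajectories(
        n_beads,
        volume,
        protocol.motion,
        protocol.frames,
        seed=seed,
        diameter=protocol.diameter,
        complex_index=protocol.bead_index,
    )
    sim = SimulationConfig(
        optical=protocol.optical,
        z2=protocol.z2,
        sample_depth=volume[2],
        snr=snr,
        seed=seed,
    )
    holograms, truth = simulate_sequence(traj, sim)
    plane_z = default_plane_set(protocol.z2, volume[2], protocol.n_planes)
    tracker = protocol.tracker or TrackerParams()
    tracker = replace(tracker, plane_z=plane_z)
    detections = []
    for frame in holograms:
        detections.extend(detect_frame(frame, tracker, protocol.optical).detections)
    det_df = detections_to_frame(detections)
    gate = protocol.match_gate or 2.0 * protocol.diameter
    matches = match_to_truth(det_df, truth, gate=gate)
    report = rms_errors(matches)
    return {
        "snr": snr,
        "n_beads": n_beads,
        "rms_xy_um": report.rms_xy,
        "rms_z_um": report.rms_z,
        "n_matched": report.n_matched,
        "n_missed": report.n_missed,
        "n_spurious": report.n_spurious,
        "detection_rate": report.n_matched / len(truth),
        "sample_depth_um": volume[2],
    }


def run_benchmark(protocol: BenchmarkProtocol) -> pd.DataFrame:
    """Run the full SNR × bead-count grid; pooled metrics per cell.

    Replicates re-run each cell with derived seeds and pool their matched
    pairs (RMS over the union) by quadratic averaging weighted by match
    counts.  Bit-reproducible from (protocol, seed).
    """
    rows = []
    for snr in protocol.snr_values:
        for n_beads in protocol.bead_counts:
            cells = []
            for r in range(protocol.replicates):
                cell_seed = (
                    protocol.seed * 100_003 + r * 1009 + n_beads * 13 + int(1e6 if np.isinf(snr) else snr)
                ) % (2**31 - 1)
                cells.append(run_cell(protocol, snr, n_beads, cell_seed))
            pooled = _pool_cells(cells)
            logger.info(
                "snr=%s beads=%d: RMS XY %.2f µm, RMS Z %.2f µm (%d matched)",
                snr, n_beads, pooled["rms_xy_um"], pooled["rms_z_um"], pooled["n_matched"],
            )
            rows.append(pooled)
    return pd.DataFrame(rows)


def _pool_cells(cells: list[dict]) -> dict:
    """Pool replicate cells: RMS combined in quadrature over matched pairs."""
    if len(cells) == 1:
        return cells[0]
    n = np.array([c["n_matched"] for c in cells], dtype=float)
    total = n.sum()
    out = dict(cells[0])
    for key in ("rms_xy_um", "rms_z_um"):
        out[key] = float(np.sqrt(np.sum(n * np.array([c[key] for c in cells]) ** 2) / total))
    for key in ("n_matched", "n_missed", "n_spurious"):
        out[key] = int(sum(c[key] for c in cells))
    out["detection_rate"] = float(np.mean([c["detection_rate"] for c in cells]))
    return out


def pivot_table(results: pd.DataFrame) -> pd.DataFrame:
    """Reshape benchmark results into the SNR × bead-count layout."""
    wide = results.pivot(index="snr", columns="n_beads", values=["rms_xy_um", "rms_z_um"])
    return wide.sort_index(ascending=False)
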