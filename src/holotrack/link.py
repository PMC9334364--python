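"""Temporal linking of detections into tracks, and evaluation against truth.

Linking is frame-to-frame optimal assignment (Hungarian algorithm) under a
distance gate.  Each active track predicts its next position with a
constant-velocity model (last position + last displacement) once it holds
at least two points; younger tracks predict their last position.  The cost
of a (track, detection) pair is the 3D Euclidean distance from the
prediction; pairs beyond ``gate_radius`` are forbidden.  Unmatched
detections open new tracks; tracks unmatched for more than ``max_gap``
frames terminate.

Evaluation matches detections to ground truth per frame (again by optimal
assignment under a gate) and pools matched pairs into RMS errors:
``rms_xy = RMS(sqrt((x − x_ideal)² + (y − y_ideal)²))`` and the analogous
``rms_z``.  Missed and spurious detections are counted separately and do
not enter the RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Detection
from .errors import DegenerateInputError

_UNREACHABLE = 1e12  # sentinel cost for gated-out pairs


@dataclass
class LinkParams:
    """gate_radius (µm) bounds the per-frame displacement; max_gap is the
    number of consecutive frames a track may go unmatched before it
    terminates; mode "velocity" predicts with constant velocity, "nearest"
    predicts the last position only."""

    gate_radius: float = 15.0
    max_gap: int = 1
    mode: str = "velocity"


@dataclass
class Track:
    """One particle identity across frames."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    detections: list[Detection] = field(default_factory=list)
    state: str = "active"
    _missed: int = 0

    def positions(self) -> np.ndarray:
        return np.array([[d.x, d.y, d.z] for d in self.detections])

    def predict(self, mode: str) -> np.ndarray:
        p = self.positions()
        if mode == "velocity" and len(p) >= 2:
            return p[-1] + (p[-1] - p[-2])
        return p[-1]

    def add(self, frame: int, det: Detection) -> None:
        self.frames.append(frame)
        self.detections.append(det)
        self._missed = 0


def link_tracks(
    frames: list[list[Detection]], params: LinkParams | None = None
) -> list[Track]:
    """Link per-frame detections into tracks.

    ``frames`` is ordered by frame index; empty frames are allowed.  The
    result is permutation-invariant to the order of detections within a
    frame (ties broken by the optimal assignment itself).
    """
    params = params or LinkParams()
    tracks: list[Track] = []
    active: list[Track] = []
    for t, dets in enumerate(frames):
        assigned_dets: set[int] = set()
        matched_tracks: set[int] = set()
        if active and dets:
            preds = np.array([tr.predict(params.mode) for tr in active])
            pts = np.array([[d.x, d.y, d.z] for d in dets])
            cost = np.sqrt(((preds[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            gated = cost.copy()
            gated[cost > params.gate_radius] = _UNREACHABLE
            rows, cols = linear_sum_assignment(gated)
            for r, c in zip(rows, cols):
                if gated[r, c] < _UNREACHABLE:
                    active[r].add(t, dets[c])
                    matched_tracks.add(r)
                    assigned_dets.add(c)
        still_active: list[Track] = []
        for i, tr in enumerate(active):
            if i in matched_tracks:
                still_active.append(tr)
            else:
                tr._missed += 1
                if tr._missed > params.max_gap:
                    tr.state = "terminated"
                else:
                    still_active.append(tr)
        for c, det in enumerate(dets):
            if c not in assigned_dets:
                tr = Track(track_id=len(tracks))
                tr.add(t, det)
                tracks.append(tr)
                still_active.append(tr)
        active = still_active
    return tracks


@dataclass
class EvaluationReport:
    """Pooled localization accuracy of a detection set against ground truth."""

    rms_xy: float
    rms_z: float
    n_matched: int
    n_missed: int
    n_spurious: int
    matches: pd.DataFrame

    def summary(self) -> str:
        return (
            f"matched {self.n_matched}, missed {self.n_missed}, "
            f"spurious {self.n_spurious}; RMS XY = {self.rms_xy:.3f} µm, "
            f"RMS Z = {self.rms_z:.3f} µm"
        )


def match_to_truth(
    detections: pd.DataFrame, truth: pd.DataFrame, gate: float = 10.0
) -> pd.DataFrame:
    """Per-frame optimal assignment of detections to ground-truth positions.

    Both tables need columns ``frame, x_um, y_um, z_um``.  Pairs farther
    than ``gate`` (µm, 3D Euclidean) stay unmatched.  Returns one row per
    matched pair with the per-axis errors, plus the unmatched counts in
    ``DataFrame.attrs``.
    """
    rows = []
    n_missed = 0
    n_spurious = 0
    all_frames = sorted(
        set(truth["frame"].unique()) | set(detections["frame"].unique())
    )
    for t in all_frames:
        tru = truth[truth["frame"] == t].reset_index(drop=True)
        det = detections[detections["frame"] == t].reset_index(drop=True)
        if len(tru) == 0 or len(det) == 0:
            n_missed += len(tru)
            n_spurious += len(det)
            continue
        tp = tru[["x_um", "y_um", "z_um"]].to_numpy()
        dp = det[["x_um", "y_um", "z_um"]].to_numpy()
        cost = np.sqrt(((tp[:, None, :] - dp[None, :, :]) ** 2).sum(-1))
        gated = cost.copy()
        gated[cost > gate] = _UNREACHABLE
        ri, ci = linear_sum_assignment(gated)
        matched_t: set[int] = set()
        matched_d: set[int] = set()
        for r, c in zip(ri, ci):
            if gated[r, c] < _UNREACHABLE:
                matched_t.add(r)
                matched_d.add(c)
                rows.append(
                    {
                        "frame": t,
                        "bead_id": tru.loc[r, "bead_id"] if "bead_id" in tru else r,
                        "dx": dp[c, 0] - tp[r, 0],
                        "dy": dp[c, 1] - tp[r, 1],
                        "dz": dp[c, 2] - tp[r, 2],
                        "distance": cost[r, c],
                    }
                )
        n_missed += len(tru) - len(matched_t)
        n_spurious += len(det) - len(matched_d)
    matches = pd.DataFrame(rows, columns=["frame", "bead_id", "dx", "dy", "dz", "distance"])
    matches.attrs["n_missed"] = n_missed
    matches.attrs["n_spurious"] = n_spurious
    return matches


def rms_errors(matches: pd.DataFrame) -> EvaluationReport:
    """Pool matched pairs into RMS XY and RMS Z localization errors."""
    if len(matches) == 0:
        raise DegenerateInputError("no matched pairs; RMS is undefined")
    dx = matches["dx"].to_numpy()
    dy = matches["dy"].to_numpy()
    dz = matches["dz"].to_numpy()
    rms_xy = float(np.sqrt(np.mean(dx**2 + dy**2)))
    rms_z = float(np.sqrt(np.mean(dz**2)))
    return EvaluationReport(
        rms_xy=rms_xy,
        rms_z=rms_z,
        n_matched=len(matches),
        n_missed=int(matches.attrs.get("n_missed", 0)),
        n_spurious=int(matches.attrs.get("n_spurious", 0)),
        matches=matches,
    )


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Tabulate a flat list of detections (µm columns, one row each)."""
    return pd.DataFrame(
        [
            {
                "frame": d.frame_index,
                "object_id": d.object_id,
                "x_um": d.x,
                "y_um": d.y,
                "z_um": d.z,
                "area_px": d.mask_area,
            }
            for d in detections
        ],
        columns=["frame", "object_id", "x_um", "y_um", "z_um", "area_px"],
    )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tabulate linked tracks as ``track_id, frame, x_um, y_um, z_um``."""
    rows = []
    for tr in tracks:
        for f, d in zip(tr.frames, tr.detections):
            rows.append(
                {"track_id": tr.track_id, "frame": f, "x_um": d.x, "y_um": d.y, "z_um": d.z}
            )
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "z_um"])
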