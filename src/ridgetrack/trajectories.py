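"""Trajectory assembly, classification and biomechanics metrics.

A trajectory is the frame-ordered record of one cell identity.  A
trajectory is *correct* when it both starts and ends at the boundary of
the field of view — cells flow in and out through the edges — whereas a
trajectory that starts or ends mid-field indicates a tracking failure or
debris.  Given the pixel layout of the channel's diagonal ridges, each
trajectory yields the cell's average speed on ridges and in the gaps
between them (stiff cells slow on ridges; softened cells do not), a
per-ridge speed profile normalized by the first traversed ridge, and the
net drift along y.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .linking import TrackState

__all__ = [
    "Trajectory",
    "RidgeLayout",
    "SpeedProfile",
    "assemble_trajectories",
    "classify_trajectory",
    "compute_speeds",
    "y_drift",
    "load_ridge_layout",
    "write_trajectory_tables",
]


@dataclass
class TrajectoryRecord:
    frame: int
    x: float
    y: float
    pixel_count: int
    radius: float


@dataclass
class Trajectory:
    """Per-frame record of one cell identity."""

    cell_id: int
    records: List[TrajectoryRecord]
    classification: Optional[str] = None  # "correct" | "incorrect"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a trajectory needs at least one record")
        frames = [r.frame for r in self.records]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("record frames must be strictly increasing")

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class RidgeLayout:
    """Ridge stripes as half-open pixel intervals [x_start, x_end) along
    the flow axis; everything outside is gap."""

    ridge_intervals: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted((float(a), float(b)) for a, b in self.ridge_intervals)
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("ridge intervals must be disjoint")
        if any(b <= a for a, b in iv):
            raise ValueError("ridge intervals must be non-empty")
        self.ridge_intervals = iv

    def ridge_index(self, x: float) -> Optional[int]:
        """Ordinal of the ridge containing x, or None in a gap."""
        for k, (a, b) in enumerate(self.ridge_intervals):
            if a <= x < b:
                return k
        return None


@dataclass
class SpeedProfile:
    """Ridge/gap speed summary of one trajectory.

    Speeds are in pixels/frame unless the recording is calibrated
    (frame_rate and pixel_size known), in which case physical units per
    second are used.  A category with no steps is reported as None, not
    zero.
    """

    speed_on_ridge: Optional[float]
    speed_in_gap: Optional[float]
    per_ridge_speed: List[float]
    normalized_per_ridge: List[float]
    n_ridges: int
    units: str = "px/frame"


def assemble_trajectories(state: TrackState) -> List[Trajectory]:
    """One trajectory per distinct cell ID, records in frame order.

    Raises on a duplicated (cell_id, frame) pair, which would mean the
    linking passes left an inconsistent state.
    """
    by_cell: dict = {}
    for f, frame_events in enumerate(state.events_by_frame):
        for ev in frame_events:
            if ev.cell_id is None:
                raise ValueError(f"unassigned event in frame {f}")
            recs = by_cell.setdefault(ev.cell_id, [])
            if recs and recs[-1].frame == f:
                raise ValueError(
                    f"cell {ev.cell_id} has two events in frame {f}"
                )
            recs.append(
                TrajectoryRecord(
                    frame=f, x=ev.x, y=ev.y,
                    pixel_count=ev.pixel_count, radius=ev.radius,
                )
            )
    return [
        Trajectory(cell_id=cid, records=recs) for cid, recs in sorted(by_cell.items())
    ]


def classify_trajectory(
    traj: Trajectory, frame_shape: Tuple[int, int], margin: float = 10.0
) -> str:
    """"correct" iff the trajectory both starts and ends within ``margin``
    pixels of some image edge; otherwise "incorrect"."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    h, w = frame_shape

    def near_edge(rec: TrajectoryRecord) -> bool:
        return (
            rec.x <= margin
            or rec.x >= w - 1 - margin
            or rec.y <= margin
            or rec.y >= h - 1 - margin
        )

    ok = near_edge(traj.records[0]) and near_edge(traj.records[-1])
    traj.classification = "correct" if ok else "incorrect"
    return traj.classification


def _steps(traj: Trajectory) -> List[Tuple[float, float, float]]:
    """Per-step (midpoint_x, speed, frame_gap) between consecutive records."""
    out = []
    for a, b in zip(traj.records, traj.records[1:]):
        gap = b.frame - a.frame
        disp = math.hypot(b.x - a.x, b.y - a.y)
        out.append(((a.x + b.x) / 2.0, disp / gap, gap))
    return out


def compute_speeds(
    traj: Trajectory,
    layout: RidgeLayout,
    frame_rate: Optional[float] = None,
    pixel_size: Optional[float] = None,
    speed_mode: str = "magnitude",
) -> SpeedProfile:
    """Ridge/gap and per-ridge average speeds of one trajectory.

    The per-step speed is the center displacement between consecutive
    records divided by the frame gap (displacement magnitude by default;
    ``speed_mode="x"`` uses the flow component only).  A step belongs to
    a ridge iff its midpoint x lies in that ridge interval.  Per-ridge
    speeds are reported in traversal order and normalized by the first
    traversed ridge.
    """
    if traj.n_records < 2:
        raise ValueError("speed metrics need at least 2 records")
    if speed_mode not in ("magnitude", "x"):
        raise ValueError("speed_mode must be 'magnitude' or 'x'")

    scale = 1.0
    units = "px/frame"
    if frame_rate is not None and pixel_size is not None:
        scale = frame_rate * pixel_size
        units = "length/s"
    elif frame_rate is not None:
        scale = frame_rate
        units = "px/s"

    ridge_speeds: List[float] = []
    gap_speeds: List[float] = []
    per_ridge: dict = {}
    order: List[int] = []
    for a, b in zip(traj.records, traj.records[1:]):
        gap_frames = b.frame - a.frame
        if speed_mode == "magnitude":
            disp = math.hypot(b.x - a.x, b.y - a.y)
        else:
            disp = abs(b.x - a.x)
        v = disp / gap_frames * scale
        mid_x = (a.x + b.x) / 2.0
        k = layout.ridge_index(mid_x)
        if k is None:
            gap_speeds.append(v)
        else:
            ridge_speeds.append(v)
            if k not in per_ridge:
                order.append(k)
            per_ridge.setdefault(k, []).append(v)

    per_ridge_speed = [float(np.mean(per_ridge[k])) for k in order]
    if per_ridge_speed and per_ridge_speed[0] > 0:
        normalized = [v / per_ridge_speed[0] for v in per_ridge_speed]
    else:
        normalized = []
    return SpeedProfile(
        speed_on_ridge=float(np.mean(ridge_speeds)) if ridge_speeds else None,
        speed_in_gap=float(np.mean(gap_speeds)) if gap_speeds else None,
        per_ridge_speed=per_ridge_speed,
        normalized_per_ridge=normalized,
        n_ridges=len(order),
        units=units,
    )


def y_drift(traj: Trajectory, up_positive: bool = True) -> float:
    """Net drift along y over the trajectory, in pixels.

    Image rows grow downward; with ``up_positive`` (the default) the sign
    is flipped so that physical upward drift is positive.
    """
    if traj.n_records < 2:
        raise ValueError("y drift needs at least 2 records")
    d = traj.records[-1].y - traj.records[0].y
    return -d if up_positive else d


def load_ridge_layout(path: str | os.PathLike) -> RidgeLayout:
    """Read a ridge layout from YAML (key ``ridge_intervals``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RidgeLayout(ridge_intervals=[tuple(iv) for iv in data["ridge_intervals"]])


def write_trajectory_tables(
    trajectories: Sequence[Trajectory],
    outdir: str | os.PathLike,
    layout: Optional[RidgeLayout] = None,
    frame_rate: Optional[float] = None,
    pixel_size: Optional[float] = None,
) -> dict:
    """Write trajectories.csv, metrics.csv and per_ridge.csv under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    traj_rows, metric_rows, ridge_rows = [], [], []
    for traj in trajectories:
        for r in traj.records:
            traj_rows.append(
                {
                    "cell_id": traj.cell_id,
                    "frame": r.frame,
                    "x": r.x,
                    "y": r.y,
                    "pixels": r.pixel_count,
                    "radius": r.radius,
                    "classification": traj.classification,
                }
            )
        row = {
            "cell_id": traj.cell_id,
            "classification": traj.classification,
            "y_drift": y_drift(traj) if traj.n_records >= 2 else np.nan,
            "speed_on_ridge": np.nan,
            "speed_in_gap": np.nan,
            "n_ridges": 0,
        }
        if layout is not None and traj.n_records >= 2:
            prof = compute_speeds(traj, layout, frame_rate, pixel_size)
            row["speed_on_ridge"] = (
                np.nan if prof.speed_on_ridge is None else prof.speed_on_ridge
            )
            row["speed_in_gap"] = (
                np.nan if prof.speed_in_gap is None else prof.speed_in_gap
            )
            row["n_ridges"] = prof.n_ridges
            for k, (v, nv) in enumerate(
                zip(prof.per_ridge_speed, prof.normalized_per_ridge)
            ):
                ridge_rows.append(
                    {
                        "cell_id": traj.cell_id,
                        "ridge_index": k,
                        "mean_speed": v,
                        "normalized_speed": nv,
                    }
                )
        metric_rows.append(row)

    paths = {
        "trajectories": outdir / "trajectories.csv",
        "metrics": outdir / "metrics.csv",
        "per_ridge": outdir / "per_ridge.csv",
    }
    pd.DataFrame(
        traj_rows,
        columns=["cell_id", "frame", "x", "y", "pixels", "radius", "classification"],
    ).to_csv(paths["trajectories"], index=False, float_format="%.9g")
    pd.DataFrame(
        metric_rows,
        columns=[
            "cell_id", "classification", "y_drift",
            "speed_on_ridge", "speed_in_gap", "n_ridges",
        ],
    ).to_csv(paths["metrics"], index=False, float_format="%.9g")
    pd.DataFrame(
        ridge_rows,
        columns=["cell_id", "ridge_index", "mean_speed", "normalized_speed"],
    ).to_csv(paths["per_ridge"], index=False, float_format="%.9g")
    return paths
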