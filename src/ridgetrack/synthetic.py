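"""Seeded synthetic recordings with ground truth, and scripted scenarios.

The generator emulates the phenomenology of high-speed brightfield
recordings of cells transiting a ridged microfluidic channel: a
near-constant background with slow illumination drift and static ridge
stripes, cells as compact bright blobs tens of pixels in area moving
predominantly along +x at a speed that may differ on ridges and in gaps,
collisions in which two blobs form a single connected component for
several frames — the doublet may rotate so the follower exits as the
leader — transient low-contrast dropouts, and sub-4-pixel fast debris.
Kinematics are scripted, not simulated from hydrodynamics.

Colliding cells occlude rather than add intensity (the rendered blob is
the union of the disks, matching the appearance of touching cells).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .foreground import Event
from .io import FrameStack
from .trajectories import RidgeLayout, Trajectory

__all__ = [
    "CellSpec",
    "CollisionScript",
    "DropoutScript",
    "DebrisSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_video",
    "write_truth_table",
    "three_cell_merge_split_scenario",
    "dense_adjacency_example",
    "gated_adjacency_example",
    "collision_swap_config",
    "ridge_cohort_config",
    "evaluate_tracking",
]


@dataclass
class CellSpec:
    """Scripted kinematics of one synthetic cell.

    ``y_drift`` is in pixels per frame with physical "up" positive (the
    image row decreases).  ``ridge_speed`` defaults to ``gap_speed``.
    """

    entry_frame: int = 0
    entry_x: float = 3.0
    entry_y: float = 40.0
    radius: float = 4.0
    intensity_offset: float = 60.0
    gap_speed: float = 3.0
    ridge_speed: Optional[float] = None
    y_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 2:
            raise ValueError("cell radii must be >= 2 px")
        if self.gap_speed < 0 or (self.ridge_speed is not None and self.ridge_speed < 0):
            raise ValueError("speeds must be >= 0")
        if self.ridge_speed is None:
            self.ridge_speed = self.gap_speed


@dataclass
class CollisionScript:
    """Two cells form one touching doublet over [start, end] (inclusive);
    with ``swap`` the doublet rotates by ~pi so the follower becomes the
    leader on detachment."""

    a: int  # index of the chasing cell (behind at contact)
    b: int  # index of the leading cell
    start: int
    end: int
    swap: bool = True


@dataclass
class DropoutScript:
    """Cell invisible (zero contrast) over frames [start, end]."""

    cell: int
    start: int
    end: int


@dataclass
class DebrisSpec:
    """A fast low-contrast speck of fewer than 4 pixels."""

    entry_frame: int
    entry_y: float
    entry_x: float = 2.0
    n_pixels: int = 2
    speed: float = 9.0
    intensity_offset: float = 25.0


@dataclass
class SimConfig:
    frame_shape: Tuple[int, int] = (80, 160)
    n_frames: int = 100
    background_level: float = 100.0
    drift_amplitude: float = 2.0
    ridge_layout: Optional[RidgeLayout] = None
    ridge_contrast: float = 6.0
    noise_sd: float = 2.0
    cells: List[CellSpec] = field(default_factory=list)
    collisions: List[CollisionScript] = field(default_factory=list)
    dropouts: List[DropoutScript] = field(default_factory=list)
    debris: List[DebrisSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-frame, per-cell centers, visibility and pixel masks."""

    centers: Dict[int, Dict[int, Tuple[float, float]]]
    visible: Dict[int, Dict[int, bool]]
    masks: Dict[Tuple[int, int], np.ndarray]  # (frame, cell) -> (n, 2) row/col
    radii: Dict[int, float]

    def cells_in_frame(self, frame: int) -> List[int]:
        return [
            c
            for c, per_frame in self.centers.items()
            if frame in per_frame and self.visible[c].get(frame, False)
        ]


_SUBSTEPS = 10


def _speed_at(x: float, spec: CellSpec, layout: Optional[RidgeLayout]) -> float:
    if layout is not None and layout.ridge_index(x) is not None:
        return float(spec.ridge_speed)
    return float(spec.gap_speed)


def _integrate_positions(cfg: SimConfig) -> Dict[int, Dict[int, Tuple[float, float]]]:
    """Scripted centers per cell per frame (collision overrides applied)."""
    h, w = cfg.frame_shape
    pos: Dict[int, Dict[int, Tuple[float, float]]] = {k: {} for k in range(len(cfg.cells))}
    cur: Dict[int, Optional[Tuple[float, float]]] = {k: None for k in range(len(cfg.cells))}
    anchors: Dict[int, Tuple[np.ndarray, np.ndarray, float]] = {}

    for f in range(cfg.n_frames):
        for k, spec in enumerate(cfg.cells):
            if f == spec.entry_frame:
                cur[k] = (spec.entry_x, spec.entry_y)
        for k, spec in enumerate(cfg.cells):
            if cur[k] is not None:
                x, y = cur[k]
                if x - spec.radius > w + 1:  # fully exited
                    cur[k] = None
                else:
                    pos[k][f] = (x, y)

        # step every active cell to frame f+1
        nxt: Dict[int, Optional[Tuple[float, float]]] = dict(cur)
        for k, spec in enumerate(cfg.cells):
            if cur[k] is None:
                continue
            x, y = cur[k]
            for _ in range(_SUBSTEPS):
                x += _speed_at(x, spec, cfg.ridge_layout) / _SUBSTEPS
                y -= spec.y_drift / _SUBSTEPS
            nxt[k] = (x, y)

        for ci, col in enumerate(cfg.collisions):
            g = f + 1
            if not (col.start <= g <= col.end):
                continue
            if cur[col.a] is None or cur[col.b] is None:
                continue
            if ci not in anchors:
                pa = np.array(cur[col.a], dtype=float)
                pb = np.array(cur[col.b], dtype=float)
                c0 = (pa + pb) / 2.0
                u = pb - pa
                nu = np.linalg.norm(u)
                u = u / nu if nu > 0 else np.array([1.0, 0.0])
                va = _speed_at(pa[0], cfg.cells[col.a], cfg.ridge_layout)
                vb = _speed_at(pb[0], cfg.cells[col.b], cfg.ridge_layout)
                anchors[ci] = (c0, u, (va + vb) / 2.0)
            c0, u, vj = anchors[ci]
            span = col.end - col.start + 1
            k_rel = g - col.start
            phi = (math.pi * k_rel / span) if col.swap else 0.0
            d = cfg.cells[col.a].radius + cfg.cells[col.b].radius - 1.0
            rot = np.array(
                [[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]]
            )
            off = rot @ (0.5 * d * u)
            c_now = c0 + np.array([vj * (k_rel + 1), 0.0])
            nxt[col.a] = tuple(c_now - off)
            nxt[col.b] = tuple(c_now + off)
        cur = nxt
    return pos


def _disk_coverage(shape: Tuple[int, int], cx: float, cy: float, r: float):
    """Anti-aliased disk: per-pixel coverage in [0, 1] on a local window."""
    h, w = shape
    r0 = max(0, int(math.floor(cy - r - 1)))
    r1 = min(h, int(math.ceil(cy + r + 2)))
    c0 = max(0, int(math.floor(cx - r - 1)))
    c1 = min(w, int(math.ceil(cx + r + 2)))
    if r0 >= r1 or c0 >= c1:
        return None
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(cols - cx, rows - cy)
    cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
    return (slice(r0, r1), slice(c0, c1)), cov


def simulate_video(cfg: SimConfig) -> Tuple[FrameStack, GroundTruth]:
    """Render the scripted scene into a frame stack with ground truth.

    Deterministic for a fixed config and seed (byte-identical output).
    """
    h, w = cfg.frame_shape
    for spec in cfg.cells:
        if not (0 <= spec.entry_y < h):
            raise ValueError("cells must be initialized inside the frame")
    rng = np.random.default_rng(cfg.seed)
    pos = _integrate_positions(cfg)

    base = np.full((h, w), cfg.background_level, dtype=np.float64)
    if cfg.ridge_layout is not None:
        cols = np.arange(w, dtype=float)
        stripe = np.zeros(w)
        for a, b in cfg.ridge_layout.ridge_intervals:
            stripe[(cols >= a) & (cols < b)] = cfg.ridge_contrast
        base = base + stripe[None, :]

    dropout_frames = {
        (d.cell, f) for d in cfg.dropouts for f in range(d.start, d.end + 1)
    }

    frames = np.empty((cfg.n_frames, h, w), dtype=np.float64)
    centers: Dict[int, Dict[int, Tuple[float, float]]] = {k: {} for k in pos}
    visible: Dict[int, Dict[int, bool]] = {k: {} for k in pos}
    masks: Dict[Tuple[int, int], np.ndarray] = {}

    for f in range(cfg.n_frames):
        img = base + cfg.drift_amplitude * math.sin(2 * math.pi * f / max(cfg.n_frames, 1))
        layer = np.zeros((h, w))
        for k, spec in enumerate(cfg.cells):
            if f not in pos[k]:
                continue
            cx, cy = pos[k][f]
            centers[k][f] = (cx, cy)
            if (k, f) in dropout_frames:
                visible[k][f] = False
                continue
            hit = _disk_coverage((h, w), cx, cy, spec.radius)
            if hit is None:
                visible[k][f] = False
                continue
            sl, cov = hit
            layer[sl] = np.maximum(layer[sl], spec.intensity_offset * cov)
            rr, cc = np.nonzero(cov >= 0.5)
            coords = np.column_stack([rr + sl[0].start, cc + sl[1].start])
            visible[k][f] = coords.shape[0] > 0
            if coords.shape[0]:
                masks[(f, k)] = coords
        for deb in cfg.debris:
            if f < deb.entry_frame:
                continue
            x = deb.entry_x + deb.speed * (f - deb.entry_frame)
            y = deb.entry_y
            if x > w + 2:
                continue
            offs = [(0, 0), (0, 1), (1, 0)][: max(1, min(deb.n_pixels, 3))]
            for dr, dc in offs:
                r_i, c_i = int(round(y)) + dr, int(round(x)) + dc
                if 0 <= r_i < h and 0 <= c_i < w:
                    layer[r_i, c_i] = max(layer[r_i, c_i], deb.intensity_offset)
        img = img + layer
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=(h, w))
        frames[f] = img

    truth = GroundTruth(
        centers=centers,
        visible=visible,
        masks=masks,
        radii={k: spec.radius for k, spec in enumerate(cfg.cells)},
    )
    return FrameStack(frames=frames), truth


def write_truth_table(truth: GroundTruth, path: str | os.PathLike) -> None:
    """Ground-truth trajectories as CSV (frame, cell, x, y, visible)."""
    rows = []
    for cell, per_frame in sorted(truth.centers.items()):
        for f, (x, y) in sorted(per_frame.items()):
            rows.append(
                {
                    "frame": f,
                    "cell": cell,
                    "x": x,
                    "y": y,
                    "visible": int(truth.visible[cell].get(f, False)),
                }
            )
    pd.DataFrame(rows, columns=["frame", "cell", "x", "y", "visible"]).to_csv(
        Path(path), index=False, float_format="%.9g"
    )


# ---------------------------------------------------------------------------
# scripted worked examples
# ---------------------------------------------------------------------------


def _disk_coords(cx: int, cy: int, r: int) -> np.ndarray:
    rows, cols = np.mgrid[cy - r : cy + r + 1, cx - r : cx + r + 1]
    keep = (cols - cx) ** 2 + (rows - cy) ** 2 <= r * r
    return np.column_stack([rows[keep], cols[keep]])


def _event_from_coords(frame: int, event_id: int, coords: np.ndarray,
                       value: float = 100.0) -> Event:
    coords = np.unique(coords, axis=0)
    return Event.from_pixels(
        frame=frame,
        event_id=event_id,
        coords=coords,
        intensities=np.full(coords.shape[0], value),
    )


def three_cell_merge_split_scenario() -> Tuple[List[List[Event]], dict]:
    """Four segmented frames with event counts [2, 1, 2, 3].

    Three cells travel as a clump that the per-frame segmentation cannot
    resolve: frame 0 shows two barely separated components, frame 1 one
    aggregate, frame 2 the upper cell plus a doublet, and frame 3 all
    three cells apart.  Forward linking must merge the frame-0 pair (no
    separation evidence) and the backward pass must split the aggregates
    once the three identities are resolved late in the clip, leaving
    three cells present in every frame.  Truncated to the first three
    frames, only two identities (the upper cell and the unresolvable
    doublet) are recoverable.
    """
    # the upper cell is slightly larger (r=5) so aggregate orientation is
    # unambiguous for the template search, as for real unequal cells; the
    # total cell area (~178 px) is conserved across frames as it would be
    # in a real recording
    f0 = [
        _event_from_coords(0, 0, _disk_coords(8, 20, 5)),
        _event_from_coords(
            0, 1, np.concatenate([_disk_coords(14, 28, 4), _disk_coords(14, 36, 4)])
        ),
    ]
    blob = np.concatenate(
        [_disk_coords(16, 13, 5), _disk_coords(16, 22, 4), _disk_coords(16, 31, 4)]
    )
    f1 = [_event_from_coords(1, 0, blob)]
    doublet = np.concatenate([_disk_coords(22, 24, 4), _disk_coords(22, 32, 4)])
    f2 = [
        _event_from_coords(2, 0, _disk_coords(22, 8, 5)),
        _event_from_coords(2, 1, doublet),
    ]
    f3 = [
        _event_from_coords(3, 0, _disk_coords(28, 8, 5)),
        _event_from_coords(3, 1, _disk_coords(28, 24, 4)),
        _event_from_coords(3, 2, _disk_coords(28, 40, 4)),
    ]
    expected = {
        "event_counts": [2, 1, 2, 3],
        "n_cells": 3,
        "n_cells_truncated": 2,
        "frame_shape": (56, 64),
    }
    return [f0, f1, f2, f3], expected


def _blob53(cx: int, cy: int) -> np.ndarray:
    """A 53-pixel blob: a radius-4 disk plus four radius-5 spurs."""
    extra = np.array(
        [[cy, cx + 5], [cy, cx - 5], [cy + 5, cx], [cy - 5, cx]]
    )
    return np.concatenate([_disk_coords(cx, cy, 4), extra])


def dense_adjacency_example() -> Tuple[List[Event], List[Event]]:
    """Two identical 53-pixel events per frame, every next event nearby
    and downstream of every current event (a fully connected 2x2
    adjacency, admitting eleven matching sets).  The displacements of the
    corresponding pairs are 12 and 13 px; the crossed distances are
    larger, so the nearest one-to-one pairing should score highest.
    """
    current = [
        _event_from_coords(0, 0, _blob53(10, 10)),
        _event_from_coords(0, 1, _blob53(10, 26)),
    ]
    next_ = [
        _event_from_coords(1, 0, _blob53(22, 10)),
        _event_from_coords(1, 1, _blob53(23, 26)),
    ]
    return current, next_


def gated_adjacency_example() -> Tuple[List[Event], List[Event]]:
    """A partially gated adjacency admitting exactly four matching sets.

    One next-frame event sits upstream of every current event, so it can
    only appear; the other is downstream of all three current events but
    nearby only two of them, leaving two candidate sources for a single
    target (subsets: none, either single edge, or the two-to-one)."""
    current = [
        _event_from_coords(0, 0, _disk_coords(20, 8, 4)),
        _event_from_coords(0, 1, _disk_coords(20, 36, 4)),
        _event_from_coords(0, 2, _disk_coords(20, 48, 4)),
    ]
    next_ = [
        _event_from_coords(1, 0, _disk_coords(30, 42, 4)),
        _event_from_coords(1, 1, _disk_coords(8, 20, 4)),
    ]
    return current, next_


# ---------------------------------------------------------------------------
# canned simulation configs
# ---------------------------------------------------------------------------


def collision_swap_config(seed: int = 0) -> SimConfig:
    """Two cells collide mid-channel, the doublet rotates, and the
    follower exits as the leader.  Both cells enter and exit through the
    field-of-view edges.  The two cells differ in radius (4 vs 5 px, the
    natural size spread of a cell line), which makes the doublet's
    orientation identifiable for the template search."""
    leader = CellSpec(entry_frame=0, entry_x=3.0, entry_y=40.0, gap_speed=2.0, radius=4.0)
    chaser = CellSpec(entry_frame=12, entry_x=3.0, entry_y=40.0, gap_speed=4.0, radius=5.0)
    return SimConfig(
        frame_shape=(80, 160),
        n_frames=84,
        cells=[leader, chaser],
        collisions=[CollisionScript(a=1, b=0, start=20, end=33, swap=True)],
        noise_sd=2.0,
        seed=seed,
    )


def ridge_cohort_config(
    stiff: bool = True, seed: int = 0, n_cells: int = 3
) -> SimConfig:
    """A small cohort crossing three ridges.

    The stiff cohort slows on ridges (2 px/frame vs 4 in gaps) and
    drifts up; the softened cohort keeps a constant 4 px/frame and
    drifts slightly down — mirroring the stiffness contrast the device
    is designed to read out.
    """
    layout = RidgeLayout(ridge_intervals=[(30, 66), (94, 130), (158, 194)])
    ridge_speed = 2.0 if stiff else 4.0
    drift = 0.30 if stiff else -0.08
    ys = [30.0, 42.0, 54.0]
    cells = [
        CellSpec(
            entry_frame=6 * k,
            entry_x=3.0,
            entry_y=ys[k % len(ys)],
            gap_speed=4.0,
            ridge_speed=ridge_speed,
            y_drift=drift,
        )
        for k in range(n_cells)
    ]
    return SimConfig(
        frame_shape=(64, 240),
        n_frames=110,
        ridge_layout=layout,
        ridge_contrast=6.0,
        noise_sd=2.0,
        cells=cells,
        debris=[DebrisSpec(entry_frame=30, entry_y=20.0), DebrisSpec(entry_frame=60, entry_y=50.0)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------


def evaluate_tracking(
    tracked: Sequence[Trajectory],
    truth: GroundTruth,
    gate_factor: float = 3.0,
) -> dict:
    """Identity accuracy of tracked trajectories against ground truth.

    Each tracked event is matched to the true cell whose center is
    nearest in that frame, within a radius-scaled gate.  Per tracked ID
    the majority true cell defines the identity mapping; accuracy is the
    fraction of events consistent with that mapping.
    """
    n_total = 0
    per_id: Dict[int, List[Optional[int]]] = {}
    for traj in tracked:
        for rec in traj.records:
            n_total += 1
            best = None
            for cell in truth.cells_in_frame(rec.frame):
                cx, cy = truth.centers[cell][rec.frame]
                d = math.hypot(rec.x - cx, rec.y - cy)
                gate = max(gate_factor * truth.radii[cell], 6.0)
                if d <= gate and (best is None or d < best[0]):
                    best = (d, cell)
            per_id.setdefault(traj.cell_id, []).append(
                None if best is None else best[1]
            )

    n_consistent = 0
    report = {}
    for tid, matched in per_id.items():
        counts: Dict[int, int] = {}
        for cell in matched:
            if cell is not None:
                counts[cell] = counts.get(cell, 0) + 1
        majority = min(
            (c for c in counts if counts[c] == max(counts.values())), default=None
        )
        ok = sum(1 for cell in matched if cell is not None and cell == majority)
        n_consistent += ok
        report[tid] = {
            "majority_cell": majority,
            "n_events": len(matched),
            "n_consistent": ok,
        }
    accuracy = n_consistent / n_total if n_total else float("nan")
    return {"accuracy": accuracy, "n_events": n_total, "per_id": report}
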