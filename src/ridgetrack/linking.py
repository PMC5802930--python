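"""Forward and backward identity linking with merge/split handling.

The forward pass seeds unique cell IDs in the first frame and then, for
each consecutive frame pair, applies the best matching set.  A
multiple-to-one matching (cells colliding into an aggregate) first tries
to *merge* members that have never shown decent separation — an
agglomerative process thresholded by the radius of the aggregate — and,
if distinct identities remain, *splits* the aggregate using the members'
own shapes as a template (inter-centroid distances shrunk by a scalar
s <= 1 and rotated by an angle theta), propagating each identity into the
aggregate.  A one-to-multiple matching (an aggregate detaching) merges
targets that stay closer than the aggregate radius and gives fresh IDs
to the rest.

The backward pass repeats the same logic in reverse time, with
separation evidence taken over all frames; it replaces aggregate IDs in
earlier frames with the identities resolved later, so cells that are
stuck together when entering the field of view are recovered as long as
they are ever separated in some frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .foreground import Event
from .matching import Matching, MatchingConfig, best_matching_set

__all__ = [
    "TemplateParams",
    "TrackState",
    "max_pairwise_separation",
    "agglomerative_merge",
    "generate_templates",
    "split_event_by_template",
    "forward_pass",
    "backward_pass",
]


def _default_s_grid() -> np.ndarray:
    return np.round(np.arange(0.30, 1.0001, 0.05), 10)


def _default_theta_grid() -> np.ndarray:
    return np.linspace(-math.pi, math.pi, 36, endpoint=False)


@dataclass
class TemplateParams:
    """Search grids for the aggregate-splitting templates.

    ``s_grid`` holds shrink scalars in (0, 1] applied to the members'
    centroid offsets (default 0.30 to 1.00 in steps of 0.05);
    ``theta_grid`` holds rotations in [-pi, pi) (default 36 even steps).
    Overlap ties prefer larger s, then theta closest to 0.
    """

    s_grid: np.ndarray = field(default_factory=_default_s_grid)
    theta_grid: np.ndarray = field(default_factory=_default_theta_grid)

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        if self.s_grid.size == 0 or self.theta_grid.size == 0:
            raise ValueError("template grids must be non-empty")
        if np.any(self.s_grid <= 0) or np.any(self.s_grid > 1):
            raise ValueError("s values must lie in (0, 1]")


@dataclass
class TrackState:
    """Per-frame event lists with evolving cell-ID assignments."""

    events_by_frame: List[List[Event]]
    next_cell_id: int = 1
    log: List[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.events_by_frame)

    def fresh_id(self) -> int:
        cid = self.next_cell_id
        self.next_cell_id += 1
        return cid

    def events_of_cell(self, cell_id: int) -> List[Event]:
        return [
            ev
            for frame_events in self.events_by_frame
            for ev in frame_events
            if ev.cell_id == cell_id
        ]


def max_pairwise_separation(
    state: TrackState,
    cell_a: int,
    cell_b: int,
    frame_range: Optional[range] = None,
) -> float:
    """Maximum center distance between two cells over co-existing frames.

    Returns 0 when the cells never co-exist in ``frame_range``: absence
    of separation evidence forces a merge when they are candidates.
    """
    if frame_range is None:
        frame_range = range(state.n_frames)
    known = {ev.cell_id for fr in state.events_by_frame for ev in fr}
    if cell_a not in known or cell_b not in known:
        raise KeyError(f"unknown cell id(s): {cell_a}, {cell_b}")
    best = 0.0
    seen = False
    for f in frame_range:
        if not 0 <= f < state.n_frames:
            continue
        pos_a = pos_b = None
        for ev in state.events_by_frame[f]:
            if ev.cell_id == cell_a:
                pos_a = ev.center
            elif ev.cell_id == cell_b:
                pos_b = ev.center
        if pos_a is not None and pos_b is not None:
            seen = True
            best = max(best, math.hypot(pos_a[0] - pos_b[0], pos_a[1] - pos_b[1]))
    return best if seen else 0.0


def agglomerative_merge(
    n_members: int, separations: np.ndarray, threshold: float
) -> List[List[int]]:
    """Group members by repeatedly merging the closest pair below threshold.

    ``separations`` is a symmetric matrix of pairwise (maximum historical)
    distances.  The separation of a merged entity to any other is the max
    over its constituents' pairwise values, so a group only forms out of
    members that have never shown decent separation.  Returns the final
    grouping as lists of member indices (deterministic: the smallest pair
    by (distance, indices) merges first).
    """
    separations = np.asarray(separations, dtype=float)
    if separations.shape != (n_members, n_members):
        raise ValueError("separations must be an n x n matrix")
    if not np.allclose(separations, separations.T):
        raise ValueError("separations must be symmetric")
    groups: List[List[int]] = [[k] for k in range(n_members)]

    def pair_sep(ga: List[int], gb: List[int]) -> float:
        return max(float(separations[i, j]) for i in ga for j in gb)

    while len(groups) > 1:
        best = None
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                d = pair_sep(groups[a], groups[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        assert best is not None
        d, a, b = best
        if d >= threshold:
            break
        groups[a] = sorted(groups[a] + groups[b])
        del groups[b]
    return groups


def _joint_centroid(members: Sequence[Event]) -> np.ndarray:
    """Pixel-weighted joint centroid of several events, as (x, y)."""
    coords = np.concatenate([m.coords for m in members])
    return np.array([coords[:, 1].mean(), coords[:, 0].mean()])


def generate_templates(
    members: Sequence[Event], params: TemplateParams
) -> List[Tuple[List[np.ndarray], Tuple[float, float]]]:
    """Candidate configurations of the members for aggregate splitting.

    For each (s, theta) on the grids, every member's pixel set is rigidly
    translated so that its centroid offset from the members' joint
    centroid is scaled by s and rotated by theta (integer-rounded
    translation); member shapes themselves are not rescaled or rotated.
    Returns ``[(member_coord_arrays, (s, theta)), ...]``.
    """
    if len(members) < 2:
        raise ValueError("template generation needs at least 2 members")
    joint = _joint_centroid(members)
    centers = np.array([[m.x, m.y] for m in members])
    offsets = centers - joint  # (k, 2) in (x, y)
    out = []
    for s in params.s_grid:
        for theta in params.theta_grid:
            c, si = math.cos(theta), math.sin(theta)
            rot = np.array([[c, -si], [si, c]])
            new_off = s * offsets @ rot.T
            shift_xy = new_off - offsets
            layout = []
            for k, m in enumerate(members):
                drow = int(round(shift_xy[k, 1]))
                dcol = int(round(shift_xy[k, 0]))
                layout.append(m.coords + np.array([drow, dcol]))
            out.append((layout, (float(s), float(theta))))
    return out


def split_event_by_template(
    one: Event, members: Sequence[Event], params: Optional[TemplateParams] = None
) -> Tuple[List[Event], dict]:
    """Split an aggregate event using its members' shapes as templates.

    The template whose union overlaps the aggregate's pixels most (joint
    centroid aligned to the aggregate centroid; ties broken by larger s,
    then theta closest to 0) selects a member layout; every aggregate
    pixel is then assigned to the member whose nearest template pixel is
    closest.  The resulting sub-events partition the aggregate's pixels
    exactly; a member left empty receives its single nearest pixel so no
    identity is silently dropped.
    """
    params = params or TemplateParams()
    if one.pixel_count < len(members):
        raise ValueError("aggregate has fewer pixels than members")
    one_pixels = set(map(tuple, one.coords.tolist()))
    joint = _joint_centroid(members)
    drow = int(round(one.y - joint[1]))
    dcol = int(round(one.x - joint[0]))

    best = None  # (overlap, s, -|theta|, theta) maximized
    for layout, (s, theta) in generate_templates(members, params):
        shifted = [coords + np.array([drow, dcol]) for coords in layout]
        union = set()
        for coords in shifted:
            union.update(map(tuple, coords.tolist()))
        overlap = len(union & one_pixels)
        key = (overlap, s, -abs(theta), theta)
        if best is None or key > best[0]:
            best = (key, shifted, (s, theta, overlap))
    assert best is not None
    _, shifted, (s, theta, overlap) = best

    # assign each aggregate pixel to the nearest template member; pixels
    # lying inside several members (distance 0 to each) go to the member
    # with the nearest template centroid, via an epsilon-weighted term
    # far below the pixel quantum
    pts = one.coords.astype(float)
    dists = np.empty((len(members), pts.shape[0]))
    for k, coords in enumerate(shifted):
        tree = cKDTree(coords.astype(float))
        d_pix = tree.query(pts)[0]
        cent = coords.mean(axis=0)
        d_cent = np.hypot(pts[:, 0] - cent[0], pts[:, 1] - cent[1])
        dists[k] = d_pix + 1e-6 * d_cent
    assign = np.argmin(dists, axis=0)  # residual ties -> lowest member index

    # re-seed members that received no pixels with their nearest pixel
    for k in range(len(members)):
        if not np.any(assign == k):
            cent = shifted[k].mean(axis=0)
            d = np.hypot(pts[:, 0] - cent[0], pts[:, 1] - cent[1])
            order = np.argsort(d, kind="stable")
            for idx in order:
                owner = assign[idx]
                if np.sum(assign == owner) > 1:
                    assign[idx] = k
                    break

    subs = []
    for k in range(len(members)):
        sel = assign == k
        subs.append(
            Event.from_pixels(
                frame=one.frame,
                event_id=-1,  # renumbered by the caller
                coords=one.coords[sel],
                intensities=one.intensities[sel],
            )
        )
    return subs, {"s": s, "theta": theta, "overlap": overlap}


def _renumber(frame_events: List[Event]) -> None:
    """Keep within-frame event ordinals unique and raster-ordered."""
    frame_events.sort(key=lambda ev: (ev.coords[:, 0].min(), ev.coords[:, 1].min(), ev.x))
    for k, ev in enumerate(frame_events):
        ev.event_id = k


def _unite_events(events: Sequence[Event], cell_id: Optional[int]) -> Event:
    coords = np.concatenate([ev.coords for ev in events])
    inten = np.concatenate([ev.intensities for ev in events])
    return Event.from_pixels(
        frame=events[0].frame, event_id=-1, coords=coords, intensities=inten,
        cell_id=cell_id,
    )


def _merge_cells(
    state: TrackState, cell_ids: Sequence[int], frames: range
) -> int:
    """Fuse several cells into one fresh identity over ``frames``.

    Within each frame the cells' events (if several co-exist) are united
    into a single event; pixel sets are conserved.
    """
    new_id = state.fresh_id()
    for f in frames:
        frame_events = state.events_by_frame[f]
        mine = [ev for ev in frame_events if ev.cell_id in cell_ids]
        if not mine:
            continue
        if len(mine) == 1:
            mine[0].cell_id = new_id
        else:
            merged = _unite_events(mine, new_id)
            for ev in mine:
                frame_events.remove(ev)
            frame_events.append(merged)
            _renumber(frame_events)
    state.log.append(
        {"action": "merge_cells", "old_ids": tuple(cell_ids), "new_ids": (new_id,)}
    )
    return new_id


def _apply_multiple_to_one(
    state: TrackState,
    sources: List[Event],
    one: Event,
    frame_of_one: int,
    history: range,
    cfg: MatchingConfig,
    tparams: TemplateParams,
) -> None:
    """Shared merge-or-split resolution of a multiple-to-one matching.

    ``sources`` are the already-identified events on the multiple side,
    ``one`` the aggregate on the single side, ``history`` the frames over
    which separation evidence is collected (up to the current frame in
    the forward pass, all frames in the backward pass).
    """
    cells = [ev.cell_id for ev in sources]
    k = len(cells)
    sep = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            sep[a, b] = sep[b, a] = max_pairwise_separation(
                state, cells[a], cells[b], history
            )
    groups = agglomerative_merge(k, sep, threshold=one.radius)

    group_ids: List[int] = []
    for g in groups:
        if len(g) == 1:
            group_ids.append(cells[g[0]])
        else:
            group_ids.append(_merge_cells(state, [cells[i] for i in g], history))

    if len(group_ids) == 1:
        one.cell_id = group_ids[0]
        return

    # still multiple distinct identities: split the aggregate using the
    # (possibly merged) member events from the source frame as templates
    src_frame = sources[0].frame
    members = []
    for cid in group_ids:
        evs = [ev for ev in state.events_by_frame[src_frame] if ev.cell_id == cid]
        members.append(evs[0])
    subs, info = split_event_by_template(one, members, tparams)
    for sub, member in zip(subs, members):
        sub.cell_id = member.cell_id
    frame_events = state.events_by_frame[frame_of_one]
    frame_events.remove(one)
    frame_events.extend(subs)
    _renumber(frame_events)
    state.log.append(
        {
            "action": "split",
            "frame": frame_of_one,
            "old_ids": (one.cell_id,),
            "new_ids": tuple(m.cell_id for m in members),
            **info,
        }
    )


def _apply_one_to_multiple(
    state: TrackState,
    one: Event,
    targets: List[Event],
    frame_of_targets: int,
    cfg: MatchingConfig,
    tparams: TemplateParams,
    history: Optional[range] = None,
) -> None:
    """Resolve a one-to-multiple matching (an aggregate detaching).

    Targets closer than the aggregate's radius are merged (within-frame
    center distances in the forward pass; all-frame separations of the
    targets' cells in the backward pass, per ``history``).  A full merge
    reduces to one-to-one; otherwise the remaining events are treated as
    newly appeared and receive fresh identities.
    """
    k = len(targets)
    sep = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            if history is None:
                d = math.hypot(
                    targets[a].x - targets[b].x, targets[a].y - targets[b].y
                )
            else:
                d = max_pairwise_separation(
                    state, targets[a].cell_id, targets[b].cell_id, history
                )
            sep[a, b] = sep[b, a] = d
    groups = agglomerative_merge(k, sep, threshold=one.radius)

    if history is None:
        # forward: unite unidentified target events within their frame
        frame_events = state.events_by_frame[frame_of_targets]
        new_targets: List[Event] = []
        for g in groups:
            if len(g) == 1:
                new_targets.append(targets[g[0]])
            else:
                merged = _unite_events([targets[i] for i in g], None)
                for i in g:
                    frame_events.remove(targets[i])
                frame_events.append(merged)
                new_targets.append(merged)
        _renumber(frame_events)
        if len(new_targets) == 1:
            new_targets[0].cell_id = one.cell_id
        else:
            for ev in new_targets:
                ev.cell_id = state.fresh_id()
    else:
        # backward: targets carry identities; merge the cells themselves
        group_ids = []
        for g in groups:
            if len(g) == 1:
                group_ids.append(targets[g[0]].cell_id)
            else:
                group_ids.append(
                    _merge_cells(state, [targets[i].cell_id for i in g], history)
                )
        evs = [
            ev
            for ev in state.events_by_frame[frame_of_targets]
            if ev.cell_id in group_ids
        ]
        if len(group_ids) == 1:
            evs[0].cell_id = one.cell_id
        else:
            for ev in evs:
                ev.cell_id = state.fresh_id()


def forward_pass(
    state: TrackState,
    cfg: Optional[MatchingConfig] = None,
    tparams: Optional[TemplateParams] = None,
) -> TrackState:
    """Chronological linking sweep.

    Seeds unique IDs in the first frame, then applies the best matching
    set between each consecutive frame pair: disappearing events are left
    alone, appearing events get fresh IDs, one-to-one matchings propagate
    the identity, and multiple-to-one / one-to-multiple matchings go
    through the merge-or-split resolution.
    """
    cfg = cfg or MatchingConfig()
    tparams = tparams or TemplateParams()
    if state.n_frames == 0:
        return state
    for ev in state.events_by_frame[0]:
        if ev.cell_id is None:
            ev.cell_id = state.fresh_id()
    for f in range(state.n_frames - 1):
        current = state.events_by_frame[f]
        next_ = state.events_by_frame[f + 1]
        ms = best_matching_set(current, next_, cfg, direction="forward")
        # bind index references before any structural edit of the lists
        bound = [
            ([current[i] for i in m.sources], [next_[j] for j in m.targets], m.kind)
            for m in ms.matchings
        ]
        for srcs, tgts, kind in bound:
            if kind == "disappear":
                continue
            if kind == "appear":
                tgts[0].cell_id = state.fresh_id()
            elif kind == "one_to_one":
                tgts[0].cell_id = srcs[0].cell_id
            elif kind == "multiple_to_one":
                _apply_multiple_to_one(
                    state, srcs, tgts[0], f + 1, range(0, f + 1), cfg, tparams
                )
            elif kind == "one_to_multiple":
                _apply_one_to_multiple(
                    state, srcs[0], tgts, f + 1, cfg, tparams, history=None
                )
    return state


def backward_pass(
    state: TrackState,
    cfg: Optional[MatchingConfig] = None,
    tparams: Optional[TemplateParams] = None,
) -> TrackState:
    """Reverse-time linking sweep re-resolving aggregate identities.

    Identical logic to the forward pass with reversed time direction and
    separation matrices computed over all frames, so identities resolved
    late in the video propagate into earlier aggregates.
    """
    cfg = cfg or MatchingConfig()
    tparams = tparams or TemplateParams()
    all_frames = range(state.n_frames)
    for f in range(state.n_frames - 1, 0, -1):
        current = state.events_by_frame[f]  # later frame = source side
        prev = state.events_by_frame[f - 1]
        ms = best_matching_set(current, prev, cfg, direction="backward")
        bound = [
            ([current[i] for i in m.sources], [prev[j] for j in m.targets], m.kind)
            for m in ms.matchings
        ]
        for srcs, tgts, kind in bound:
            if kind == "disappear":
                continue
            if kind == "appear":
                tgts[0].cell_id = state.fresh_id()
            elif kind == "one_to_one":
                tgts[0].cell_id = srcs[0].cell_id
            elif kind == "multiple_to_one":
                _apply_multiple_to_one(
                    state, srcs, tgts[0], f - 1, all_frames, cfg, tparams
                )
            elif kind == "one_to_multiple":
                _apply_one_to_multiple(
                    state, srcs[0], tgts, f - 1, cfg, tparams, history=all_frames
                )
    return state


def provenance_table(state: TrackState):
    """Merge/split provenance as a DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for entry in state.log:
        rows.append(
            {
                "frame": entry.get("frame", ""),
                "action": entry["action"],
                "old_ids": ";".join(map(str, entry.get("old_ids", ()))),
                "new_ids": ";".join(map(str, entry.get("new_ids", ()))),
                "s": entry.get("s", ""),
                "theta": entry.get("theta", ""),
                "overlap": entry.get("overlap", ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["frame", "action", "old_ids", "new_ids", "s", "theta", "overlap"]
    )
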