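"""Frame-to-frame matching-set enumeration and scoring.

Between two consecutive frames, every event of either frame is assigned to
exactly one *matching*: appear (phi->j), disappear (i->phi), one-to-one,
one-to-multiple (an aggregate detaching) or multiple-to-one (cells
colliding into an aggregate).  Multiple-to-multiple matchings are not
admitted.  A candidate edge connects a current-frame event to a nearby,
downstream next-frame event; an admissible *matching set* is any edge
subset in which no connected component links two or more sources with two
or more targets, with untouched events becoming disappear/appear
matchings.  Each matching is scored by penalizing changes in size, center
displacement and pixel-intensity distribution, and the set score is the
product of its members' scores; the admissible set with the highest
product score is applied.

Score comparison is done in the log domain, and the optimization
decomposes over connected components of the candidate adjacency because
the product factorizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .foreground import Event

__all__ = [
    "MatchingConfig",
    "Matching",
    "MatchingSet",
    "PooledStats",
    "candidate_edges",
    "enumerate_matching_sets",
    "pooled_intensity_stats",
    "score_matching",
    "best_matching_set",
]

Edge = Tuple[int, int]


@dataclass
class MatchingConfig:
    """Parameters of candidate gating and score regularization.

    nearby_factor
        Two events are "nearby" when their center distance is within this
        multiple of the larger of their radii (default 5); this sets the
        speed limit of trackable cells.
    upstream_slack
        Pixels a target may sit upstream of its source and still count as
        "further along the flow direction"; absorbs sub-pixel jitter of
        slow cells (default 1).
    size_floor, distance_floor
        Minimum magnitudes substituted for zero size differences and zero
        per-axis displacements in score denominators (default 1 pixel
        each); the printed score expressions are singular without them.
    factor_floor
        Minimum value of an intensity factor, keeping every score
        strictly positive (default 1e-6).
    max_edges_per_component
        Guard on exact enumeration per adjacency component.
    flow_sign
        +1 for left-to-right flow (+x); -1 flips the direction for
        mirrored recordings.
    """

    nearby_factor: float = 5.0
    upstream_slack: float = 1.0
    size_floor: float = 1.0
    distance_floor: float = 1.0
    factor_floor: float = 1e-6
    max_edges_per_component: int = 20
    flow_sign: int = 1

    def __post_init__(self) -> None:
        if self.nearby_factor <= 0:
            raise ValueError("nearby_factor must be > 0")
        for name in ("size_floor", "distance_floor", "factor_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.flow_sign not in (1, -1):
            raise ValueError("flow_sign must be +1 or -1")


@dataclass
class Matching:
    """One matching within a set; ``sources``/``targets`` are indices into
    the current/next frame event lists."""

    kind: str  # appear | disappear | one_to_one | one_to_multiple | multiple_to_one
    sources: Tuple[int, ...]
    targets: Tuple[int, ...]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        ns, nt = len(self.sources), len(self.targets)
        ok = {
            "appear": ns == 0 and nt == 1,
            "disappear": ns == 1 and nt == 0,
            "one_to_one": ns == 1 and nt == 1,
            "one_to_multiple": ns == 1 and nt >= 2,
            "multiple_to_one": ns >= 2 and nt == 1,
        }.get(self.kind)
        if not ok:
            raise ValueError(
                f"invalid matching: kind={self.kind} sources={self.sources} targets={self.targets}"
            )


@dataclass
class MatchingSet:
    """A complete admissible assignment of both frames' events."""

    matchings: List[Matching]
    log_score: Optional[float] = None

    @property
    def total_score(self) -> Optional[float]:
        return None if self.log_score is None else math.exp(self.log_score)

    def edges(self) -> Tuple[Edge, ...]:
        """Canonical encoding: the sorted tuple of matched (source, target)
        index pairs."""
        out = []
        for m in self.matchings:
            for i in m.sources:
                for j in m.targets:
                    out.append((i, j))
        return tuple(sorted(out))


@dataclass(frozen=True)
class PooledStats:
    """Mean and population SD of pixel intensities over the union of
    several events' member pixels."""

    mean: float
    sd: float


def candidate_edges(
    current: Sequence[Event],
    next_: Sequence[Event],
    cfg: MatchingConfig,
    direction: str = "forward",
) -> List[Edge]:
    """Admissible (source, target) pairs between two frames.

    Forward: the target must be nearby (center distance within
    ``nearby_factor`` times the larger radius) and not sit upstream of
    the source by more than the effective slack; backward mirrors time
    (the source frame is the later one and the target must not sit
    downstream by more than the slack).

    The effective slack is ``max(upstream_slack, larger radius)``: the
    centroid of an aggregate can lie up to its radius behind its
    forward-most member, so a center-only downstream test would force
    the leading cell of a collision to "disappear" when the union blob
    forms.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    edges: List[Edge] = []
    for i, ev_i in enumerate(current):
        for j, ev_j in enumerate(next_):
            dx = cfg.flow_sign * (ev_j.x - ev_i.x)
            slack = max(cfg.upstream_slack, ev_i.radius, ev_j.radius)
            if direction == "forward":
                if dx < -slack:
                    continue
            else:
                if dx > slack:
                    continue
            dist = math.hypot(ev_j.x - ev_i.x, ev_j.y - ev_i.y)
            if dist <= cfg.nearby_factor * max(ev_i.radius, ev_j.radius):
                edges.append((i, j))
    return edges


class _DSU:
    """Union-find over event nodes tracking how many distinct sources and
    targets each component touches (to reject multiple-to-multiple)."""

    def __init__(self) -> None:
        self.parent: Dict[Tuple[str, int], Tuple[str, int]] = {}
        self.n_src: Dict[Tuple[str, int], int] = {}
        self.n_tgt: Dict[Tuple[str, int], int] = {}

    def copy(self) -> "_DSU":
        d = _DSU()
        d.parent = dict(self.parent)
        d.n_src = dict(self.n_src)
        d.n_tgt = dict(self.n_tgt)
        return d

    def find(self, x: Tuple[str, int]) -> Tuple[str, int]:
        if x not in self.parent:
            self.parent[x] = x
            self.n_src[x] = 1 if x[0] == "s" else 0
            self.n_tgt[x] = 1 if x[0] == "t" else 0
            return x
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: Tuple[str, int], b: Tuple[str, int]) -> bool:
        """Union the components of a and b; return True when the merged
        component is still admissible (< 2 sources or < 2 targets)."""
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
            self.n_src[ra] += self.n_src[rb]
            self.n_tgt[ra] += self.n_tgt[rb]
        return self.n_src[ra] < 2 or self.n_tgt[ra] < 2


def _admissible_subsets(edges: Sequence[Edge]) -> Iterable[Tuple[Edge, ...]]:
    """Yield every admissible subset of ``edges`` exactly once.

    Admissibility is downward closed (adding edges only grows
    components), so the include-branch of the subset recursion can be
    pruned as soon as a component gains >= 2 sources and >= 2 targets.
    """
    edges = list(edges)

    def rec(k: int, chosen: List[Edge], dsu: _DSU):
        if k == len(edges):
            yield tuple(chosen)
            return
        # exclude edges[k]
        yield from rec(k + 1, chosen, dsu)
        # include edges[k] if still admissible
        i, j = edges[k]
        d2 = dsu.copy()
        if d2.union(("s", i), ("t", j)):
            chosen.append(edges[k])
            yield from rec(k + 1, chosen, d2)
            chosen.pop()

    yield from rec(0, [], _DSU())


def matchings_from_edges(
    chosen: Sequence[Edge], n_current: int, n_next: int
) -> List[Matching]:
    """Complete a chosen edge subset into a full matching list, turning
    untouched events into disappear/appear matchings."""
    by_source: Dict[int, List[int]] = {}
    by_target: Dict[int, List[int]] = {}
    for i, j in chosen:
        by_source.setdefault(i, []).append(j)
        by_target.setdefault(j, []).append(i)

    matchings: List[Matching] = []
    done_targets = set()
    for i in sorted(by_source):
        tgts = sorted(by_source[i])
        if len(tgts) == 1:
            j = tgts[0]
            srcs = by_target[j]
            if len(srcs) > 1:
                continue  # handled via the target side below
            matchings.append(Matching("one_to_one", (i,), (j,)))
            done_targets.add(j)
        else:
            matchings.append(Matching("one_to_multiple", (i,), tuple(tgts)))
            done_targets.update(tgts)
    for j in sorted(by_target):
        srcs = sorted(by_target[j])
        if len(srcs) > 1:
            matchings.append(Matching("multiple_to_one", tuple(srcs), (j,)))
            done_targets.add(j)
    for i in range(n_current):
        if i not in by_source:
            matchings.append(Matching("disappear", (i,), ()))
    for j in range(n_next):
        if j not in by_target and j not in done_targets:
            matchings.append(Matching("appear", (), (j,)))
    return matchings


def _adjacency_components(
    edges: Sequence[Edge], n_current: int, n_next: int
) -> List[Tuple[List[int], List[int], List[Edge]]]:
    """Connected components of the candidate adjacency, including isolated
    events as singleton components."""
    dsu = _DSU()
    for i in range(n_current):
        dsu.find(("s", i))
    for j in range(n_next):
        dsu.find(("t", j))
    for i, j in edges:
        dsu.union(("s", i), ("t", j))
    comps: Dict[Tuple[str, int], Tuple[List[int], List[int], List[Edge]]] = {}
    for i in range(n_current):
        comps.setdefault(dsu.find(("s", i)), ([], [], []))[0].append(i)
    for j in range(n_next):
        comps.setdefault(dsu.find(("t", j)), ([], [], []))[1].append(j)
    for e in edges:
        comps[dsu.find(("s", e[0]))][2].append(e)
    return [comps[k] for k in sorted(comps)]


def enumerate_matching_sets(
    edges: Sequence[Edge],
    n_current: int,
    n_next: int,
    cfg: Optional[MatchingConfig] = None,
) -> List[MatchingSet]:
    """All admissible matching sets over the given candidate adjacency
    (unscored skeletons).

    Enumeration is exact per connected component of the adjacency; a
    component with more than ``max_edges_per_component`` edges raises, as
    the gating parameters likely need review.
    """
    cfg = cfg or MatchingConfig()
    comps = _adjacency_components(edges, n_current, n_next)
    per_comp: List[List[Tuple[Edge, ...]]] = []
    for _, _, comp_edges in comps:
        if len(comp_edges) > cfg.max_edges_per_component:
            raise RuntimeError(
                f"adjacency component has {len(comp_edges)} edges "
                f"(> max_edges_per_component={cfg.max_edges_per_component}); "
                "review nearby_factor/upstream_slack"
            )
        per_comp.append(list(_admissible_subsets(comp_edges)))
    sets: List[MatchingSet] = []
    for combo in itertools.product(*per_comp) if per_comp else [()]:
        chosen = tuple(sorted(e for part in combo for e in part))
        sets.append(MatchingSet(matchings_from_edges(chosen, n_current, n_next)))
    return sets


def pooled_intensity_stats(events: Sequence[Event]) -> PooledStats:
    """Mean and population SD over the multiset union of the events'
    member pixel intensities."""
    if len(events) == 0:
        raise ValueError("pooled stats need at least one event")
    vals = np.concatenate([ev.intensities for ev in events])
    return PooledStats(mean=float(vals.mean()), sd=float(vals.std()))


def _intensity_factor(a: float, b: float, floor: float) -> float:
    m = max(a, b)
    if m <= 0.0:
        return 1.0 if a == b else floor
    return max(1.0 - abs(a - b) / m, floor)


def score_matching(
    m: Matching,
    current: Sequence[Event],
    next_: Sequence[Event],
    cfg: MatchingConfig,
) -> float:
    """Score of an individual matching (always finite and > 0).

    Disappear/appear score (1/P)^2 in the event's pixel count.  Matched
    kinds multiply a squared inverse size-difference factor, an inverse
    per-axis displacement factor, and two intensity-similarity factors in
    the mean and SD of pixel intensities (pooled over the multiple side).
    Size differences and axis displacements are floored at the pixel
    quantum so identical events score 1.
    """
    if m.kind == "disappear":
        p = current[m.sources[0]].pixel_count
        if p <= 0:
            raise ValueError("non-positive pixel count")
        return (1.0 / p) ** 2
    if m.kind == "appear":
        p = next_[m.targets[0]].pixel_count
        if p <= 0:
            raise ValueError("non-positive pixel count")
        return (1.0 / p) ** 2

    srcs = [current[i] for i in m.sources]
    tgts = [next_[j] for j in m.targets]
    if any(ev.pixel_count <= 0 for ev in srcs + tgts):
        raise ValueError("non-positive pixel count")

    p_src = sum(ev.pixel_count for ev in srcs)
    p_tgt = sum(ev.pixel_count for ev in tgts)
    size = max(abs(p_src - p_tgt), cfg.size_floor)

    # the "one" side is single by construction; displacements are taken
    # per axis as the max over the multiple side
    if len(srcs) == 1:
        one, many = srcs[0], tgts
    else:
        one, many = tgts[0], srcs
    dx = max(abs(one.x - ev.x) for ev in many)
    dy = max(abs(one.y - ev.y) for ev in many)
    dist = max(dx, cfg.distance_floor) * max(dy, cfg.distance_floor)

    stats_src = pooled_intensity_stats(srcs)
    stats_tgt = pooled_intensity_stats(tgts)
    f_mu = _intensity_factor(stats_src.mean, stats_tgt.mean, cfg.factor_floor)
    f_sd = _intensity_factor(stats_src.sd, stats_tgt.sd, cfg.factor_floor)

    return (1.0 / size) ** 2 * (1.0 / dist) * f_mu * f_sd


def score_matching_set(
    ms: MatchingSet,
    current: Sequence[Event],
    next_: Sequence[Event],
    cfg: MatchingConfig,
) -> MatchingSet:
    """Fill in member scores and the log-domain total of a skeleton set."""
    total = 0.0
    for m in ms.matchings:
        m.score = score_matching(m, current, next_, cfg)
        total += math.log(m.score)
    ms.log_score = total
    return ms


def best_matching_set(
    current: Sequence[Event],
    next_: Sequence[Event],
    cfg: Optional[MatchingConfig] = None,
    direction: str = "forward",
) -> MatchingSet:
    """The admissible matching set with maximal product score.

    The argmax decomposes over connected components of the candidate
    adjacency; ties in log score are broken by the lexicographically
    smallest canonical edge encoding.  With no events on either side the
    empty set (score 1) is returned.
    """
    cfg = cfg or MatchingConfig()
    edges = candidate_edges(current, next_, cfg, direction)
    comps = _adjacency_components(edges, len(current), len(next_))

    best_edges: List[Edge] = []
    for src_idx, tgt_idx, comp_edges in comps:
        if len(comp_edges) > cfg.max_edges_per_component:
            raise RuntimeError(
                f"adjacency component has {len(comp_edges)} edges "
                f"(> max_edges_per_component={cfg.max_edges_per_component}); "
                "review nearby_factor/upstream_slack"
            )
        best: Optional[Tuple[float, Tuple[Edge, ...]]] = None
        for subset in _admissible_subsets(comp_edges):
            chosen = tuple(sorted(subset))
            log_total = 0.0
            # score only this component's events; index maps are global
            sub_matchings = _component_matchings(chosen, src_idx, tgt_idx)
            for m in sub_matchings:
                log_total += math.log(score_matching(m, current, next_, cfg))
            if (
                best is None
                or log_total > best[0]
                or (log_total == best[0] and chosen < best[1])
            ):
                best = (log_total, chosen)
        assert best is not None
        best_edges.extend(best[1])

    chosen = tuple(sorted(best_edges))
    ms = MatchingSet(matchings_from_edges(chosen, len(current), len(next_)))
    return score_matching_set(ms, current, next_, cfg)


def _component_matchings(
    chosen: Sequence[Edge], src_idx: Sequence[int], tgt_idx: Sequence[int]
) -> List[Matching]:
    """Matchings covering exactly one adjacency component's events."""
    by_source: Dict[int, List[int]] = {}
    by_target: Dict[int, List[int]] = {}
    for i, j in chosen:
        by_source.setdefault(i, []).append(j)
        by_target.setdefault(j, []).append(i)
    out: List[Matching] = []
    for i in sorted(by_source):
        tgts = sorted(by_source[i])
        if len(tgts) == 1 and len(by_target[tgts[0]]) > 1:
            continue
        kind = "one_to_one" if len(tgts) == 1 else "one_to_multiple"
        out.append(Matching(kind, (i,), tuple(tgts)))
    for j in sorted(by_target):
        srcs = sorted(by_target[j])
        if len(srcs) > 1:
            out.append(Matching("multiple_to_one", tuple(srcs), (j,)))
    matched_t = set(j for _, j in chosen)
    for i in src_idx:
        if i not in by_source:
            out.append(Matching("disappear", (i,), ()))
    for j in tgt_idx:
        if j not in matched_t:
            out.append(Matching("appear", (), (j,)))
    return out
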