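import itertools
import math

import numpy as np
import pytest

from ridgetrack.foreground import Event
from ridgetrack.matching import (
    Matching,
    MatchingConfig,
    best_matching_set,
    candidate_edges,
    enumerate_matching_sets,
    pooled_intensity_stats,
    score_matching,
    score_matching_set,
)
from ridgetrack.synthetic import dense_adjacency_example, gated_adjacency_example


# ---------------------------------------------------------------------------
# independent oracle: filter all 2^E edge subsets by the
# no-multiple-to-multiple rule using a plain BFS component check
# ---------------------------------------------------------------------------


def _admissible_bruteforce(edges):
    out = []
    for size in range(len(edges) + 1):
        for subset in itertools.combinations(edges, size):
            nodes = set()
            adj = {}
            for i, j in subset:
                a, b = ("s", i), ("t", j)
                nodes |= {a, b}
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            ok = True
            unvisited = set(nodes)
            while unvisited:
                comp = set()
                stack = [unvisited.pop()]
                while stack:
                    n = stack.pop()
                    comp.add(n)
                    for m in adj.get(n, ()):
                        if m in unvisited:
                            unvisited.discard(m)
                            stack.append(m)
                n_src = sum(1 for n in comp if n[0] == "s")
                n_tgt = sum(1 for n in comp if n[0] == "t")
                if n_src >= 2 and n_tgt >= 2:
                    ok = False
                    break
            if ok:
                out.append(tuple(sorted(subset)))
    return sorted(out)


def _make_event(x, y, n_pixels=49, frame=0, event_id=0, value=100.0):
    """Compact blob of about n_pixels centered near (x, y)."""
    r = max(1, int(round(math.sqrt(n_pixels / math.pi))))
    rows, cols = np.mgrid[y - r : y + r + 1, x - r : x + r + 1]
    keep = (cols - x) ** 2 + (rows - y) ** 2 <= r * r
    coords = np.column_stack([rows[keep], cols[keep]])
    return Event.from_pixels(frame, event_id, coords,
                             np.full(coords.shape[0], value))


class TestCandidateEdges:
    def test_upstream_event_can_only_appear(self):
        current, next_ = gated_adjacency_example()
        edges = candidate_edges(current, next_, MatchingConfig())
        assert all(j != 1 for _, j in edges)  # the upstream target has no edges

    def test_far_event_excluded_near_event_linked(self):
        current, next_ = gated_adjacency_example()
        edges = candidate_edges(current, next_, MatchingConfig())
        # the downstream target links only to the two nearby sources
        assert sorted(edges) == [(1, 0), (2, 0)]

    def test_no_next_events_empty_adjacency(self):
        current, _ = gated_adjacency_example()
        assert candidate_edges(current, [], MatchingConfig()) == []

    def test_flow_sign_flip_mirrors_condition(self):
        a = _make_event(10, 10)
        b = _make_event(30, 10, frame=1)
        cfg = MatchingConfig()
        assert candidate_edges([a], [b], cfg) == [(0, 0)]
        assert candidate_edges([b], [a], cfg) == []
        cfg_flipped = MatchingConfig(flow_sign=-1)
        assert candidate_edges([b], [a], cfg_flipped) == [(0, 0)]


class TestEnumeration:
    def test_fully_connected_two_by_two_gives_eleven_sets(self):
        current, next_ = dense_adjacency_example()
        cfg = MatchingConfig()
        edges = candidate_edges(current, next_, cfg)
        assert sorted(edges) == [(0, 0), (0, 1), (1, 0), (1, 1)]
        sets = enumerate_matching_sets(edges, 2, 2, cfg)
        assert len(sets) == 11
        assert len(_admissible_bruteforce(edges)) == 11

    def test_gated_adjacency_gives_four_sets(self):
        current, next_ = gated_adjacency_example()
        cfg = MatchingConfig()
        edges = candidate_edges(current, next_, cfg)
        sets = enumerate_matching_sets(edges, len(current), len(next_), cfg)
        assert len(sets) == 4
        assert len(_admissible_bruteforce(edges)) == 4

    def test_empty_adjacency_single_set(self):
        sets = enumerate_matching_sets([], 3, 2)
        assert len(sets) == 1
        kinds = sorted(m.kind for m in sets[0].matchings)
        assert kinds == ["appear", "appear", "disappear", "disappear", "disappear"]

    def test_single_edge_two_sets(self):
        sets = enumerate_matching_sets([(0, 0)], 1, 1)
        assert sorted(s.edges() for s in sets) == [(), ((0, 0),)]

    def test_matches_bruteforce_on_random_adjacencies(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(1, 5)
            n = rng.integers(1, 5)
            all_edges = [(i, j) for i in range(m) for j in range(n)]
            k = int(rng.integers(0, min(len(all_edges), 12) + 1))
            idx = rng.choice(len(all_edges), size=k, replace=False)
            edges = sorted(all_edges[i] for i in idx)
            got = sorted(s.edges() for s in enumerate_matching_sets(edges, m, n))
            assert got == _admissible_bruteforce(edges)

    @pytest.mark.parametrize("m,n", [(1, 1), (1, 2), (2, 2), (2, 3), (3, 3)])
    def test_complete_bipartite_counts_against_oracle(self, m, n):
        edges = [(i, j) for i in range(m) for j in range(n)]
        got = len(enumerate_matching_sets(edges, m, n))
        assert got == len(_admissible_bruteforce(edges))
        if (m, n) == (2, 2):
            assert got == 11

    def test_every_event_covered_exactly_once(self):
        current, next_ = dense_adjacency_example()
        cfg = MatchingConfig()
        edges = candidate_edges(current, next_, cfg)
        for ms in enumerate_matching_sets(edges, 2, 2, cfg):
            src_cover = sorted(i for mm in ms.matchings for i in mm.sources)
            tgt_cover = sorted(j for mm in ms.matchings for j in mm.targets)
            assert src_cover == [0, 1]
            assert tgt_cover == [0, 1]

    def test_component_guard_raises(self):
        edges = [(0, j) for j in range(5)]
        cfg = MatchingConfig(max_edges_per_component=4)
        with pytest.raises(RuntimeError, match="max_edges_per_component"):
            enumerate_matching_sets(edges, 1, 5, cfg)


class TestPooledStats:
    def test_single_event_identity(self):
        ev = _make_event(10, 10)
        stats = pooled_intensity_stats([ev])
        assert stats.mean == pytest.approx(ev.mean_intensity)
        assert stats.sd == pytest.approx(ev.std_intensity)

    def test_two_equal_events_zero_internal_variance(self):
        a = _make_event(10, 10, value=10.0)
        b = _make_event(30, 10, value=20.0)
        assert a.pixel_count == b.pixel_count
        stats = pooled_intensity_stats([a, b])
        assert stats.mean == pytest.approx(15.0)
        assert stats.sd == pytest.approx(5.0)

    def test_identical_distribution_union_keeps_sd(self):
        rng = np.random.default_rng(0)
        coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        vals = rng.uniform(0, 100, 4)
        a = Event.from_pixels(0, 0, coords, vals)
        b = Event.from_pixels(0, 1, coords + 10, vals)
        stats = pooled_intensity_stats([a, b])
        assert stats.sd == pytest.approx(a.std_intensity)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_intensity_stats([])


class TestScoreMatching:
    def test_disappear_score_is_inverse_square_pixel_count(self):
        current, _ = dense_adjacency_example()
        assert current[0].pixel_count == 53
        m = Matching("disappear", (0,), ())
        s = score_matching(m, current, [], MatchingConfig())
        assert s == pytest.approx((1 / 53) ** 2)

    def test_one_to_one_distance_only(self):
        # identical sizes and intensities, displacement (10, 2):
        # 1 * 1/(10*2) * 1 * 1 = 0.05 under the default floors
        a = _make_event(10, 10)
        b = _make_event(20, 12, frame=1)
        m = Matching("one_to_one", (0,), (0,))
        s = score_matching(m, [a], [b], MatchingConfig())
        assert s == pytest.approx(0.05)

    def test_identical_events_zero_displacement_floor_to_one(self):
        a = _make_event(10, 10)
        b = _make_event(10, 10, frame=1)
        m = Matching("one_to_one", (0,), (0,))
        assert score_matching(m, [a], [b], MatchingConfig()) == pytest.approx(1.0)

    def test_one_to_multiple_uses_pooled_stats_and_max_axis(self):
        one = _make_event(10, 20, n_pixels=120)
        t1 = _make_event(20, 12, frame=1, value=90.0)
        t2 = _make_event(22, 28, frame=1, value=110.0)
        cfg = MatchingConfig()
        m = Matching("one_to_multiple", (0,), (0, 1))
        s = score_matching(m, [one], [t1, t2], cfg)
        size = max(abs(one.pixel_count - t1.pixel_count - t2.pixel_count), 1)
        dist = max(abs(one.x - t1.x), abs(one.x - t2.x)) * max(
            abs(one.y - t1.y), abs(one.y - t2.y)
        )
        pooled = pooled_intensity_stats([t1, t2])
        f_mu = 1 - abs(one.mean_intensity - pooled.mean) / max(
            one.mean_intensity, pooled.mean
        )
        f_sd_raw = 1 - abs(one.std_intensity - pooled.sd) / max(
            one.std_intensity, pooled.sd
        )
        f_sd = max(f_sd_raw, cfg.factor_floor)
        assert s == pytest.approx(size ** -2 / dist * f_mu * f_sd)

    def test_scores_positive_and_finite_on_random_events(self):
        rng = np.random.default_rng(3)
        cfg = MatchingConfig()
        for _ in range(50):
            cur = [
                _make_event(int(rng.integers(8, 40)), int(rng.integers(8, 40)),
                            n_pixels=int(rng.integers(10, 120)), event_id=k,
                            value=float(rng.uniform(1, 200)))
                for k in range(2)
            ]
            nxt = [
                _make_event(int(rng.integers(8, 40)), int(rng.integers(8, 40)),
                            n_pixels=int(rng.integers(10, 120)), frame=1, event_id=k,
                            value=float(rng.uniform(1, 200)))
                for k in range(2)
            ]
            for m in (
                Matching("one_to_one", (0,), (1,)),
                Matching("one_to_multiple", (0,), (0, 1)),
                Matching("multiple_to_one", (0, 1), (0,)),
                Matching("disappear", (1,), ()),
                Matching("appear", (), (0,)),
            ):
                s = score_matching(m, cur, nxt, cfg)
                assert math.isfinite(s) and s > 0


class TestBestMatchingSet:
    def test_nearest_pairing_wins_on_dense_example(self):
        current, next_ = dense_adjacency_example()
        best = best_matching_set(current, next_, MatchingConfig())
        assert best.edges() == ((0, 0), (1, 1))
        assert all(m.kind == "one_to_one" for m in best.matchings)

    def test_single_edge_closed_form_threshold(self):
        # one-to-one beats disappear+appear exactly when its score
        # exceeds (1/P)^4
        a = _make_event(10, 10)
        b = _make_event(15, 11, frame=1)
        cfg = MatchingConfig()
        best = best_matching_set([a], [b], cfg)
        s_link = score_matching(Matching("one_to_one", (0,), (0,)), [a], [b], cfg)
        s_unlinked = (1 / a.pixel_count) ** 2 * (1 / b.pixel_count) ** 2
        assert s_link > s_unlinked
        assert best.edges() == ((0, 0),)

    def test_empty_frames_give_empty_product(self):
        best = best_matching_set([], [], MatchingConfig())
        assert best.matchings == []
        assert best.log_score == 0.0
        assert best.total_score == pytest.approx(1.0)

    def test_component_decomposition_equals_exhaustive(self):
        rng = np.random.default_rng(7)
        cfg = MatchingConfig()
        for _ in range(30):
            n_cur = int(rng.integers(0, 5))
            n_nxt = int(rng.integers(0, 5))
            cur = [
                _make_event(int(rng.integers(8, 60)), int(rng.integers(8, 60)),
                            n_pixels=int(rng.integers(12, 90)), event_id=k,
                            value=float(rng.uniform(50, 150)))
                for k in range(n_cur)
            ]
            nxt = [
                _make_event(int(rng.integers(8, 60)), int(rng.integers(8, 60)),
                            n_pixels=int(rng.integers(12, 90)), frame=1, event_id=k,
                            value=float(rng.uniform(50, 150)))
                for k in range(n_nxt)
            ]
            best = best_matching_set(cur, nxt, cfg)
            edges = candidate_edges(cur, nxt, cfg)
            exhaustive = [
                score_matching_set(ms, cur, nxt, cfg)
                for ms in enumerate_matching_sets(edges, n_cur, n_nxt, cfg)
            ]
            top = max(ms.log_score for ms in exhaustive)
            assert best.log_score == pytest.approx(top, abs=1e-9)

    def test_total_score_reproducible_from_members(self):
        current, next_ = dense_adjacency_example()
        cfg = MatchingConfig()
        edges = candidate_edges(current, next_, cfg)
        for ms in enumerate_matching_sets(edges, 2, 2, cfg):
            score_matching_set(ms, current, next_, cfg)
            total = sum(math.log(m.score) for m in ms.matchings)
            assert abs(total - ms.log_score) <= 1e-12 * max(1.0, abs(total))
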