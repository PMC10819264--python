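"""Crossing numbers, extraction and the three validation stages."""

import itertools
import math
import warnings

import numpy as np
import pytest

from polyprint.minutiae import (
    AVERAGED,
    BIFURCATION,
    TERMINATION,
    Minutia,
    MinutiaSet,
    ValidationParams,
    convex_hull,
    crossing_number,
    extract_minutiae,
    filter_same_type_distance,
    merge_clouds,
    roi_filter,
    validate,
)
from conftest import make_set

# same cyclic neighbor order the implementation walks (row, col offsets)
CYCLE = [(-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0)]


def oracle_cn(neigh):
    """Independent oracle: count 0->1 transitions around the 8-cycle."""
    ring = [int(bool(neigh[1 + dr, 1 + dc])) for dr, dc in CYCLE]
    return sum(1 for i in range(8) if ring[i] == 0 and ring[(i + 1) % 8] == 1)


class TestCrossingNumber:
    def test_isolated_point(self):
        neigh = np.zeros((3, 3), dtype=int)
        neigh[1, 1] = 1
        assert crossing_number(neigh) == 0

    def test_single_neighbor_is_termination(self):
        neigh = np.zeros((3, 3), dtype=int)
        neigh[1, 1] = 1
        neigh[0, 1] = 1
        assert crossing_number(neigh) == 1

    def test_three_spread_neighbors_is_bifurcation(self):
        neigh = np.zeros((3, 3), dtype=int)
        neigh[1, 1] = 1
        # pairwise non-adjacent positions on the 8-cycle
        for dr, dc in [(-1, 0), (1, -1), (1, 1)]:
            neigh[1 + dr, 1 + dc] = 1
        assert crossing_number(neigh) == 3

    def test_straight_ridge_interior(self):
        neigh = np.zeros((3, 3), dtype=int)
        neigh[1, :] = 1
        assert crossing_number(neigh) == 2

    def test_all_256_neighborhoods_match_transition_oracle(self):
        for bits in range(256):
            neigh = np.zeros((3, 3), dtype=int)
            neigh[1, 1] = 1
            for k, (dr, dc) in enumerate(CYCLE):
                neigh[1 + dr, 1 + dc] = (bits >> k) & 1
            assert crossing_number(neigh) == oracle_cn(neigh), bits

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            crossing_number(np.zeros((2, 3)))


def oracle_extract(skel):
    """Direct CN at every interior ridge pixel."""
    out = []
    h, w = skel.shape
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            if not skel[r, c]:
                continue
            cn = oracle_cn(skel[r - 1 : r + 2, c - 1 : c + 2])
            if cn == 1:
                out.append((c, r, TERMINATION))
            elif cn == 3:
                out.append((c, r, BIFURCATION))
    return out


class TestExtractMinutiae:
    def test_straight_line_two_terminations(self):
        skel = np.zeros((20, 20), dtype=bool)
        skel[10, 5:15] = True
        s = extract_minutiae(skel)
        got = sorted((m.x, m.y, m.mtype) for m in s)
        assert got == sorted((x, y, t) for x, y, t in oracle_extract(skel))
        assert len(s) == 2
        assert all(m.mtype == TERMINATION for m in s)
        assert {(m.x, m.y) for m in s} == {(5.0, 10.0), (14.0, 10.0)}

    def test_y_shape_one_bifurcation_three_terminations(self):
        skel = np.zeros((30, 30), dtype=bool)
        # three 1-px arms meeting at (15, 15)
        skel[15, 15] = True
        for i in range(1, 8):
            skel[15 - i, 15] = True  # up
            skel[15 + i, 15 - i] = True  # lower-left diagonal
            skel[15 + i, 15 + i] = True  # lower-right diagonal
        s = extract_minutiae(skel)
        expected = oracle_extract(skel)
        assert sorted((m.x, m.y, m.mtype) for m in s) == sorted(expected)
        types = [m.mtype for m in s]
        assert types.count(BIFURCATION) == 1
        assert types.count(TERMINATION) == 3

    def test_empty_skeleton(self):
        s = extract_minutiae(np.zeros((10, 10), dtype=bool))
        assert len(s) == 0

    def test_border_pixels_excluded(self):
        skel = np.zeros((10, 10), dtype=bool)
        skel[0, :] = True  # ridge on the border only
        assert len(extract_minutiae(skel)) == 0


class TestSameTypeDistance:
    def test_close_same_type_pair_both_removed(self):
        s = make_set([(10, 10), (14, 10)], [TERMINATION, TERMINATION])
        assert math.dist((10, 10), (14, 10)) < 5
        out = filter_same_type_distance(s, 5)
        assert len(out) == 0

    def test_close_different_type_pair_survives(self):
        s = make_set([(10, 10), (12, 10)], [TERMINATION, BIFURCATION])
        out = filter_same_type_distance(s, 5)
        assert len(out) == 2

    def test_delta_zero_is_identity(self):
        s = make_set([(10, 10), (11, 10)], [TERMINATION, TERMINATION])
        out = filter_same_type_distance(s, 0)
        assert [m.xy for m in out] == [m.xy for m in s]

    def test_random_set_against_pairwise_oracle(self, rng):
        coords = rng.uniform(0, 100, size=(25, 2))
        types = [TERMINATION if b else BIFURCATION for b in rng.integers(0, 2, 25)]
        s = make_set(coords, types)
        delta = 12.0
        drop = set()
        for i, j in itertools.combinations(range(25), 2):
            if types[i] == types[j] and math.dist(coords[i], coords[j]) < delta:
                drop.update((i, j))
        out = filter_same_type_distance(s, delta)
        expected = [tuple(coords[i]) for i in range(25) if i not in drop]
        assert [m.xy for m in out] == expected


def oracle_hull_vertices(points):
    """Brute force: p is a hull vertex iff some closed half-plane through p
    contains all points with p on its boundary and p extreme on it."""
    verts = []
    pts = [tuple(map(float, p)) for p in points]
    uniq = sorted(set(pts))
    for p in uniq:
        others = [q for q in uniq if q != p]
        for q in others:
            # direction p->q defines a candidate supporting line
            ax, ay = q[0] - p[0], q[1] - p[1]
            side = [
                (r[0] - p[0]) * ay - (r[1] - p[1]) * ax
                for r in others
            ]
            if all(v >= -1e-9 for v in side) or all(v <= 1e-9 for v in side):
                verts.append(p)
                break
    return set(verts)


class TestConvexHull:
    def test_square_plus_center(self):
        pts = [(0, 0), (10, 0), (10, 10), (0, 10), (5, 5)]
        hull = convex_hull(pts)
        assert set(hull) == {(0, 0), (10, 0), (10, 10), (0, 10)}

    def test_hull_is_counter_clockwise(self):
        hull = convex_hull([(0, 0), (10, 0), (10, 10), (0, 10), (5, 5)])
        area2 = sum(
            hull[i][0] * hull[(i + 1) % len(hull)][1]
            - hull[(i + 1) % len(hull)][0] * hull[i][1]
            for i in range(len(hull))
        )
        assert area2 > 0

    def test_triangle(self):
        pts = [(0, 0), (4, 0), (2, 3)]
        assert set(convex_hull(pts)) == set(pts)

    def test_random_points_match_bruteforce_oracle(self, rng):
        pts = rng.uniform(0, 200, size=(50, 2))
        hull = convex_hull(pts)
        assert set(hull) == oracle_hull_vertices(pts)

    @pytest.mark.parametrize(
        "pts", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2), (3, 3)]]
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(ValueError, match="degenerate hull"):
            convex_hull(pts)


def point_segment_distance(p, a, b):
    px, py = p
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    t = ((px - ax) * vx + (py - ay) * vy) / (vx * vx + vy * vy)
    t = max(0.0, min(1.0, t))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def oracle_roi_keep(points, gamma):
    """Brute-force membership: inside hull and >= gamma from every edge."""
    hull = convex_hull(points)
    k = len(hull)
    kept = []
    for p in points:
        inside = all(
            (hull[(i + 1) % k][0] - hull[i][0]) * (p[1] - hull[i][1])
            - (hull[(i + 1) % k][1] - hull[i][1]) * (p[0] - hull[i][0])
            >= 0
            for i in range(k)
        )
        dmin = min(
            point_segment_distance(p, hull[i], hull[(i + 1) % k]) for i in range(k)
        )
        kept.append(inside and dmin >= gamma)
    return kept


class TestRoiFilter:
    def test_gamma_zero_keeps_all(self):
        s = make_set([(0, 0), (100, 0), (100, 100), (0, 100), (50, 50)])
        assert len(roi_filter(s, 0)) == 5

    def test_point_near_edge_removed(self):
        pts = [(0, 0), (100, 0), (100, 100), (0, 100), (5, 50), (50, 50)]
        s = make_set(pts)
        out = roi_filter(s, 10)
        xy = {m.xy for m in out}
        assert (5.0, 50.0) not in xy  # 5 px from the left edge
        assert (50.0, 50.0) in xy

    def test_hull_vertices_removed_for_positive_gamma(self):
        pts = [(0, 0), (100, 0), (100, 100), (0, 100), (50, 50)]
        out = roi_filter(make_set(pts), 1)
        assert {m.xy for m in out} == {(50.0, 50.0)}

    def test_gamma_beyond_inradius_empties_with_warning(self):
        pts = [(0, 0), (20, 0), (20, 20), (0, 20), (10, 10)]
        with pytest.warns(UserWarning):
            out = roi_filter(make_set(pts), 50)
        assert len(out) == 0

    def test_random_sets_match_bruteforce_oracle(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 250, size=(18, 2))
            gamma = float(rng.uniform(2, 40))
            s = make_set(pts)
            expected = oracle_roi_keep([tuple(p) for p in pts], gamma)
            out = roi_filter(s, gamma)
            got = [m.xy in {n.xy for n in out} for m in s]
            assert got == expected

    def test_threshold_monotonicity(self, rng):
        pts = rng.uniform(0, 250, size=(20, 2))
        s = make_set(pts)
        out = roi_filter(s, 15)
        if len(out) == 0:
            pytest.skip("degenerate draw")
        hull = convex_hull([m.xy for m in s])
        k = len(hull)
        dmin = min(
            min(point_segment_distance(m.xy, hull[i], hull[(i + 1) % k]) for i in range(k))
            for m in out
        )
        again = roi_filter(s, dmin)  # lowering gamma to the min kept distance
        assert {m.xy for m in again} >= {m.xy for m in out}
        assert len(again) == len(out) or dmin > 15


class TestMergeClouds:
    def test_pair_replaced_by_centroid(self):
        s = make_set([(10, 10), (12, 10)], [TERMINATION, BIFURCATION])
        out = merge_clouds(s, 5)
        assert len(out) == 1
        assert out[0].mtype == AVERAGED
        assert out[0].xy == (11.0, 10.0)

    def test_three_mutually_close_collapse_to_centroid(self):
        s = make_set([(0, 0), (2, 0), (1, 2)], [TERMINATION, BIFURCATION, TERMINATION])
        out = merge_clouds(s, 5)
        assert len(out) == 1
        assert out[0].xy == (1.0, pytest.approx(2 / 3))

    def test_chain_collapses_via_connected_components(self):
        # a-b close, b-c close, a-c not: one component of three
        s = make_set([(0, 0), (4, 0), (8, 0)])
        out = merge_clouds(s, 5)
        assert len(out) == 1
        assert out[0].xy == (4.0, 0.0)

    def test_radius_zero_is_identity(self):
        s = make_set([(0, 0), (1, 0)])
        out = merge_clouds(s, 0)
        assert [m.xy for m in out] == [(0.0, 0.0), (1.0, 0.0)]

    def test_singletons_untouched(self):
        s = make_set([(0, 0), (100, 100)])
        out = merge_clouds(s, 5)
        assert [m.xy for m in out] == [(0.0, 0.0), (100.0, 100.0)]


class TestValidate:
    def test_sparse_central_set_is_fixed_point(self):
        pts = [(50, 50), (150, 50), (250, 50), (50, 150), (150, 150),
               (250, 150), (50, 250), (150, 250), (250, 250), (150, 200)]
        s = make_set(pts)
        out = validate(s, ValidationParams(delta=10, gamma=10, cloud_radius=10))
        # the 9 interior-enough points minus hull-adjacent ones survive unchanged
        kept = {m.xy for m in out}
        assert kept <= {tuple(map(float, p)) for p in pts}
        assert out.provenance == "validated"

    def test_crafted_fixture_matches_manual_rule_application(self):
        # manual bookkeeping for delta=5, gamma=10, cloud_radius=5:
        # A(40,40) B(43,40) same type, 3 px apart  -> both cut by delta rule
        # C(5,150) termination: within 10 px of the hull      -> cut by ROI
        # D(150,150) E(153,150) different types 3 px apart    -> merged cloud
        # corner anchors form the hull and are cut by ROI
        anchors = [(0, 0), (300, 0), (300, 300), (0, 300)]
        pts = anchors + [(40, 40), (43, 40), (5, 150), (150, 150), (153, 150), (200, 100)]
        types = [TERMINATION, BIFURCATION, TERMINATION, BIFURCATION,
                 TERMINATION, TERMINATION, TERMINATION, TERMINATION,
                 BIFURCATION, BIFURCATION]
        s = make_set(pts, types)
        out = validate(s, ValidationParams(delta=5, gamma=10, cloud_radius=5))
        kept = {m.xy for m in out}
        assert kept == {(151.5, 150.0), (200.0, 100.0)}
        assert {m.mtype for m in out} == {AVERAGED, BIFURCATION}

    def test_all_zero_params_is_identity(self):
        pts = [(10, 10), (50, 10), (30, 40), (20, 25)]
        s = make_set(pts)
        out = validate(s, ValidationParams(delta=0, gamma=0, cloud_radius=0))
        assert [m.xy for m in out] == [m.xy for m in s]

    def test_deterministic_order(self, rng):
        pts = rng.uniform(0, 300, size=(30, 2))
        s = make_set(pts)
        p = ValidationParams(delta=8, gamma=12, cloud_radius=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = validate(s, p)
            b = validate(s, p)
        assert [m.xy for m in a] == [m.xy for m in b]
        assert [m.mtype for m in a] == [m.mtype for m in b]

    def test_steps_non_increasing_except_merge(self, rng):
        pts = rng.uniform(0, 300, size=(40, 2))
        s = make_set(pts)
        s1 = filter_same_type_distance(s, 10)
        assert len(s1) <= len(s)
        s2 = roi_filter(s1, 10)
        assert len(s2) <= len(s1)
        s3 = merge_clouds(s2, 10)
        assert len(s3) <= len(s2)
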