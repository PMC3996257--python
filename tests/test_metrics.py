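"""VLA/FBL measurement, branch-point matching, paired deltas."""

import numpy as np
import pytest

from ermetrics.grid_metrics import (
    BranchPoint,
    ETDRSGrid,
    FBLResult,
    MatchResult,
    QUADRANTS,
    QuadrantVLA,
    SubfieldMetrics,
    compute_fbl,
    compute_fbl_pair,
    compute_vla,
    detect_branch_points,
    match_branch_points,
    pair_metrics,
)


class _Chains:
    """Minimal measurement source: hand-made chains and branch points."""

    def __init__(self, chains, points=()):
        self._chains = chains
        self._points = points

    def root_to_end_chains(self):
        return list(self._chains)

    def branch_points(self):
        return list(self._points)


def _spoke(angle_deg, r0=100.0, r1=4000.0, n=40):
    t = np.radians(angle_deg)
    r = np.linspace(r0, r1, n)
    return np.stack([r * np.cos(t), r * np.sin(t)], axis=1)


class TestComputeVLA:
    def test_four_spokes_flagged_missing_then_relaxed(self, grid):
        src = _Chains([(f"s{i}", _spoke(a)) for i, a in enumerate((90, 270, 0, 180))])
        strict = compute_vla(src, grid)
        assert all(v.missing and v.n == 1 for v in strict.values())
        relaxed = compute_vla(src, grid, min_vessels=1)
        for q in QUADRANTS:
            assert relaxed[q].mean_um == pytest.approx(2500.0, rel=1e-9)

    def test_top5_mean_of_six_candidates(self, grid):
        # six radial vessels packed in the superior sector whose tips stop
        # short of the outer ring, giving clipped lengths {2500, ..., 2000}
        chains = [
            (f"v{i}", _spoke(60 + i * 12, r0=0.01, r1=3000.0 - i * 100.0))
            for i in range(6)
        ]
        src = _Chains(chains)
        out = compute_vla(src, grid)["superior"]
        # clipped lengths are {2500, 2400, ..., 2000}; top five drop 2000
        assert out.n == 5
        assert out.mean_um == pytest.approx(np.mean([2500, 2400, 2300, 2200, 2100]), rel=1e-9)

    def test_matches_polyline_oracle_on_synthetic_tree(self, tree, tree_truth, grid):
        """Exact-intersection VLA equals the dense-resampling oracle."""
        exact = compute_vla(tree, grid)
        for q in QUADRANTS:
            assert not exact[q].missing
            assert exact[q].mean_um == pytest.approx(tree_truth.vla[q].mean_um, rel=2e-3)


class TestBranchPoints:
    def test_detection_filters_and_orders(self, grid):
        pts = [
            ("in_central", (300.0, 0.0)),  # excluded: central subfield
            ("far", (3500.0, 0.0)),  # excluded: beyond 6 mm ring
            ("b", (0.0, 1000.0)),
            ("a", (0.0, 800.0)),
        ]
        out = detect_branch_points(_Chains([], pts), grid)
        assert [p.label for p in out] == ["a", "b"]
        assert out[0].distance_um == pytest.approx(800.0)
        assert out[0].quadrant == "superior"

    def test_equidistant_points_tie_broken_by_angle(self, grid):
        # two points exactly 1000 μm from the foveola (3-4-5 triangle)
        pts = [("p_up", (0.0, 1000.0)), ("p_left", (-600.0, 800.0))]
        out = detect_branch_points(_Chains([], pts), grid)
        # OD temporal axis is -x; CCW angles from temporal: p_up 270°, p_left ~307°
        assert [p.label for p in out] == ["p_up", "p_left"]

    def test_fbl_sum_of_five_nearest(self, grid):
        dists = [1000, 1200, 1400, 1600, 1800, 5000]
        # keep all inside the superior sector and the 6 mm disc
        pts = [(f"p{i}", (0.0, min(d, 2900))) for i, d in enumerate(dists)]
        out = detect_branch_points(_Chains([], pts), grid)
        res = compute_fbl(out, "superior")
        # the 5000 point was clamped to 2900; the five nearest are 1000..1800
        assert res.sum_um == pytest.approx(7000.0)

    def test_fbl_missing_below_five(self, grid):
        pts = [(f"p{i}", (0.0, 800.0 + 100 * i)) for i in range(4)]
        out = detect_branch_points(_Chains([], pts), grid)
        res = compute_fbl(out, "superior")
        assert res.missing and res.sum_um is None


class TestMatching:
    def _points(self, offsets):
        return [
            BranchPoint(f"p{i}", (x, y), float(np.hypot(x, y)), "superior")
            for i, (x, y) in enumerate(offsets)
        ]

    def test_identical_sets_match_identity(self):
        pts = self._points([(0, 800), (200, 1200), (-300, 1500)])
        m = match_branch_points(pts, pts, mode="position")
        assert m.mapping == {"p0": "p0", "p1": "p1", "p2": "p2"}

    def test_uniform_shift_within_limit_matches_fully(self):
        """Mutual-NN matching under a 100 μm uniform shift equals the
        brute-force optimal assignment."""
        import itertools

        pre = self._points([(0, 800), (250, 1300), (-350, 1700), (100, 2300)])
        post = self._points([(x + 70, y + 70) for p in pre for x, y in [p.position_um]])
        m = match_branch_points(pre, post, max_shift_um=300.0, mode="position")
        assert len(m.mapping) == 4
        # brute-force minimal-cost assignment oracle
        a = np.array([p.position_um for p in pre])
        b = np.array([p.position_um for p in post])
        best = min(
            itertools.permutations(range(4)),
            key=lambda perm: sum(np.linalg.norm(a[i] - b[j]) for i, j in enumerate(perm)),
        )
        want = {f"p{i}": f"p{j}" for i, j in enumerate(best)}
        assert m.mapping == want

    def test_shift_beyond_limit_yields_no_match(self):
        pre = self._points([(0, 800)])
        post = self._points([(0, 1200)])
        m = match_branch_points(pre, post, max_shift_um=300.0, mode="position")
        assert m.mapping == {} and m.unmatched_pre == ("p0",)

    def test_label_mode_uses_stable_ids(self):
        pre = self._points([(0, 800), (0, 1200)])
        post = self._points([(500, 900), (0, 1100)])
        m = match_branch_points(pre, post, mode="label")
        assert m.mapping == {"p0": "p0", "p1": "p1"}

    def test_paired_fbl_follows_pre_selection(self, grid):
        pre_pts = detect_branch_points(
            _Chains([], [(f"p{i}", (0.0, 700.0 + 150 * i)) for i in range(6)]), grid
        )
        # post: the five nearest moved outward by 100; p5 unchanged
        post_pts = detect_branch_points(
            _Chains(
                [],
                [(f"p{i}", (0.0, 800.0 + 150 * i)) for i in range(5)]
                + [("p5", (0.0, 700.0 + 150 * 5))],
            ),
            grid,
        )
        match = match_branch_points(pre_pts, post_pts, mode="label")
        pre_res, post_res = compute_fbl_pair(pre_pts, post_pts, "superior", match)
        assert pre_res.labels == ("p0", "p1", "p2", "p3", "p4")
        assert post_res.sum_um == pytest.approx(pre_res.sum_um + 500.0)

    def test_unmatched_selected_point_flags_pair_missing(self, grid):
        pre_pts = detect_branch_points(
            _Chains([], [(f"p{i}", (0.0, 700.0 + 150 * i)) for i in range(5)]), grid
        )
        post_pts = pre_pts[:4]  # p4 vanished post-operatively
        match = match_branch_points(pre_pts, post_pts, mode="label")
        _, post_res = compute_fbl_pair(pre_pts, post_pts, "superior", match)
        assert post_res.missing


def _metrics(visit, vla_vals, fbl_vals, mt_vals, missing=()):
    vla = {
        q: QuadrantVLA(None if q in missing else v, 3, (v, v, v) if v else ())
        for q, v in vla_vals.items()
    }
    for q in missing:
        vla[q] = QuadrantVLA(None, 1, (), missing=True)
    fbl = {q: FBLResult(v, (v / 5.0,) * 5, ("a", "b", "c", "d", "e")) for q, v in fbl_vals.items()}
    return SubfieldMetrics(visit=visit, vla=vla, fbl=fbl, mt=dict(mt_vals))


class TestPairMetrics:
    def test_identical_visits_give_zero_deltas(self):
        kw = dict(
            vla_vals={q: 1500.0 for q in QUADRANTS},
            fbl_vals={"superior": 9000.0, "inferior": 9500.0},
            mt_vals={"central": 350.0, "superior": 330.0},
        )
        pair = pair_metrics(_metrics("pre", **kw), _metrics("post", **kw), 0.3, 0.3)
        assert pair.d_vla_sum == 0.0
        assert pair.d_fbl_sum == 0.0
        assert pair.d_cmt == 0.0
        assert pair.d_bcva == 0.0

    def test_study_sign_conventions(self):
        pre = _metrics(
            "pre",
            {q: 1500.0 for q in QUADRANTS},
            {"superior": 9000.0, "inferior": 9500.0},
            {"central": 360.0},
        )
        post = _metrics(
            "post",
            {q: 1100.0 for q in QUADRANTS},
            {"superior": 9600.0, "inferior": 10100.0},
            {"central": 300.0},
        )
        pair = pair_metrics(pre, post, bcva_pre=0.31, bcva_post=0.08)
        assert pair.d_vla("superior") == pytest.approx(400.0)  # pre - post
        assert pair.d_fbl("superior") == pytest.approx(600.0)  # post - pre
        assert pair.d_cmt == pytest.approx(60.0)
        assert pair.d_bcva == pytest.approx(0.23)
        assert pair.d_vla_sum == pytest.approx(sum(pair.d_vla(q) for q in QUADRANTS))

    def test_missing_component_propagates(self):
        pre = _metrics(
            "pre", {q: 1500.0 for q in QUADRANTS}, {"superior": 9000.0}, {}, missing=("nasal",)
        )
        post = _metrics("post", {q: 1100.0 for q in QUADRANTS}, {"superior": 9300.0}, {})
        pair = pair_metrics(pre, post)
        assert pair.d_vla("nasal") is None
        assert pair.d_vla_sum is None
        assert pair.d_vla("superior") == pytest.approx(400.0)

    def test_visit_label_mismatch_raises(self):
        m = _metrics("pre", {q: 1.0 for q in QUADRANTS}, {}, {})
        with pytest.raises(ValueError):
            pair_metrics(m, m)


class TestFrameInvariance:
    def test_rotation_by_quadrant_permutes_metrics(self, tree, grid):
        """Rotating the whole frame by 90° permutes quadrant labels but
        leaves every VLA value unchanged to 1e-6 relative."""
        from ermetrics.synthetic_fundus import TreeEdge, TreeNode, VesselTree

        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # +90 deg CCW
        nodes = [TreeNode(n.node_id, rot @ n.position, n.role) for n in tree.nodes]
        edges = [
            TreeEdge(e.edge_id, e.kind, (rot @ e.polyline.T).T, e.caliber_um, e.u, e.v)
            for e in tree.edges
        ]
        rotated = VesselTree(nodes, edges, dict(tree.branch_labels))
        base = compute_vla(tree, grid)
        turned = compute_vla(rotated, grid)
        mapping = {"nasal": "superior", "superior": "temporal", "temporal": "inferior",
                   "inferior": "nasal"}  # OD: +x(nasal) -> +y(superior), etc.
        for src, dst in mapping.items():
            assert turned[dst].mean_um == pytest.approx(base[src].mean_um, rel=1e-6)

    def test_small_rotation_preserves_clipped_lengths(self, tree, grid):
        from ermetrics.grid_metrics import clip_to_annulus, polyline_length

        ang = np.radians(5.0)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        for _, poly in tree.root_to_end_chains()[:10]:
            a = sum(polyline_length(p) for p in clip_to_annulus(poly, grid))
            b = sum(polyline_length(p) for p in clip_to_annulus((rot @ poly.T).T, grid))
            assert b == pytest.approx(a, rel=1e-6)
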