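"""Vessel-tree generation, the contraction model, rendering, ground truth."""

import numpy as np
import pytest

from ermetrics.grid_metrics import ETDRSGrid, QUADRANTS, subfield_of
from ermetrics.synthetic_fundus import (
    ContractionField,
    EffectModel,
    GenerationError,
    apply_contraction,
    generate_cohort,
    generate_vessel_tree,
    ground_truth_metrics,
    render_fundus,
    simulate_eye,
    subfield_contraction_index,
)


def _circle_crossed(poly, radius):
    r = np.linalg.norm(poly, axis=1)
    return (r.min() < radius) and (r.max() > radius)


class TestGenerateVesselTree:
    def test_deterministic_for_fixed_seed(self):
        a = generate_vessel_tree(8, 3, seed=1)
        b = generate_vessel_tree(8, 3, seed=1)
        assert len(a.edges) == len(b.edges)
        for ea, eb in zip(a.edges, b.edges):
            np.testing.assert_array_equal(ea.polyline, eb.polyline)
        c = generate_vessel_tree(8, 3, seed=2)
        assert any(
            not np.array_equal(ea.polyline, eb.polyline) for ea, eb in zip(a.edges, c.edges)
        )

    def test_every_quadrant_has_through_going_radial_vessel(self, tree, grid):
        """Brute-force circle-crossing check on all root-to-leaf chains."""
        covered = set()
        for _, poly in tree.root_to_end_chains():
            if _circle_crossed(poly, 500.0) and _circle_crossed(poly, 3000.0):
                mid = poly[np.argmin(np.abs(np.linalg.norm(poly, axis=1) - 1750.0))]
                covered.add(subfield_of(mid, grid))
        assert covered >= set(QUADRANTS)

    def test_enough_branch_points_for_fbl(self, tree, grid):
        counts = {q: 0 for q in QUADRANTS}
        for _, pos in tree.branch_points():
            d = float(np.hypot(*pos))
            if 500.0 < d <= 3000.0:
                counts[subfield_of(pos, grid)] += 1
        assert counts["superior"] >= 5 and counts["inferior"] >= 5

    def test_too_few_arcades_rejected(self):
        with pytest.raises(ValueError):
            generate_vessel_tree(3, 3, seed=1)

    def test_unsatisfiable_geometry_raises_generation_error(self):
        # depth 1 cannot yield five branch points per vertical quadrant
        with pytest.raises(GenerationError):
            generate_vessel_tree(4, 1, seed=1)

    def test_tree_invariants(self, tree):
        tree.validate()


class TestContraction:
    def test_identity_when_amplitude_and_wrinkle_zero(self, tree):
        field = ContractionField(amplitude=0.0, wrinkle_amp_um=0.0)
        out = apply_contraction(tree, field, seed=3)
        for ea, eb in zip(tree.edges, out.edges):
            np.testing.assert_allclose(ea.polyline, eb.polyline, atol=1e-9)

    def test_pure_inward_displacement_shortens_branch_distances(self, tree):
        field = ContractionField(amplitude=0.3, wrinkle_amp_um=0.0, nasal_attenuation=0.3)
        out = apply_contraction(tree, field, seed=3)
        pre = dict(out.branch_points())
        post = dict(tree.branch_points())
        assert pre.keys() == post.keys()
        for label in pre:
            assert np.hypot(*pre[label]) < np.hypot(*post[label])

    def test_wrinkle_only_never_shortens_arc_length(self, tree):
        field = ContractionField(amplitude=0.0, wrinkle_amp_um=35.0)
        out = apply_contraction(tree, field, seed=3)
        for ea, eb in zip(tree.edges, out.edges):
            la = np.linalg.norm(np.diff(ea.polyline, axis=0), axis=1).sum()
            lb = np.linalg.norm(np.diff(eb.polyline, axis=0), axis=1).sum()
            assert lb >= la - 1e-6

    def test_fixed_points_fovea_and_disc(self):
        field = ContractionField(amplitude=0.3, wrinkle_amp_um=30.0)
        pts = np.array([[0.0, 0.0], list(field.disc_position_um)])
        disp = field.displacement(pts, phase=1.2)
        np.testing.assert_allclose(disp, 0.0, atol=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ContractionField(amplitude=0.6)
        with pytest.raises(ValueError):
            ContractionField(amplitude=0.1, sigma_r_um=-1.0)
        with pytest.raises(ValueError):
            ContractionField(amplitude=0.1, nasal_attenuation=1.5)

    def test_nasal_attenuation_reduces_nasal_displacement(self, grid):
        field = ContractionField(amplitude=0.3, nasal_attenuation=0.3)
        idx = subfield_contraction_index(field, grid)
        assert idx["nasal"] < idx["temporal"]
        assert idx["temporal"] > 0


class TestRender:
    def test_empty_tree_renders_background_only(self):
        from ermetrics.synthetic_fundus import VesselTree

        empty = VesselTree([], [], {})
        img = render_fundus(empty, noise_sd=0.0, seed=0)
        assert img.pixels.min() > 140  # no vessel-dark pixels

    def test_render_deterministic(self, tree):
        a = render_fundus(tree, noise_sd=4.0, seed=9)
        b = render_fundus(tree, noise_sd=4.0, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_single_vessel_band_centered_on_polyline(self):
        """The dark band's pixels all lie within half a caliber (+1 px) of
        the true centerline."""
        from ermetrics.synthetic_fundus import TreeEdge, TreeNode, VesselTree

        poly = np.array([[-3000.0, -1200.0], [3000.0, 1200.0]])
        tree = VesselTree(
            [TreeNode(0, poly[0], "root"), TreeNode(1, poly[1], "end")],
            [TreeEdge(0, "artery", poly, 50.0, 0, 1)],
            {},
        )
        img = render_fundus(tree, noise_sd=0.0, seed=0)
        rows, cols = np.nonzero(img.pixels < 140)
        assert len(rows) > 50
        pts_um = np.stack(
            [
                (cols - img.foveola_px[1]) * img.scale_um_per_px,
                (img.foveola_px[0] - rows) * img.scale_um_per_px,
            ],
            axis=1,
        )
        # distance to the (infinite) centerline through the two points
        d = poly[1] - poly[0]
        d = d / np.linalg.norm(d)
        perp = np.abs((pts_um - poly[0]) @ np.array([-d[1], d[0]]))
        assert perp.max() <= 25.0 + img.scale_um_per_px

    def test_raster_too_small_raises(self, tree):
        with pytest.raises(ValueError):
            render_fundus(tree, scale_um_per_px=11.7, size_px=(256, 256))


class TestGroundTruth:
    def test_straight_radial_vessel_true_vla(self, grid):
        from ermetrics.synthetic_fundus import TreeEdge, TreeNode, VesselTree

        poly = np.array([[50.0, 0.0], [4000.0, 0.0]])
        tree = VesselTree(
            [TreeNode(0, poly[0], "root"), TreeNode(1, poly[1], "end")],
            [TreeEdge(0, "artery", poly, 50.0, 0, 1)],
            {},
        )
        gt = ground_truth_metrics(tree, grid, min_vessels=1)
        assert gt.vla["nasal"].mean_um == pytest.approx(2500.0, rel=1e-3)

    def test_circumferential_arc_contributes_nothing(self, grid):
        from ermetrics.synthetic_fundus import TreeEdge, TreeNode, VesselTree

        theta = np.linspace(0.1, 1.2, 120)
        poly = np.stack([1800.0 * np.cos(theta), 1800.0 * np.sin(theta)], axis=1)
        tree = VesselTree(
            [TreeNode(0, poly[0], "root"), TreeNode(1, poly[-1], "end")],
            [TreeEdge(0, "artery", poly, 50.0, 0, 1)],
            {},
        )
        gt = ground_truth_metrics(tree, grid, min_vessels=1)
        assert all(v.n == 0 for v in gt.vla.values())

    def test_fbl_is_sum_of_five_nearest(self, tree_truth):
        for q in ("superior", "inferior"):
            res = tree_truth.fbl[q]
            assert not res.missing
            assert len(res.distances_um) == 5
            assert res.sum_um == pytest.approx(sum(res.distances_um))
            others = [
                p.distance_um
                for p in tree_truth.branch_points
                if p.quadrant == q and p.label not in res.labels
            ]
            assert all(d >= max(res.distances_um) - 1e-9 for d in others)


class TestCohort:
    def test_cohort_files_and_counts(self, tmp_path):
        manifest = generate_cohort(
            tmp_path, n_eyes=2, seed=4, render=True, scale_um_per_px=15.0, size_px=(512, 512)
        )
        import pandas as pd

        df = pd.read_csv(manifest)
        assert len(df) == 2
        assert len(list(tmp_path.glob("*_pre.png"))) == 2
        assert len(list(tmp_path.glob("*_post.png"))) == 2
        assert len(list(tmp_path.glob("*_truth.json"))) == 4

    def test_zero_amplitude_cohort_has_no_systematic_thickening(self):
        d = []
        for i in range(8):
            eye = simulate_eye(i, seed=6, amplitude_range=(0.0, 0.0), compute_truth=False)
            for s in eye.truth_pre.mt_um:
                d.append(eye.truth_pre.mt_um[s] - eye.truth_post.mt_um[s])
        d = np.array(d)
        noise = EffectModel().mt_noise_sd_um
        assert abs(d.mean()) < 3 * noise * np.sqrt(2) / np.sqrt(len(d))

    def test_bcva_worse_before_surgery(self):
        eyes = [simulate_eye(i, seed=8, compute_truth=False) for i in range(8)]
        pre = np.mean([e.truth_pre.bcva_logmar for e in eyes])
        post = np.mean([e.truth_post.bcva_logmar for e in eyes])
        assert pre > post
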