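"""Synthetic infrared-fundus data with a parameterised ERM contraction model.

An idiopathic epiretinal membrane (ERM) exerts tangential traction on the
inner retina: vessels around the macula are drawn inward toward the
foveola and wrinkled, and the effect is attenuated on the nasal side where
the optic disc anchors the retina.  Surgical membrane peeling releases the
traction.  No public dataset accompanies the clinical study design this
package implements, so this module generates the whole study: branching
radial vasculature around a fovea, a paired pre-operative (contracted) /
post-operative (released) state, infrared-style raster renderings, and
exported ground truth (true VLA/FBL, labelled branch points, per-subfield
macular thickness, BCVA) so every downstream stage is testable.

Coordinates: the μm frame has the foveola at the origin, +y superior.
The nasal direction is +x for a right eye (OD) and −x for a left eye (OS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy import ndimage

from .grid_metrics import (
    ETDRSGrid,
    FBL_QUADRANTS,
    FBLResult,
    QUADRANTS,
    QuadrantVLA,
    SUBFIELDS,
    BranchPoint,
    compute_fbl,
    subfield_of,
    subfield_of_points,
)

__all__ = [
    "GenerationError",
    "TreeNode",
    "TreeEdge",
    "VesselTree",
    "ContractionField",
    "FundusImage",
    "GroundTruthMetrics",
    "GroundTruth",
    "EffectModel",
    "SimulatedEye",
    "generate_vessel_tree",
    "apply_contraction",
    "render_fundus",
    "ground_truth_metrics",
    "subfield_contraction_index",
    "simulate_eye",
    "generate_cohort",
]


class GenerationError(RuntimeError):
    """Raised when a valid vessel tree cannot be generated."""


# ---------------------------------------------------------------------------
# Vessel tree
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    node_id: int
    position: np.ndarray  # (2,) μm
    role: str  # root | branch | end


@dataclass
class TreeEdge:
    edge_id: int
    kind: str  # artery | vein
    polyline: np.ndarray  # (N, 2) μm, oriented u -> v (outward)
    caliber_um: float
    u: int
    v: int


@dataclass
class VesselTree:
    """Ground-truth vasculature: a forest of polyline edges in the μm frame.

    ``branch_labels`` gives every branch node a stable string id so that
    the same physical branching point can be identified across visits.
    """

    nodes: list[TreeNode]
    edges: list[TreeEdge]
    branch_labels: dict[int, str]
    laterality: str = "OD"

    def node(self, node_id: int) -> TreeNode:
        return self._node_index()[node_id]

    def _node_index(self) -> dict[int, TreeNode]:
        return {n.node_id: n for n in self.nodes}

    def _degrees(self) -> dict[int, int]:
        deg = {n.node_id: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    def validate(self) -> None:
        idx = self._node_index()
        if len(idx) != len(self.nodes):
            raise ValueError("duplicate node ids")
        deg = self._degrees()
        # acyclicity of the edge graph (forest)
        parent: dict[int, int] = {n.node_id: n.node_id for n in self.nodes}

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for e in self.edges:
            if e.caliber_um <= 0:
                raise ValueError(f"edge {e.edge_id}: caliber must be > 0")
            poly = np.asarray(e.polyline, dtype=float)
            if len(poly) < 2:
                raise ValueError(f"edge {e.edge_id}: polyline needs >= 2 points")
            if np.any(np.linalg.norm(np.diff(poly, axis=0), axis=1) == 0):
                raise ValueError(f"edge {e.edge_id}: consecutive duplicate points")
            ru, rv = find(e.u), find(e.v)
            if ru == rv:
                raise ValueError("edge graph contains a cycle; a vessel tree must be a forest")
            parent[ru] = rv
        for n in self.nodes:
            if n.role == "branch" and deg[n.node_id] < 3:
                raise ValueError(f"branch node {n.node_id} has degree {deg[n.node_id]} < 3")
            if n.role == "end" and deg[n.node_id] != 1:
                raise ValueError(f"end node {n.node_id} has degree {deg[n.node_id]} != 1")
        labels = list(self.branch_labels.values())
        if len(labels) != len(set(labels)):
            raise ValueError("branch_labels must be unique")

    # -- measurement protocol ------------------------------------------------

    def root_to_end_chains(self) -> list[tuple[str, np.ndarray]]:
        """Root→leaf centerline chains (the VLA candidate vessels)."""
        children: dict[int, list[TreeEdge]] = {}
        for e in self.edges:
            children.setdefault(e.u, []).append(e)
        for lst in children.values():
            lst.sort(key=lambda e: e.edge_id)
        chains: list[tuple[str, np.ndarray]] = []
        roots = [n for n in self.nodes if n.role == "root"]
        for root in sorted(roots, key=lambda n: n.node_id):
            stack: list[tuple[int, list[np.ndarray]]] = [(root.node_id, [])]
            while stack:
                nid, acc = stack.pop()
                out_edges = children.get(nid, [])
                if not out_edges:
                    if acc:
                        pts = [acc[0]] + [p[1:] for p in acc[1:]]
                        chains.append((f"t{root.node_id}-{nid}", np.vstack(pts)))
                    continue
                for e in reversed(out_edges):
                    stack.append((e.v, acc + [np.asarray(e.polyline, dtype=float)]))
        chains.sort(key=lambda c: c[0])
        return chains

    def branch_points(self) -> list[tuple[str, tuple[float, float]]]:
        idx = self._node_index()
        out = []
        for nid, label in sorted(self.branch_labels.items()):
            p = idx[nid].position
            out.append((label, (float(p[0]), float(p[1]))))
        return out


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------


def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


class _TreeBuilder:
    def __init__(self) -> None:
        self.nodes: list[TreeNode] = []
        self.edges: list[TreeEdge] = []
        self.branch_labels: dict[int, str] = {}

    def add_node(self, pos: np.ndarray, role: str, label: str | None = None) -> int:
        nid = len(self.nodes)
        self.nodes.append(TreeNode(nid, np.asarray(pos, dtype=float), role))
        if label is not None:
            self.branch_labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, polyline: np.ndarray, kind: str, caliber: float) -> None:
        eid = len(self.edges)
        poly = np.asarray(polyline, dtype=float)
        keep = np.ones(len(poly), bool)
        keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-9
        self.edges.append(TreeEdge(eid, kind, poly[keep], caliber, u, v))


def _march_branch(
    rng: np.random.Generator,
    start: np.ndarray,
    offset_rad: float,
    r_stop: float,
    step_um: float,
    relax_um: float = 500.0,
) -> np.ndarray:
    """March a child vessel outward: its direction starts at ``offset_rad``
    from the local radial direction and relaxes exponentially back to
    radial, so side branches curve back toward a fovea-directed course."""
    pts = [np.asarray(start, dtype=float)]
    s = 0.0
    guard = 0
    while np.linalg.norm(pts[-1]) < r_stop and guard < 2000:
        p = pts[-1]
        radial = p / np.linalg.norm(p)
        d = _rot(radial, offset_rad * math.exp(-s / relax_um))
        pts.append(p + step_um * d)
        s += step_um
        guard += 1
    return np.asarray(pts)


def generate_vessel_tree(
    arcades: int = 8,
    branch_depth: int = 3,
    seed: int = 0,
    *,
    r_start_um: tuple[float, float] = (330.0, 430.0),
    r_end_um: tuple[float, float] = (3400.0, 3900.0),
    step_um: float = 40.0,
    trunk_caliber_um: float = 50.0,
    caliber_decay: float = 0.8,
    max_retries: int = 5,
    laterality: str = "OD",
) -> VesselTree:
    """Generate a radial macular vasculature as a forest of ``arcades`` trunks.

    Each trunk is a perturbed ray from just inside the 1 mm ring to beyond
    the 6 mm ring, carrying ``branch_depth`` side branches (which
    themselves carry ``branch_depth - 2`` grandchildren).  Trunk bearings
    are evenly spaced and offset from the ±45° quadrant diagonals, so every
    quadrant receives at least one through-going radial vessel.
    Deterministic for a fixed seed; raises :class:`GenerationError` when the
    requested geometry cannot be satisfied after bounded retries.
    """
    if arcades < 4:
        raise ValueError("arcades must be >= 4 (at least one radial vessel per quadrant)")
    if branch_depth < 1:
        raise ValueError("branch_depth must be >= 1")

    last_error = "unknown"
    for attempt in range(max_retries):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, attempt])
        b = _TreeBuilder()
        sector = 2.0 * math.pi / arcades
        for i in range(arcades):
            theta = (i + 0.5) * sector + math.radians(rng.uniform(-4.0, 4.0))
            # quadrant centre (0, 90, 180 or 270 deg) nearest this trunk
            qc = round(theta / (math.pi / 2)) % 4 * (math.pi / 2)
            kind = "artery" if i % 2 == 0 else "vein"
            r0 = rng.uniform(*r_start_um)
            r1 = rng.uniform(*r_end_um)
            wob_amp = rng.uniform(15.0, 35.0)
            wob_lambda = rng.uniform(1400.0, 2200.0)
            wob_phase = rng.uniform(0.0, 2.0 * math.pi)
            u_hat = np.array([math.cos(theta), math.sin(theta)])
            n_hat = np.array([-math.sin(theta), math.cos(theta)])

            def trunk_pt(r: float) -> np.ndarray:
                w = wob_amp * math.sin(2 * math.pi * (r - r0) / wob_lambda + wob_phase)
                return r * u_hat + w * n_hat

            # radii of the trunk's branch nodes
            lo, hi = 800.0, 2600.0
            branch_radii = [
                lo + (j + 0.5) * (hi - lo) / branch_depth + rng.uniform(-100.0, 100.0)
                for j in range(branch_depth)
            ]
            branch_radii = sorted(min(max(r, 700.0), 2750.0) for r in branch_radii)

            # trunk polyline sample radii (regular grid + exact branch radii)
            radii = sorted(set(np.arange(r0, r1, step_um)) | {r1} | set(branch_radii))
            node_rs = [r0] + branch_radii + [r1]
            root_id = b.add_node(trunk_pt(r0), "root")
            prev_id, prev_r = root_id, r0
            branch_node_ids: list[int] = []
            for j, rb in enumerate(branch_radii):
                seg = np.array([trunk_pt(r) for r in radii if prev_r <= r <= rb])
                nid = b.add_node(trunk_pt(rb), "branch", label=f"A{i}B{j}")
                b.add_edge(prev_id, nid, seg, kind, trunk_caliber_um)
                branch_node_ids.append(nid)
                prev_id, prev_r = nid, rb
            seg = np.array([trunk_pt(r) for r in radii if prev_r <= r <= r1])
            tip_id = b.add_node(trunk_pt(r1), "end")
            b.add_edge(prev_id, tip_id, seg, kind, trunk_caliber_um)

            # side branches
            ang_from_qc = (theta - qc + math.pi) % (2 * math.pi) - math.pi
            for j, (rb, nid) in enumerate(zip(branch_radii, branch_node_ids)):
                if abs(ang_from_qc) > math.radians(10.0):
                    sign = -math.copysign(1.0, ang_from_qc)  # bend toward quadrant centre
                else:
                    sign = 1.0 if (j % 2 == 0) else -1.0
                offset = sign * math.radians(rng.uniform(18.0, 30.0))
                r_stop = rng.uniform(3100.0, 3600.0)
                child = _march_branch(rng, trunk_pt(rb), offset, r_stop, step_um)
                child_cal = trunk_caliber_um * caliber_decay
                n_grand = max(branch_depth - 2, 0)
                if n_grand == 0:
                    end_id = b.add_node(child[-1], "end")
                    b.add_edge(nid, end_id, child, kind, child_cal)
                    continue
                # grandchild branch points at existing child samples
                child_r = np.linalg.norm(child, axis=1)
                targets = np.linspace(rb + 450.0, 2500.0, n_grand + 2)[1:-1]
                g_idx = sorted(
                    {int(np.clip(np.argmin(np.abs(child_r - t)), 2, len(child) - 3)) for t in targets}
                )
                prev_c, prev_i = nid, 0
                for k, gi in enumerate(g_idx):
                    gid = b.add_node(child[gi], "branch", label=f"A{i}B{j}G{k}")
                    b.add_edge(prev_c, gid, child[prev_i : gi + 1], kind, child_cal)
                    g_off = -offset * rng.uniform(0.8, 1.2)
                    g_stop = rng.uniform(3050.0, 3400.0)
                    grand = _march_branch(rng, child[gi], g_off, g_stop, step_um)
                    g_end = b.add_node(grand[-1], "end")
                    b.add_edge(gid, g_end, grand, kind, child_cal * caliber_decay)
                    prev_c, prev_i = gid, gi
                end_id = b.add_node(child[-1], "end")
                b.add_edge(prev_c, end_id, child[prev_i:], kind, child_cal)

        tree = VesselTree(b.nodes, b.edges, b.branch_labels, laterality=laterality)
        ok, why = _tree_geometry_ok(tree)
        if ok:
            tree.validate()
            return tree
        last_error = why
    raise GenerationError(f"could not generate a valid vessel tree: {last_error}")


def _tree_geometry_ok(tree: VesselTree, grid: ETDRSGrid | None = None) -> tuple[bool, str]:
    grid = grid or ETDRSGrid(laterality=tree.laterality)
    crossing_quads: set[str] = set()
    for cid, poly in tree.root_to_end_chains():
        r = np.linalg.norm(poly, axis=1)
        if r.min() < grid.r_central and r.max() > grid.r_outer:
            mid = poly[np.argmin(np.abs(r - 1750.0))]
            q = subfield_of(mid, grid)
            if q in QUADRANTS:
                crossing_quads.add(q)
    if crossing_quads != set(QUADRANTS):
        return False, f"quadrants without a through-going radial vessel: {set(QUADRANTS) - crossing_quads}"
    counts = {q: 0 for q in QUADRANTS}
    idx = {n.node_id: n for n in tree.nodes}
    for nid in tree.branch_labels:
        p = idx[nid].position
        d = float(np.linalg.norm(p))
        if grid.r_central < d <= grid.r_outer:
            q = subfield_of(p, grid)
            if q in counts:
                counts[q] += 1
    for q in FBL_QUADRANTS:
        if counts[q] < 5:
            return False, f"only {counts[q]} branch points in {q} quadrant (need >= 5)"
    return True, ""


# ---------------------------------------------------------------------------
# Contraction model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContractionField:
    """Tangential ERM traction as a smooth point map of the retinal plane.

    Every point p moves inward along the fovea direction by
    ``amplitude · r · exp(−r²/(2·sigma_r²))`` (zero at the foveola,
    vanishing far away), scaled down toward ``nasal_attenuation`` on the
    nasal half and pinned to zero at the optic disc.  A tangential sinusoid
    of amplitude ``wrinkle_amp_um`` and frequency ``wrinkle_freq_per_mm``
    adds the surface wrinkling that makes contracted vessels tortuous.
    """

    amplitude: float
    sigma_r_um: float = 1500.0
    wrinkle_amp_um: float = 0.0
    wrinkle_freq_per_mm: float = 3.0
    nasal_attenuation: float = 1.0
    disc_position_um: tuple[float, float] = (4500.0, 0.0)
    nasal_blend_um: float = 150.0
    disc_sigma_um: float = 600.0
    fovea_wrinkle_sigma_um: float = 250.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude <= 0.5):
            raise ValueError("amplitude must be in [0, 0.5]")
        if self.sigma_r_um <= 0:
            raise ValueError("sigma_r_um must be > 0")
        if self.wrinkle_amp_um < 0:
            raise ValueError("wrinkle_amp_um must be >= 0")
        if not (0.0 <= self.nasal_attenuation <= 1.0):
            raise ValueError("nasal_attenuation must be in [0, 1]")

    def _envelope(self, pts: np.ndarray) -> np.ndarray:
        """Anchoring envelope: ->0 at the disc, ->nasal_attenuation nasally."""
        disc = np.asarray(self.disc_position_um, dtype=float)
        dd = np.linalg.norm(pts - disc, axis=1)
        disc_env = 1.0 - np.exp(-(dd**2) / (2.0 * self.disc_sigma_um**2))
        nasal_dir = disc / max(np.linalg.norm(disc), 1e-9)
        xn = pts @ nasal_dir
        from scipy.special import expit

        nasal_mult = 1.0 + (self.nasal_attenuation - 1.0) * expit(xn / self.nasal_blend_um)
        return disc_env * nasal_mult

    def warp(self, pts: np.ndarray, phase: float = 0.0) -> np.ndarray:
        """Apply the contraction map to an (N, 2) array of μm points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        r = np.linalg.norm(pts, axis=1)
        safe_r = np.where(r > 0, r, 1.0)
        rhat = pts / safe_r[:, None]
        mag = self.amplitude * r * np.exp(-(r**2) / (2.0 * self.sigma_r_um**2))
        d = mag * self._envelope(pts)
        q = pts - (d * (r > 0))[:, None] * rhat

        if self.wrinkle_amp_um > 0:
            rq = np.linalg.norm(q, axis=1)
            safe_rq = np.where(rq > 0, rq, 1.0)
            tau = np.stack([-q[:, 1], q[:, 0]], axis=1) / safe_rq[:, None]
            fov_env = 1.0 - np.exp(-(rq**2) / (2.0 * self.fovea_wrinkle_sigma_um**2))
            k = 2.0 * math.pi * self.wrinkle_freq_per_mm / 1000.0  # rad/μm
            h = self.wrinkle_amp_um * np.sin(k * rq + phase) * fov_env * self._envelope(q)
            q = q + (h * (rq > 0))[:, None] * tau
        return q

    def displacement(self, pts: np.ndarray, phase: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.warp(pts, phase) - pts


def apply_contraction(tree: VesselTree, cfield: ContractionField, seed: int = 0) -> VesselTree:
    """Deformed copy of *tree* under the contraction field.

    Node positions, edge polylines and branch labels all map under the same
    smooth point map, so topology and cross-visit correspondence are
    preserved.  The wrinkle phase is drawn once from ``seed``.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    nodes = [
        TreeNode(n.node_id, cfield.warp(n.position[None, :], phase)[0], n.role) for n in tree.nodes
    ]
    edges = []
    for e in tree.edges:
        poly = cfield.warp(np.asarray(e.polyline, dtype=float), phase)
        keep = np.ones(len(poly), bool)
        keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-9
        edges.append(TreeEdge(e.edge_id, e.kind, poly[keep], e.caliber_um, e.u, e.v))
    return VesselTree(nodes, edges, dict(tree.branch_labels), laterality=tree.laterality)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class FundusImage:
    """Grayscale infrared-style fundus raster with its physical scale and
    the marked foveola pixel (row, col)."""

    pixels: np.ndarray
    scale_um_per_px: float
    foveola_px: tuple[int, int]
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be > 0")
        rows, cols = self.pixels.shape
        fr, fc = self.foveola_px
        if not (0 <= fr < rows and 0 <= fc < cols):
            raise ValueError("foveola_px must lie inside the raster")

    def um_to_px(self, pts_um: np.ndarray) -> np.ndarray:
        """(x, y) μm -> (row, col) float pixels."""
        pts_um = np.atleast_2d(np.asarray(pts_um, dtype=float))
        fr, fc = self.foveola_px
        col = fc + pts_um[:, 0] / self.scale_um_per_px
        row = fr - pts_um[:, 1] / self.scale_um_per_px
        return np.stack([row, col], axis=1)


def _resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length steps (vertices kept)."""
    poly = np.asarray(poly, dtype=float)
    seg = np.diff(poly, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    total = cum[-1]
    if total == 0:
        return poly[:1]
    n = max(int(math.ceil(total / step)), 1)
    s = np.union1d(np.linspace(0.0, total, n + 1), cum)
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.stack([x, y], axis=1)


def render_fundus(
    tree: VesselTree,
    scale_um_per_px: float = 11.7,
    size_px: tuple[int, int] = (768, 768),
    noise_sd: float = 0.0,
    seed: int = 0,
    foveola_px: tuple[int, int] | None = None,
    background_level: float = 178.0,
    vessel_depth: float = 92.0,
) -> FundusImage:
    """Render dark vessels on a brighter background with a smooth
    illumination gradient and (optionally) additive Gaussian noise.

    Vessel bands are built from an exact Euclidean distance transform of
    the rasterised centerlines, so the band's medial axis tracks the true
    polyline to sub-pixel accuracy.  Deterministic for a fixed seed.
    """
    rows, cols = size_px
    if foveola_px is None:
        foveola_px = (rows // 2, cols // 2)
    fr, fc = foveola_px
    ring_px = 3000.0 / scale_um_per_px
    if min(fr, rows - 1 - fr, fc, cols - 1 - fc) < ring_px + 2:
        raise ValueError(
            f"raster too small: the 6 mm ring (radius {ring_px:.0f} px) must fit "
            f"around foveola_px {foveola_px} in a {size_px} image"
        )

    img = FundusImage(np.zeros(size_px, dtype=np.uint8), scale_um_per_px, foveola_px,
                      laterality=tree.laterality)

    depth_map = np.zeros(size_px, dtype=float)
    by_caliber: dict[float, list[TreeEdge]] = {}
    for e in tree.edges:
        by_caliber.setdefault(round(e.caliber_um, 3), []).append(e)
    for caliber, edges in sorted(by_caliber.items()):
        mask = np.zeros(size_px, dtype=bool)
        for e in edges:
            pts = _resample_polyline(e.polyline, 0.4 * scale_um_per_px)
            rc = np.rint(img.um_to_px(pts)).astype(int)
            ok = (rc[:, 0] >= 0) & (rc[:, 0] < rows) & (rc[:, 1] >= 0) & (rc[:, 1] < cols)
            mask[rc[ok, 0], rc[ok, 1]] = True
        if not mask.any():
            continue
        dist = ndimage.distance_transform_edt(~mask)
        half_w = caliber / (2.0 * scale_um_per_px)
        prof = np.clip((half_w + 0.6 - dist) / 1.2, 0.0, 1.0)
        np.maximum(depth_map, prof, out=depth_map)

    rr, cc = np.mgrid[0:rows, 0:cols]
    background = background_level + 10.0 * (cc / cols - 0.5) + 6.0 * (rr / rows - 0.5)
    out = background - vessel_depth * depth_map
    if noise_sd > 0:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        out = out + rng.normal(0.0, noise_sd, size_px)
    img.pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# Analytic ground truth (oracle twin of the image-based metrics)
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthMetrics:
    """True VLA/FBL computed on the polylines themselves by dense
    resampling — the independent oracle for image-based measurements."""

    vla: dict[str, QuadrantVLA]
    fbl: dict[str, FBLResult]
    branch_points: list[BranchPoint]


def ground_truth_metrics(
    tree: VesselTree,
    grid: ETDRSGrid | None = None,
    resample_um: float = 2.0,
    angle_tol_deg: float = 30.0,
    min_vessels: int = 3,
    max_vessels: int = 5,
) -> GroundTruthMetrics:
    """Per-quadrant VLA and superior/inferior FBL from the vessel polylines.

    Clipping to the 1–6 mm annulus is brute-force: each chain is resampled
    at ``resample_um`` steps and tiny segments are kept when their midpoint
    radius lies in the annulus — deliberately a different code path from
    the exact-intersection clipping used by the measurement module, so the
    two can check each other.  Selection semantics (radial filter, quadrant
    of the clipped midpoint, top-5 by length, 3–5 vessel rule, five nearest
    branch points) mirror the measurement definitions.
    """
    grid = grid or ETDRSGrid(laterality=tree.laterality)
    candidates: dict[str, list[tuple[float, str]]] = {q: [] for q in QUADRANTS}
    for chain_id, poly in tree.root_to_end_chains():
        pts = _resample_polyline(poly, resample_um)
        if len(pts) < 2:
            continue
        seg = np.diff(pts, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        mid = 0.5 * (pts[:-1] + pts[1:])
        rm = np.linalg.norm(mid, axis=1)
        inside = (rm >= grid.r_central) & (rm <= grid.r_outer) & (lens > 0)
        if not inside.any():
            continue
        clip_len = float(lens[inside].sum())
        if clip_len <= 0:
            continue
        # arc-length midpoint of the clipped portion
        cum = np.cumsum(lens * inside)
        j = int(np.searchsorted(cum, clip_len / 2.0))
        quad = subfield_of(mid[min(j, len(mid) - 1)], grid)
        if quad not in QUADRANTS:
            continue
        u = mid[inside] / rm[inside, None]
        v = seg[inside] / lens[inside, None]
        ang = np.degrees(np.arccos(np.clip(np.sum(u * v, axis=1), -1.0, 1.0)))
        dev = float((ang * lens[inside]).sum() / clip_len)
        if dev > angle_tol_deg:
            continue
        candidates[quad].append((clip_len, str(chain_id)))

    vla: dict[str, QuadrantVLA] = {}
    for quad in QUADRANTS:
        cand = sorted(candidates[quad], key=lambda lc: (-lc[0], lc[1]))[:max_vessels]
        lengths = tuple(l for l, _ in cand)
        if len(cand) < min_vessels:
            vla[quad] = QuadrantVLA(None, len(cand), lengths, missing=True,
                                    note=f"only {len(cand)} radial candidate(s)")
        else:
            vla[quad] = QuadrantVLA(float(np.mean(lengths)), len(cand), lengths)

    # exact branch-point distances
    bps: list[tuple[float, float, BranchPoint]] = []
    tx, ty = grid.temporal_axis
    t_ang = math.atan2(ty, tx)
    for label, (x, y) in tree.branch_points():
        d = math.hypot(x, y)
        if d <= grid.r_central or d > grid.r_outer:
            continue
        ang = (math.atan2(y, x) - t_ang) % (2.0 * math.pi)
        bps.append((d, ang, BranchPoint(label, (x, y), d, subfield_of((x, y), grid))))
    bps.sort(key=lambda t: (t[0], t[1], t[2].label))
    points = [bp for _, _, bp in bps]
    fbl = {q: compute_fbl(points, q) for q in FBL_QUADRANTS}
    return GroundTruthMetrics(vla=vla, fbl=fbl, branch_points=points)


def subfield_contraction_index(
    cfield: ContractionField, grid: ETDRSGrid, spacing_um: float = 100.0,
    central_margin_um: float = 750.0,
) -> dict[str, float]:
    """Mean displacement magnitude (μm) of the contraction field over each
    subfield — the mechanical dose that drives subfield thickening.

    The central subfield's dose is taken over the perifoveal margin
    (``r <= central_margin_um``) rather than the 0.5 mm disc alone: the
    displacement vanishes at the foveola by symmetry, but the tissue that
    piles up centrally is the surrounding material drawn inward, so the
    margin's displacement is the physically relevant dose for central
    thickening."""
    ax = np.arange(-grid.r_outer, grid.r_outer + spacing_um / 2, spacing_um)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    r = np.linalg.norm(pts, axis=1)
    pts, r = pts[r <= grid.r_outer], r[r <= grid.r_outer]
    labels = subfield_of_points(pts, grid)
    disp = np.linalg.norm(cfield.displacement(pts), axis=1)
    out = {s: float(disp[labels == s].mean()) for s in SUBFIELDS}
    out["central"] = float(disp[r <= central_margin_um].mean())
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-visit ground truth: true vessel metrics plus the OCT thickness
    table (μm per subfield) and BCVA (logMAR)."""

    metrics: GroundTruthMetrics
    mt_um: dict[str, float]
    bcva_logmar: float

    def validate(self) -> None:
        for q, res in self.fbl_items():
            if not res.missing and abs(res.sum_um - sum(res.distances_um)) > 1e-6:
                raise ValueError(f"FBL sum inconsistent in {q}")
        for s, v in self.mt_um.items():
            if not (150.0 <= v <= 800.0):
                raise ValueError(f"thickness {v} μm in {s} outside [150, 800]")

    def fbl_items(self):
        return self.metrics.fbl.items()


@dataclass(frozen=True)
class EffectModel:
    """Linear-plus-noise link from contraction dose to thickness and BCVA.

    Pre-op subfield thickness = baseline + ``mt_slope_um_per_um`` × (mean
    displacement magnitude in the subfield) + noise; post-op = baseline +
    residual noise.  Pre-op BCVA (logMAR) = post-op + ``bcva_slope`` ×
    amplitude + noise, so vision is worse before surgery on average.
    """

    mt_base_mean_um: float = 290.0
    mt_base_sd_um: float = 25.0
    mt_slope_um_per_um: float = 0.55
    mt_noise_sd_um: float = 10.0
    bcva_post_mean: float = 0.08
    bcva_post_sd: float = 0.05
    bcva_slope_per_amplitude: float = 1.3
    bcva_noise_sd: float = 0.05


@dataclass
class SimulatedEye:
    eye_id: str
    laterality: str
    amplitude: float
    cfield: ContractionField
    pre_tree: VesselTree
    post_tree: VesselTree
    truth_pre: GroundTruth
    truth_post: GroundTruth


def simulate_eye(
    eye_index: int,
    seed: int,
    amplitude_range: tuple[float, float] = (0.05, 0.3),
    arcades: int = 8,
    branch_depth: int = 3,
    effect: EffectModel | None = None,
    nasal_attenuation: float = 0.3,
    wrinkle_gain_um: float = 170.0,
    sigma_r_um: float = 1500.0,
    wrinkle_freq_per_mm: float = 3.0,
    compute_truth: bool = True,
) -> SimulatedEye:
    """Simulate one eye: a vessel tree, an ERM contraction of random
    amplitude (the pre-operative state), the released post-operative state
    (identity — surgery removes all traction), and ground truth."""
    effect = effect or EffectModel()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, eye_index])
    laterality = "OD" if eye_index % 2 == 0 else "OS"
    disc_x = 4500.0 if laterality == "OD" else -4500.0
    lo, hi = amplitude_range
    amplitude = float(rng.uniform(lo, hi))
    cfield = ContractionField(
        amplitude=amplitude,
        sigma_r_um=sigma_r_um,
        wrinkle_amp_um=wrinkle_gain_um * amplitude,
        wrinkle_freq_per_mm=wrinkle_freq_per_mm,
        nasal_attenuation=nasal_attenuation,
        disc_position_um=(disc_x, 0.0),
    )
    tree = generate_vessel_tree(
        arcades, branch_depth, seed=int(rng.integers(2**31)), laterality=laterality
    )
    pre_tree = apply_contraction(tree, cfield, seed=int(rng.integers(2**31)))
    post_tree = tree
    grid = ETDRSGrid(laterality=laterality)

    idx = subfield_contraction_index(cfield, grid)
    base = {s: float(rng.normal(effect.mt_base_mean_um, effect.mt_base_sd_um)) for s in SUBFIELDS}
    mt_post = {
        s: float(np.clip(base[s] + rng.normal(0.0, effect.mt_noise_sd_um), 150.0, 800.0))
        for s in SUBFIELDS
    }
    mt_pre = {
        s: float(
            np.clip(
                base[s] + effect.mt_slope_um_per_um * idx[s] + rng.normal(0.0, effect.mt_noise_sd_um),
                150.0,
                800.0,
            )
        )
        for s in SUBFIELDS
    }
    bcva_post = float(np.clip(rng.normal(effect.bcva_post_mean, effect.bcva_post_sd), 0.0, 2.0))
    bcva_pre = float(
        np.clip(
            bcva_post + effect.bcva_slope_per_amplitude * amplitude + rng.normal(0.0, effect.bcva_noise_sd),
            0.0,
            2.5,
        )
    )

    if compute_truth:
        truth_pre = GroundTruth(ground_truth_metrics(pre_tree, grid), mt_pre, bcva_pre)
        truth_post = GroundTruth(ground_truth_metrics(post_tree, grid), mt_post, bcva_post)
        truth_pre.validate()
        truth_post.validate()
    else:
        empty = GroundTruthMetrics({}, {}, [])
        truth_pre = GroundTruth(empty, mt_pre, bcva_pre)
        truth_post = GroundTruth(empty, mt_post, bcva_post)
    return SimulatedEye(
        eye_id=f"eye{eye_index:02d}",
        laterality=laterality,
        amplitude=amplitude,
        cfield=cfield,
        pre_tree=pre_tree,
        post_tree=post_tree,
        truth_pre=truth_pre,
        truth_post=truth_post,
    )


def generate_cohort(
    outdir: str | Path,
    n_eyes: int = 16,
    amplitude_range: tuple[float, float] = (0.05, 0.3),
    seed: int = 0,
    render: bool = True,
    noise_sd: float = 3.0,
    scale_um_per_px: float = 11.7,
    size_px: tuple[int, int] = (768, 768),
    arcades: int = 8,
    branch_depth: int = 3,
    effect: EffectModel | None = None,
    nasal_attenuation: float = 0.3,
) -> Path:
    """Write a paired pre/post cohort to ``outdir`` and return the manifest path.

    Per eye: pre (contracted) and post (released) images with sidecar
    metadata, vessel-tree JSON, ground-truth JSON for both visits, and a
    thickness table; plus one ``manifest.csv`` row per eye.
    """
    from . import io as _io  # local import: io depends on the types above
    import pandas as pd

    if n_eyes < 2:
        raise ValueError("n_eyes must be >= 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_eyes):
        eye = simulate_eye(
            i, seed, amplitude_range, arcades, branch_depth, effect,
            nasal_attenuation=nasal_attenuation,
        )
        row: dict[str, object] = {
            "eye_id": eye.eye_id,
            "laterality": eye.laterality,
            "amplitude": eye.amplitude,
            "wrinkle_amp_um": eye.cfield.wrinkle_amp_um,
            "bcva_pre": eye.truth_pre.bcva_logmar,
            "bcva_post": eye.truth_post.bcva_logmar,
        }
        for visit, tree, truth in (
            ("pre", eye.pre_tree, eye.truth_pre),
            ("post", eye.post_tree, eye.truth_post),
        ):
            tree_path = outdir / f"{eye.eye_id}_{visit}_tree.json"
            _io.save_vessel_tree(tree, tree_path)
            truth_path = outdir / f"{eye.eye_id}_{visit}_truth.json"
            _io.save_ground_truth(truth, truth_path)
            row[f"tree_{visit}"] = tree_path.name
            row[f"truth_{visit}"] = truth_path.name
            if render:
                img = render_fundus(
                    tree, scale_um_per_px, size_px, noise_sd=noise_sd,
                    seed=int(np.random.default_rng([seed & 0x7FFFFFFF, i, 0 if visit == "pre" else 1]).integers(2**31)),
                )
                img_path = outdir / f"{eye.eye_id}_{visit}.png"
                _io.save_fundus_image(img, img_path, visit=visit)
                row[f"image_{visit}"] = img_path.name
        mt_path = outdir / f"{eye.eye_id}_mt.csv"
        pd.DataFrame(
            {
                "subfield": list(SUBFIELDS),
                "mt_pre_um": [eye.truth_pre.mt_um[s] for s in SUBFIELDS],
                "mt_post_um": [eye.truth_post.mt_um[s] for s in SUBFIELDS],
            }
        ).to_csv(mt_path, index=False)
        row["mt_table"] = mt_path.name
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
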