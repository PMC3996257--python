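"""File formats: JSON schemas for trees/graphs/ground truth, PNG images
with sidecar metadata, and the flat cohort CSV.

All JSON payloads carry a ``schema_version`` field; parse→serialize→parse
is the identity for every artifact.  Schema violations raise
:class:`SchemaError` naming the offending field path.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .grid_metrics import (
    FBL_QUADRANTS,
    QUADRANTS,
    SUBFIELDS,
    EyeVisitPair,
    FBLResult,
    QuadrantVLA,
    SubfieldMetrics,
)
from .synthetic_fundus import (
    FundusImage,
    GroundTruth,
    GroundTruthMetrics,
    TreeEdge,
    TreeNode,
    VesselTree,
)
from .vessel_extraction import GraphEdge, GraphNode, VesselGraph
from .grid_metrics import BranchPoint

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "save_vessel_tree",
    "load_vessel_tree",
    "save_vessel_graph",
    "load_vessel_graph",
    "save_fundus_image",
    "load_fundus_image",
    "save_ground_truth",
    "load_ground_truth",
    "save_cohort_csv",
    "load_cohort_csv",
]


class SchemaError(ValueError):
    pass


def _np_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _req(d: dict, key: str, path: str) -> Any:
    if not isinstance(d, dict) or key not in d:
        raise SchemaError(f"missing required field '{path}.{key}'")
    return d[key]


def _load_json(path: str | Path, kind: str) -> dict:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    if _req(data, "kind", str(path)) != kind:
        raise SchemaError(f"{path}: expected kind '{kind}', got {data.get('kind')!r}")
    _req(data, "schema_version", str(path))
    return data


# ---------------------------------------------------------------------------
# VesselTree
# ---------------------------------------------------------------------------


def save_vessel_tree(tree: VesselTree, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "vessel_tree",
        "laterality": tree.laterality,
        "nodes": [
            {"id": n.node_id, "position_um": [float(n.position[0]), float(n.position[1])],
             "role": n.role}
            for n in tree.nodes
        ],
        "edges": [
            {
                "id": e.edge_id,
                "kind": e.kind,
                "caliber_um": e.caliber_um,
                "u": e.u,
                "v": e.v,
                "polyline_um": np.asarray(e.polyline, dtype=float).tolist(),
            }
            for e in tree.edges
        ],
        "branch_labels": {str(k): v for k, v in tree.branch_labels.items()},
    }
    Path(path).write_text(json.dumps(payload, default=_np_default))


def load_vessel_tree(path: str | Path) -> VesselTree:
    data = _load_json(path, "vessel_tree")
    nodes = [
        TreeNode(int(_req(n, "id", "nodes[]")), np.array(_req(n, "position_um", "nodes[]"), float),
                 _req(n, "role", "nodes[]"))
        for n in _req(data, "nodes", "tree")
    ]
    edges = [
        TreeEdge(
            int(_req(e, "id", "edges[]")),
            _req(e, "kind", "edges[]"),
            np.array(_req(e, "polyline_um", "edges[]"), float),
            float(_req(e, "caliber_um", "edges[]")),
            int(_req(e, "u", "edges[]")),
            int(_req(e, "v", "edges[]")),
        )
        for e in _req(data, "edges", "tree")
    ]
    labels = {int(k): str(v) for k, v in _req(data, "branch_labels", "tree").items()}
    return VesselTree(nodes, edges, labels, laterality=_req(data, "laterality", "tree"))


# ---------------------------------------------------------------------------
# VesselGraph
# ---------------------------------------------------------------------------


def save_vessel_graph(graph: VesselGraph, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "vessel_graph",
        "scale_um_per_px": graph.scale_um_per_px,
        "foveola_px": [float(graph.foveola_px[0]), float(graph.foveola_px[1])],
        "laterality": graph.laterality,
        "nodes": [
            {"id": nid, "pos_px": [float(n.pos_px[0]), float(n.pos_px[1])], "role": n.role}
            for nid, n in sorted(graph.nodes.items())
        ],
        "edges": [
            {"id": e.edge_id, "u": e.u, "v": e.v, "chain_px": e.chain_px.tolist()}
            for e in graph.edges
        ],
    }
    Path(path).write_text(json.dumps(payload, default=_np_default))


def load_vessel_graph(path: str | Path) -> VesselGraph:
    data = _load_json(path, "vessel_graph")
    nodes = {
        int(_req(n, "id", "nodes[]")): GraphNode(
            int(n["id"]), np.array(_req(n, "pos_px", "nodes[]"), float), _req(n, "role", "nodes[]")
        )
        for n in _req(data, "nodes", "graph")
    }
    edges = [
        GraphEdge(
            int(_req(e, "id", "edges[]")),
            int(_req(e, "u", "edges[]")),
            int(_req(e, "v", "edges[]")),
            np.array(_req(e, "chain_px", "edges[]"), int),
        )
        for e in _req(data, "edges", "graph")
    ]
    fov = _req(data, "foveola_px", "graph")
    return VesselGraph(
        nodes,
        edges,
        float(_req(data, "scale_um_per_px", "graph")),
        (fov[0], fov[1]),
        _req(data, "laterality", "graph"),
    )


# ---------------------------------------------------------------------------
# Images (PNG + sidecar JSON)
# ---------------------------------------------------------------------------


def save_fundus_image(image: FundusImage, path: str | Path, visit: str = "") -> None:
    path = Path(path)
    Image.fromarray(image.pixels).save(path)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "kind": "fundus_image_meta",
        "scale_um_per_px": image.scale_um_per_px,
        "foveola_px": [int(image.foveola_px[0]), int(image.foveola_px[1])],
        "laterality": image.laterality,
        "visit": visit,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, default=_np_default))


def load_fundus_image(path: str | Path) -> FundusImage:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar metadata {sidecar_path} (foveola/scale required)")
    meta = _load_json(sidecar_path, "fundus_image_meta")
    pixels = np.asarray(Image.open(path).convert("L"))
    fov = _req(meta, "foveola_px", "image_meta")
    return FundusImage(
        pixels,
        float(_req(meta, "scale_um_per_px", "image_meta")),
        (int(fov[0]), int(fov[1])),
        _req(meta, "laterality", "image_meta"),
    )


# ---------------------------------------------------------------------------
# GroundTruth
# ---------------------------------------------------------------------------


def _vla_to_json(v: QuadrantVLA) -> dict:
    return {
        "mean_um": v.mean_um, "n": v.n, "lengths_um": list(v.lengths_um),
        "missing": v.missing, "note": v.note,
    }


def _vla_from_json(d: dict, path: str) -> QuadrantVLA:
    return QuadrantVLA(
        d.get("mean_um"), int(_req(d, "n", path)), tuple(_req(d, "lengths_um", path)),
        bool(d.get("missing", False)), d.get("note", ""),
    )


def _fbl_to_json(f: FBLResult) -> dict:
    return {
        "sum_um": f.sum_um, "distances_um": list(f.distances_um), "labels": list(f.labels),
        "missing": f.missing, "note": f.note,
    }


def _fbl_from_json(d: dict, path: str) -> FBLResult:
    return FBLResult(
        d.get("sum_um"), tuple(_req(d, "distances_um", path)), tuple(_req(d, "labels", path)),
        bool(d.get("missing", False)), d.get("note", ""),
    )


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    m = truth.metrics
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "ground_truth",
        "vla": {q: _vla_to_json(v) for q, v in m.vla.items()},
        "fbl": {q: _fbl_to_json(f) for q, f in m.fbl.items()},
        "branch_points": [
            {"label": b.label, "position_um": list(b.position_um),
             "distance_um": b.distance_um, "quadrant": b.quadrant}
            for b in m.branch_points
        ],
        "mt_um": truth.mt_um,
        "bcva_logmar": truth.bcva_logmar,
    }
    Path(path).write_text(json.dumps(payload, default=_np_default))


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = _load_json(path, "ground_truth")
    vla = {q: _vla_from_json(v, f"vla.{q}") for q, v in _req(data, "vla", "truth").items()}
    fbl = {q: _fbl_from_json(f, f"fbl.{q}") for q, f in _req(data, "fbl", "truth").items()}
    bps = [
        BranchPoint(
            _req(b, "label", "branch_points[]"),
            tuple(_req(b, "position_um", "branch_points[]")),
            float(_req(b, "distance_um", "branch_points[]")),
            _req(b, "quadrant", "branch_points[]"),
        )
        for b in _req(data, "branch_points", "truth")
    ]
    return GroundTruth(
        GroundTruthMetrics(vla, fbl, bps),
        {k: float(v) for k, v in _req(data, "mt_um", "truth").items()},
        float(_req(data, "bcva_logmar", "truth")),
    )


# ---------------------------------------------------------------------------
# Cohort CSV (one row per eye; the analysis input)
# ---------------------------------------------------------------------------


def _pair_row(p: EyeVisitPair) -> dict:
    row: dict[str, Any] = {
        "eye_id": p.eye_id,
        "laterality": p.laterality,
        "bcva_pre": p.bcva_pre,
        "bcva_post": p.bcva_post,
    }
    for q in QUADRANTS:
        row[f"vla_pre_{q}"] = p.pre.vla_value(q)
        row[f"vla_post_{q}"] = p.post.vla_value(q)
        vq_pre, vq_post = p.pre.vla.get(q), p.post.vla.get(q)
        row[f"vla_n_pre_{q}"] = vq_pre.n if vq_pre else 0
        row[f"vla_n_post_{q}"] = vq_post.n if vq_post else 0
    for q in FBL_QUADRANTS:
        row[f"fbl_pre_{q}"] = p.pre.fbl_value(q)
        row[f"fbl_post_{q}"] = p.post.fbl_value(q)
    for s in SUBFIELDS:
        row[f"mt_pre_{s}"] = p.pre.mt_value(s)
        row[f"mt_post_{s}"] = p.post.mt_value(s)
    return row


def save_cohort_csv(cohort: Sequence[EyeVisitPair], path: str | Path) -> None:
    pd.DataFrame([_pair_row(p) for p in cohort]).to_csv(path, index=False)


def _nan_none(v) -> float | None:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def load_cohort_csv(path: str | Path) -> list[EyeVisitPair]:
    df = pd.read_csv(path)
    required = {"eye_id", "bcva_pre", "bcva_post"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"cohort CSV missing column(s): {sorted(missing)}")
    cohort: list[EyeVisitPair] = []
    for _, r in df.iterrows():
        metrics = {}
        for visit in ("pre", "post"):
            vla = {}
            for q in QUADRANTS:
                mean = _nan_none(r.get(f"vla_{visit}_{q}"))
                n = int(r.get(f"vla_n_{visit}_{q}", 0) or 0)
                vla[q] = QuadrantVLA(mean, n, (), missing=mean is None)
            fbl = {
                q: FBLResult(v := _nan_none(r.get(f"fbl_{visit}_{q}")), (), (), missing=v is None)
                for q in FBL_QUADRANTS
            }
            mt = {s: _nan_none(r.get(f"mt_{visit}_{s}")) for s in SUBFIELDS}
            metrics[visit] = SubfieldMetrics(visit=visit, vla=vla, fbl=fbl, mt=mt)
        cohort.append(
            EyeVisitPair(
                eye_id=str(r["eye_id"]),
                pre=metrics["pre"],
                post=metrics["post"],
                bcva_pre=_nan_none(r["bcva_pre"]),
                bcva_post=_nan_none(r["bcva_post"]),
                laterality=str(r.get("laterality", "OD")),
            )
        )
    return cohort
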