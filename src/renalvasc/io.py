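"""Readers and writers for every artifact boundary.

Coordinates are always serialized in μm world units, never voxel
indices, so files from different stages can be combined without unit
drift.  Formats:

* volumetric masks — NIfTI (via nibabel) and NRRD (via SimpleITK);
  anisotropic voxel spacing is rejected because the whole pipeline
  assumes isotropic voxels;
* trees — a lossless documented JSON dialect (native), GraphML, SWC
  (lossy: topology + radius only), and legacy-VTK polydata polylines
  with per-vessel radius/flow/pressure/order scalars;
* centerline graphs — GraphML and the JSON dialect;
* point sets — CSV (x,y,z μm) and JSON with r_min/seed metadata;
* per-iteration cost logs and per-order stats — CSV via pandas.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .imageprior import VoxelMask
from .sampling import PointSet
from .tree import VascularTree, TreeError

__all__ = [
    "read_mask",
    "write_mask",
    "export_tree",
    "import_tree",
    "write_centerline",
    "read_centerline",
    "write_pointset",
    "read_pointset",
    "sha256_of",
]

_ISO_RTOL = 1e-4


def _check_isotropic(spacing) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=_ISO_RTOL):
        raise ValueError(f"anisotropic voxel spacing {tuple(spacing)} not supported")
    return float(spacing[0])


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        affine = np.diag([mask.voxel_size] * 3 + [1.0])
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine), str(path))
    elif path.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(mask.grid.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing([mask.voxel_size] * 3)
        img.SetOrigin(list(mask.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown mask format {path.suffix!r} (use .nii/.nii.gz/.nrrd)")


def read_mask(path: str | Path) -> VoxelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        vs = _check_isotropic(spacing)
        return VoxelMask(np.asanyarray(img.dataobj) > 0, vs, affine[:3, 3])
    if path.suffix == ".nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        vs = _check_isotropic(img.GetSpacing())
        grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0) > 0
        return VoxelMask(grid, vs, np.asarray(img.GetOrigin()))
    raise ValueError(f"unknown mask format {path.suffix!r}")


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
def _tree_to_records(tree: VascularTree) -> dict:
    nodes = []
    for v in tree.nodes():
        d = tree.graph.nodes[v]
        rec = {
            "id": int(v),
            "x": float(d["position"][0]),
            "y": float(d["position"][1]),
            "z": float(d["position"][2]),
            "role": tree.role(v),
        }
        for key in ("subtree_label", "leaf_radius", "radius"):
            if key in d and d[key] is not None:
                rec[key] = float(d[key]) if key != "subtree_label" else int(d[key])
        nodes.append(rec)
    vessels = []
    for u, v in tree.vessels():
        e = tree.graph.edges[u, v]
        rec = {"parent": int(u), "child": int(v)}
        for key in ("radius", "flow"):
            if key in e:
                rec[key] = float(e[key])
        vessels.append(rec)
    return {"root": int(tree.root), "nodes": nodes, "vessels": vessels}


def _tree_from_records(doc: dict) -> VascularTree:
    g = nx.DiGraph()
    for rec in doc["nodes"]:
        attrs = {"position": np.array([rec["x"], rec["y"], rec["z"]])}
        if rec.get("role") == "prebuilt":
            attrs["prebuilt"] = True
        for key in ("subtree_label", "leaf_radius", "radius"):
            if key in rec:
                attrs[key] = rec[key]
        g.add_node(int(rec["id"]), **attrs)
    for rec in doc["vessels"]:
        attrs = {k: rec[k] for k in ("radius", "flow") if k in rec}
        g.add_edge(int(rec["parent"]), int(rec["child"]), **attrs)
    return VascularTree(g, int(doc["root"]))


def _write_swc(tree: VascularTree, path: Path) -> None:
    # SWC: id type x y z radius parent; radius = parent-vessel radius
    # (the root uses its thickest outgoing vessel). Flow is not stored.
    lines = ["# generated by renalvasc; coordinates in um"]
    for v in sorted(tree.nodes()):
        p = tree.parent(v)
        if p is None:
            radii = [
                tree.graph.edges[v, c].get("radius", 0.0) for c in tree.children(v)
            ]
            r = max(radii) if radii else 0.0
        else:
            r = tree.graph.edges[p, v].get("radius", 0.0)
        x, y, z = tree.position(v)
        swc_type = 1 if p is None else 2
        lines.append(
            f"{v + 1} {swc_type} {x:.6g} {y:.6g} {z:.6g} {r:.6g} {(p + 1) if p is not None else -1}"
        )
    path.write_text("\n".join(lines) + "\n")


def _read_swc(path: Path) -> VascularTree:
    g = nx.DiGraph()
    edges = []
    root = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, _t, x, y, z, r, parent = line.split()
        v = int(sid) - 1
        g.add_node(v, position=np.array([float(x), float(y), float(z)]))
        if int(parent) == -1:
            root = v
        else:
            edges.append((int(parent) - 1, v, float(r)))
    for u, v, r in edges:
        g.add_edge(u, v, radius=r)
    if root is None:
        raise TreeError("SWC file has no root sample")
    return VascularTree(g, root)


def _write_vtk(tree: VascularTree, path: Path, pressures=None, orders=None) -> None:
    ids = sorted(tree.nodes())
    idx = {v: i for i, v in enumerate(ids)}
    edges = sorted(tree.vessels())
    out = [
        "# vtk DataFile Version 3.0",
        "vascular tree polylines (um)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(ids)} float",
    ]
    for v in ids:
        x, y, z = tree.position(v)
        out.append(f"{x:.6g} {y:.6g} {z:.6g}")
    out.append(f"LINES {len(edges)} {3 * len(edges)}")
    for u, v in edges:
        out.append(f"2 {idx[u]} {idx[v]}")
    scalars = {
        "radius": [tree.graph.edges[e].get("radius", 0.0) for e in edges],
        "flow": [tree.graph.edges[e].get("flow", 0.0) for e in edges],
    }
    if pressures is not None:
        scalars["outlet_pressure_mmhg"] = [pressures.get(v, 0.0) for _, v in edges]
    if orders is not None:
        scalars["strahler_order"] = [orders.get(e, 0) for e in edges]
    out.append(f"CELL_DATA {len(edges)}")
    for name, vals in scalars.items():
        out.append(f"SCALARS {name} float 1")
        out.append("LOOKUP_TABLE default")
        out.extend(f"{val:.6g}" for val in vals)
    path.write_text("\n".join(out) + "\n")


def _read_vtk(path: Path) -> VascularTree:
    tokens = path.read_text().split("\n")
    it = iter(tokens)
    points: list[float] = []
    lines: list[tuple[int, int]] = []
    scalars: dict[str, list[float]] = {}
    n_points = n_lines = 0
    cur = next(it, None)
    while cur is not None:
        t = cur.split()
        if not t:
            cur = next(it, None)
            continue
        if t[0] == "POINTS":
            n_points = int(t[1])
            vals: list[float] = []
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in next(it).split())
            points = vals
        elif t[0] == "LINES":
            n_lines = int(t[1])
            for _ in range(n_lines):
                rec = next(it).split()
                lines.append((int(rec[1]), int(rec[2])))
        elif t[0] == "SCALARS":
            name = t[1]
            next(it)  # LOOKUP_TABLE
            vals = []
            while len(vals) < n_lines:
                vals.extend(float(x) for x in next(it).split())
            scalars[name] = vals
        cur = next(it, None)
    pts = np.asarray(points).reshape(-1, 3)
    g = nx.DiGraph()
    for i, p in enumerate(pts):
        g.add_node(i, position=p)
    children = {v for _, v in lines}
    for k, (u, v) in enumerate(lines):
        attrs = {}
        if "radius" in scalars:
            attrs["radius"] = scalars["radius"][k]
        if "flow" in scalars:
            attrs["flow"] = scalars["flow"][k]
        g.add_edge(u, v, **attrs)
    roots = [v for v in g.nodes if v not in children]
    if len(roots) != 1:
        raise TreeError(f"VTK polydata does not encode a rooted tree ({roots})")
    return VascularTree(g, roots[0])


def export_tree(
    tree: VascularTree,
    path: str | Path,
    format: str | None = None,
    pressures: dict[int, float] | None = None,
    orders: dict[tuple[int, int], int] | None = None,
) -> None:
    """Write a tree; format from the extension unless given explicitly."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt == "json":
        path.write_text(json.dumps(_tree_to_records(tree), indent=1))
    elif fmt == "graphml":
        g = nx.DiGraph()
        for v in tree.nodes():
            d = tree.graph.nodes[v]
            attrs = {
                "x": float(d["position"][0]),
                "y": float(d["position"][1]),
                "z": float(d["position"][2]),
                "role": tree.role(v),
            }
            for key in ("subtree_label", "leaf_radius", "radius"):
                if key in d and d[key] is not None:
                    attrs[key] = d[key]
            g.add_node(v, **attrs)
        for u, v in tree.vessels():
            g.add_edge(u, v, **{
                k: float(val)
                for k, val in tree.graph.edges[u, v].items()
                if isinstance(val, (int, float, np.floating))
            })
        g.graph["root"] = int(tree.root)
        nx.write_graphml(g, str(path))
    elif fmt == "swc":
        _write_swc(tree, path)
    elif fmt == "vtk":
        _write_vtk(tree, path, pressures=pressures, orders=orders)
    else:
        raise ValueError(f"unknown tree format {fmt!r}")


def import_tree(path: str | Path, format: str | None = None) -> VascularTree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt == "json":
        return _tree_from_records(json.loads(path.read_text()))
    if fmt == "graphml":
        raw = nx.read_graphml(str(path))
        g = nx.DiGraph()
        for v, d in raw.nodes(data=True):
            attrs = {"position": np.array([d["x"], d["y"], d["z"]])}
            if d.get("role") == "prebuilt":
                attrs["prebuilt"] = True
            for key in ("subtree_label", "leaf_radius", "radius"):
                if key in d:
                    attrs[key] = d[key]
            g.add_node(int(v), **attrs)
        for u, v, d in raw.edges(data=True):
            g.add_edge(int(u), int(v), **d)
        return VascularTree(g, int(raw.graph["root"]))
    if fmt == "swc":
        return _read_swc(path)
    if fmt == "vtk":
        return _read_vtk(path)
    raise ValueError(f"unknown tree format {fmt!r}")


# ----------------------------------------------------------------------
# centerline graphs / point sets / misc
# ----------------------------------------------------------------------
def write_centerline(graph: nx.Graph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.Graph()
        for v, d in graph.nodes(data=True):
            g.add_node(
                v,
                x=float(d["position"][0]),
                y=float(d["position"][1]),
                z=float(d["position"][2]),
                radius=float(d.get("radius", 0.0)),
            )
        g.add_edges_from(graph.edges)
        nx.write_graphml(g, str(path))
    elif path.suffix == ".json":
        doc = {
            "nodes": [
                {
                    "id": int(v),
                    "x": float(d["position"][0]),
                    "y": float(d["position"][1]),
                    "z": float(d["position"][2]),
                    "radius": float(d.get("radius", 0.0)),
                }
                for v, d in graph.nodes(data=True)
            ],
            "edges": [{"source": int(u), "target": int(v)} for u, v in graph.edges],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown centerline format {path.suffix!r}")


def read_centerline(path: str | Path) -> nx.Graph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    g = nx.Graph()
    if path.suffix == ".graphml":
        raw = nx.read_graphml(str(path))
        for v, d in raw.nodes(data=True):
            g.add_node(
                int(v),
                position=np.array([d["x"], d["y"], d["z"]]),
                radius=float(d.get("radius", 0.0)),
            )
        g.add_edges_from((int(u), int(v)) for u, v in raw.edges)
    elif path.suffix == ".json":
        doc = json.loads(path.read_text())
        for rec in doc["nodes"]:
            g.add_node(
                int(rec["id"]),
                position=np.array([rec["x"], rec["y"], rec["z"]]),
                radius=float(rec.get("radius", 0.0)),
            )
        g.add_edges_from((int(e["source"]), int(e["target"])) for e in doc["edges"])
    else:
        raise ValueError(f"unknown centerline format {path.suffix!r}")
    return g


def write_pointset(points: PointSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        pd.DataFrame(points.positions, columns=["x", "y", "z"]).to_csv(
            path, index=False
        )
    elif path.suffix == ".json":
        path.write_text(
            json.dumps(
                {
                    "r_min_um": points.r_min,
                    "seed": points.seed,
                    "positions": points.positions.tolist(),
                },
                indent=1,
            )
        )
    else:
        raise ValueError(f"unknown point-set format {path.suffix!r}")


def read_pointset(path: str | Path) -> PointSet:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        return PointSet(df[["x", "y", "z"]].to_numpy(), r_min=0.0, seed=-1)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        return PointSet(
            np.asarray(doc["positions"]), r_min=doc["r_min_um"], seed=doc["seed"]
        )
    raise ValueError(f"unknown point-set format {path.suffix!r}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
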