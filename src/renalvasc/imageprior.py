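"""Image priors: cortex-shell approximation and centerline preprocessing.

Two segmentation maps seed the reconstruction: the whole-organ mask Y_w
and the large-artery mask / centerline.  From Y_w a renal-cortex proxy
is carved out as a fixed-thickness surface shell (the cortex of a young
adult rat is ≈2 mm thick) minus a ball around the arterial root that
covers the hilar region:

    Y_c = { x | x ∈ Y_w − (Y_w ⊖ ball R₁)  and  ‖x − v_r‖₂ > R₂ }

From the raw centerline graph — which may carry loops, noisy spurs and
polyline sampling nodes — a trustworthy pre-built arterial tree is
distilled by: maximum-total-radius spanning tree (break every loop at
its thinnest edge), root-oriented conversion keeping the root component,
collapse of degree-2 polyline chains into straight vessels, degree
pruning (at most 4 children, keeping the geometrically deepest paths)
and depth pruning (discard everything farther than ~10 000 μm of
along-tree path from the root, where segmentations stop being
trustworthy).

World/voxel convention used throughout: 0-based indices, corner origin,
``world = origin + index · voxel_size`` with isotropic voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .tree import VascularTree, TreeError, vessel_length

__all__ = [
    "VoxelMask",
    "approximate_cortex",
    "radii_from_distance_transform",
    "mst_by_radius",
    "to_directed_tree",
    "collapse_intermediate",
    "degree_prune",
    "depth_prune",
    "preprocess_centerline",
]


@dataclass
class VoxelMask:
    """3-D boolean raster with isotropic voxel size (μm) and world origin."""

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def volume_um3(self) -> float:
        return float(self.grid.sum()) * self.voxel_size**3

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.voxel_size).astype(int)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World position of the voxel *center*."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean in-mask test for world-space points (μm)."""
        idx = self.world_to_index(points)
        ok = np.all((idx >= 0) & (idx < self.grid.shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if ok.any():
            sub = idx[ok]
            out[ok] = self.grid[sub[:, 0], sub[:, 1], sub[:, 2]]
        return out


def approximate_cortex(
    whole_mask: VoxelMask,
    R1_um: float,
    root_position: np.ndarray,
    R2_um: float,
) -> VoxelMask:
    """Fixed-thickness cortex shell minus a hilar exclusion ball.

    Erosion by a Euclidean ball of radius R₁ is computed exactly as a
    distance-transform threshold (a voxel survives erosion iff its
    distance to the background exceeds R₁), so the shell is the set of
    foreground voxels within R₁ of the surface.  Voxels within R₂ of the
    root position are then removed to keep terminals away from the
    hilus.
    """
    if R1_um <= 0 or R2_um < 0:
        raise ValueError("R1 must be positive and R2 non-negative")
    if not whole_mask.grid.any():
        raise ValueError("empty whole-organ mask")
    if R1_um < whole_mask.voxel_size:
        warnings.warn(
            "R1 is below one voxel: erosion is a no-op and the shell is empty-ish",
            stacklevel=2,
        )
    dt = ndimage.distance_transform_edt(
        whole_mask.grid, sampling=whole_mask.voxel_size
    )
    shell = whole_mask.grid & ~(dt > R1_um)
    centers = np.stack(
        np.meshgrid(*[np.arange(n) for n in whole_mask.grid.shape], indexing="ij"),
        axis=-1,
    )
    world = whole_mask.origin + (centers + 0.5) * whole_mask.voxel_size
    d2 = np.sum((world - np.asarray(root_position, dtype=float)) ** 2, axis=-1)
    shell &= d2 > R2_um**2
    if not shell.any():
        raise ValueError("cortex approximation is empty (R1/R2 too aggressive)")
    return VoxelMask(shell, whole_mask.voxel_size, whole_mask.origin)


# ----------------------------------------------------------------------
# centerline graph preprocessing
# ----------------------------------------------------------------------
def _edge_radius(g: nx.Graph, u: int, v: int) -> float:
    """Radius of a centerline edge = min of its endpoint node radii.

    A vessel segment is no wider than its thinnest end, so artifact
    edges through thin spurious nodes rank below every true edge.
    """
    return float(min(g.nodes[u].get("radius", 0.0), g.nodes[v].get("radius", 0.0)))


def radii_from_distance_transform(
    centerline: nx.Graph, vessel_mask: VoxelMask
) -> nx.Graph:
    """Set each node's radius to its distance from the mask background.

    Nodes outside the vessel mask get radius 0 and a warning — they are
    almost certainly skeletonization artifacts.
    """
    dt = ndimage.distance_transform_edt(
        vessel_mask.grid, sampling=vessel_mask.voxel_size
    )
    out = centerline.copy()
    n_outside = 0
    for v, data in out.nodes(data=True):
        idx = vessel_mask.world_to_index(data["position"])[0]
        if np.all((idx >= 0) & (idx < vessel_mask.grid.shape)) and vessel_mask.grid[
            tuple(idx)
        ]:
            data["radius"] = float(dt[tuple(idx)])
        else:
            data["radius"] = 0.0
            n_outside += 1
    if n_outside:
        warnings.warn(
            f"{n_outside} centerline node(s) outside the vessel mask; radius set to 0",
            stacklevel=2,
        )
    return out


def mst_by_radius(centerline: nx.Graph) -> nx.Graph:
    """Break loops by keeping the maximum-total-radius spanning forest.

    Edge weight is the negative of the edge radius, so a minimum
    spanning tree removes the thinnest edge of every cycle.  Operates
    per connected component; node/edge attributes are preserved.
    """
    g = centerline.copy()
    for u, v in g.edges:
        g.edges[u, v]["_w"] = -_edge_radius(g, u, v)
    mst = nx.minimum_spanning_tree(g, weight="_w")
    for u, v in mst.edges:
        mst.edges[u, v].pop("_w", None)
    return mst


def to_directed_tree(acyclic_graph: nx.Graph, root_id: int) -> VascularTree:
    """Orient edges away from the root; keep only the root's component."""
    if root_id not in acyclic_graph:
        raise TreeError(f"root {root_id} not in graph")
    comp = nx.node_connected_component(acyclic_graph, root_id)
    sub = acyclic_graph.subgraph(comp)
    g = nx.DiGraph()
    for v in sub.nodes:
        g.add_node(v, **{k: val for k, val in sub.nodes[v].items()})
        g.nodes[v]["position"] = np.asarray(sub.nodes[v]["position"], dtype=float)
        g.nodes[v]["prebuilt"] = True
    for u, v in nx.bfs_edges(sub, root_id):
        g.add_edge(u, v, **{k: val for k, val in sub.edges[u, v].items()})
    return VascularTree(g, root_id)


def collapse_intermediate(tree: VascularTree) -> VascularTree:
    """Replace every maximal degree-2 chain with one straight vessel.

    The collapsed vessel's radius is the length-weighted mean of the
    constituent node radii (when node radii are available), preserving
    the distance-transform information along the original polyline.
    """
    out = tree.copy()
    g = out.graph
    changed = True
    while changed:
        changed = False
        for v in sorted(g.nodes):
            if v == out.root or g.out_degree(v) != 1 or g.in_degree(v) != 1:
                continue
            p = out.parent(v)
            (c,) = out.children(v)
            lp = vessel_length(out, (p, v))
            lc = vessel_length(out, (v, c))
            rp = g.edges[p, v].get("radius")
            rc = g.edges[v, c].get("radius")
            attrs = {}
            if rp is not None and rc is not None and (lp + lc) > 0:
                attrs["radius"] = (rp * lp + rc * lc) / (lp + lc)
            elif rc is not None:
                attrs["radius"] = rc
            g.remove_node(v)
            g.add_edge(p, c, **attrs)
            changed = True
    # seed edge radii from node radii where the chain walk had none
    for u, v in g.edges:
        if "radius" not in g.edges[u, v]:
            ru = g.nodes[u].get("radius")
            rv = g.nodes[v].get("radius")
            if ru is not None and rv is not None:
                g.edges[u, v]["radius"] = float(min(ru, rv))
    out.validate()
    return out


def _deepest_path_length(tree: VascularTree, node: int) -> float:
    """Geometric length (μm) of the longest downward path from ``node``."""
    best = 0.0
    for c in tree.children(node):
        best = max(best, vessel_length(tree, (node, c)) + _deepest_path_length(tree, c))
    return best


def degree_prune(tree: VascularTree, max_children: int = 4) -> VascularTree:
    """Cap branching at ``max_children`` per node.

    Branching into more than four daughters is anatomically implausible;
    at every over-branched node only the children whose subtrees reach
    deepest (along-tree geometric length) are kept, the rest are removed
    with their subtrees.  Ties break toward the lower node id.
    """
    out = tree.copy()
    for v in sorted(list(out.nodes())):
        if v not in out.graph:
            continue
        kids = out.children(v)
        if len(kids) <= max_children:
            continue
        ranked = sorted(
            kids,
            key=lambda c: (
                -(vessel_length(out, (v, c)) + _deepest_path_length(out, c)),
                c,
            ),
        )
        for c in ranked[max_children:]:
            out.remove_subtree(c)
    out.validate()
    return out


def depth_prune(tree: VascularTree, max_path_um: float = 10000.0) -> VascularTree:
    """Drop nodes beyond a cumulative along-tree distance from the root.

    Only the first few branch generations of a noisy centerline are
    trustworthy; everything farther than ``max_path_um`` of path length
    (default 10 000 μm) is removed together with its subtree.
    """
    if max_path_um <= 0:
        raise TreeError("depth threshold must be positive (would remove the root)")
    out = tree.copy()
    dist = {out.root: 0.0}
    doomed = []
    for u, v in nx.bfs_edges(out.graph, out.root):
        if u in dist:
            dist[v] = dist[u] + vessel_length(out, (u, v))
            if dist[v] > max_path_um:
                doomed.append(v)
                del dist[v]
    for v in doomed:
        if v in out.graph:
            out.remove_subtree(v)
    out.validate()
    return out


def preprocess_centerline(
    centerline: nx.Graph,
    root_id: int,
    max_children: int = 4,
    max_path_um: float = 10000.0,
) -> VascularTree:
    """Full raw-centerline → pre-built-tree chain.

    MST loop removal → root-oriented tree on the root component →
    polyline-chain collapse → degree pruning → depth pruning → a final
    chain collapse (depth pruning can orphan one child of a bifurcation,
    leaving a fresh degree-2 node).  The chain is idempotent:
    re-applying it to its own output is a no-op.
    """
    t = to_directed_tree(mst_by_radius(centerline), root_id)
    t = collapse_intermediate(t)
    t = degree_prune(t, max_children)
    t = depth_prune(t, max_path_um)
    return collapse_intermediate(t)
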