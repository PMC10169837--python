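"""Synthetic kidney phantom: mask, pre-built arterial tree, noisy centerline.

The real pipeline starts from an ex-vivo micro-CT scan of a rat kidney
(whole-organ mask + semi-automated large-artery segmentation).  No such
scan ships with the package, so this module emulates its essential
features at desk scale:

* ``make_kidney_phantom`` — a solid ellipsoid with a concave hilar
  indentation (a subtracted paraboloid on the root side) and a gently
  perturbed surface, standing in for the thresholded whole-organ mask.
* ``make_prebuilt_tree`` — a rooted arterial scaffold with 2–3 children
  per branch over ~3 generations, all nodes inside the mask, tip radii
  ≈30 μm and Murray-law radii upstream — emulating the first few
  trustworthy branch generations that survive centerline preprocessing.
* ``make_noisy_centerline`` — the raw skeletonization analogue: the
  tree's undirected skeleton plus degree-2 polyline nodes along each
  vessel, thin short spurs, and thin loop edges; exactly the artifacts
  the image-prior chain must remove.

Every generator takes a seed and is bitwise reproducible.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .hemodynamics import murray_parent_radius
from .imageprior import VoxelMask
from .tree import VascularTree, TreeError

__all__ = [
    "make_kidney_phantom",
    "make_prebuilt_tree",
    "make_noisy_centerline",
    "default_phantom",
]

#: Terminal radius (μm) used for pre-built tree tips, chosen so that
#: distance-transform radii and Murray radii agree on fixtures.
TIP_RADIUS_UM = 30.0


def make_kidney_phantom(
    half_axes_um: tuple[float, float, float] = (8000.0, 5000.0, 4000.0),
    voxel_size_um: float = 100.0,
    hilum_depth_um: float = 2000.0,
    seed: int = 0,
) -> VoxelMask:
    """Kidney-like voxel mask: noisy ellipsoid minus a hilar paraboloid.

    The hilum is carved on the −x side (where the arterial root sits) as
    a paraboloid of depth ``hilum_depth_um``.  A low-amplitude smooth
    angular perturbation (~2 % of the radius) breaks the perfect
    ellipsoid without moving the volume outside a 10 % band.
    """
    a, b, c = half_axes_um
    if min(a, b, c) <= 0:
        raise ValueError("half axes must be positive")
    if voxel_size_um > min(a, b, c):
        raise ValueError("voxel size exceeds the smallest half-axis")
    rng = np.random.default_rng(seed)

    pad = 2.0 * voxel_size_um
    shape = tuple(int(np.ceil(2 * (h + pad) / voxel_size_um)) for h in (a, b, c))
    origin = -np.array([a + pad, b + pad, c + pad])
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    )
    xyz = origin + (idx + 0.5) * voxel_size_um
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]

    # smooth multiplicative surface perturbation from a few random harmonics
    theta = np.arctan2(np.hypot(y, z), x)
    phi = np.arctan2(z, y)
    bump = np.zeros_like(x)
    for _ in range(4):
        k1, k2 = rng.integers(1, 4, size=2)
        amp = rng.uniform(0.005, 0.02)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        bump += amp * np.cos(k1 * theta + ph1) * np.cos(k2 * phi + ph2)
    rho2 = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2
    grid = rho2 <= (1.0 + bump) ** 2

    if hilum_depth_um > 0:
        # paraboloid opening inward from the -x apex
        h = hilum_depth_um
        w = 0.9 * h  # lateral half-width at the surface
        t = (x + a) / h  # 0 at apex, 1 at full depth
        hole = (t >= 0) & (t <= 1) & ((y**2 + z**2) <= w**2 * (1.0 - t))
        grid &= ~hole
    return VoxelMask(grid, voxel_size_um, origin)


def _try_place(
    mask: VoxelMask,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """End point for a vessel from ``start``; shrinks/retries to stay in-mask."""
    d = direction / np.linalg.norm(direction)
    for scale in (1.0, 0.7, 0.5, 0.3):
        for _ in range(8):
            jitter = rng.normal(scale=0.25, size=3)
            cand_dir = d + jitter
            cand_dir /= np.linalg.norm(cand_dir)
            end = start + cand_dir * length * scale
            if mask.contains(end[None, :])[0]:
                return end
    # fall back: creep toward the mask centroid, which is interior
    centroid = mask.index_to_world(np.argwhere(mask.grid).mean(axis=0))
    return start + 0.25 * (centroid - start)


def make_prebuilt_tree(
    mask: VoxelMask,
    root_position: np.ndarray | None = None,
    generations: int = 3,
    seed: int = 0,
    children_per_node: tuple[int, int] = (2, 3),
) -> VascularTree:
    """Rooted large-artery scaffold inside the mask.

    Grows ``generations`` branch generations from the root with 2–3
    children per node (uniform over ``children_per_node``), segment
    lengths shrinking by ~0.65 per generation.  Tip vessels get radius
    ≈30 μm and all upstream radii follow Murray's law, so radii are
    monotonically non-increasing from root to tips.  All node positions
    are guaranteed inside the mask.
    """
    if not 2 <= generations <= 5:
        raise ValueError("generations must be in 2..5")
    rng = np.random.default_rng(seed)
    centroid = mask.index_to_world(np.argwhere(mask.grid).mean(axis=0))
    if root_position is None:
        # deepest in-mask voxel on the -x axis: the hilar entrance
        occ = np.argwhere(mask.grid)
        imin = occ[np.lexsort((occ[:, 2], occ[:, 1], occ[:, 0]))][0]
        root_position = mask.index_to_world(imin)
    root_position = np.asarray(root_position, dtype=float)
    if not mask.contains(root_position[None, :])[0]:
        raise TreeError("root position lies outside the mask")

    extent = mask.voxel_size * max(mask.grid.shape)
    g = nx.DiGraph()
    g.add_node(0, position=root_position, prebuilt=True)
    # trunk toward the interior
    trunk_dir = centroid - root_position
    trunk_len = 0.3 * extent
    frontier = [(0, trunk_dir, trunk_len)]
    next_id = 1
    for gen in range(generations):
        new_frontier = []
        for parent, direction, length in frontier:
            n_child = rng.integers(children_per_node[0], children_per_node[1] + 1)
            for _ in range(n_child):
                end = _try_place(mask, g.nodes[parent]["position"], direction, length, rng)
                g.add_node(next_id, position=end, prebuilt=True)
                g.add_edge(parent, next_id)
                new_frontier.append((next_id, end - g.nodes[parent]["position"], length * 0.65))
                next_id += 1
        frontier = new_frontier
    tree = VascularTree(g, 0)

    # Murray radii from 30 μm tips, stored on edges and nodes
    radii: dict[int, float] = {}
    order = [0] + [v for _, v in nx.bfs_edges(g, 0)]
    for v in reversed(order):
        kids = list(g.successors(v))
        radii[v] = TIP_RADIUS_UM if not kids else murray_parent_radius(
            [radii[c] for c in kids]
        )
        g.nodes[v]["radius"] = radii[v]
        p = tree.parent(v)
        if p is not None:
            g.edges[p, v]["radius"] = radii[v]
    return tree


def make_noisy_centerline(
    tree: VascularTree,
    loop_count: int = 0,
    spur_count: int = 0,
    intermediate_per_edge: int = 0,
    seed: int = 0,
) -> nx.Graph:
    """Raw-skeleton analogue of a pre-built tree.

    Starts from the tree's undirected skeleton (node radii = incident
    vessel radii) and injects, reproducibly: ``intermediate_per_edge``
    degree-2 nodes along every vessel, ``spur_count`` short thin spurs
    and ``loop_count`` loops (each a thin two-edge detour through a new
    node).  Spur/loop nodes get radii strictly below every true node
    radius and anchor only at branching nodes, so the preprocessing
    chain can provably remove exactly them.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    for v in tree.nodes():
        r = tree.graph.nodes[v].get("radius")
        if r is None:
            p = tree.parent(v)
            r = (
                tree.graph.edges[p, v].get("radius", TIP_RADIUS_UM)
                if p is not None
                else TIP_RADIUS_UM
            )
        g.add_node(v, position=tree.position(v), radius=float(r))
    next_id = max(g.nodes) + 1
    min_true_radius = min(nx.get_node_attributes(g, "radius").values())

    for u, v in tree.vessels():
        pu, pv = tree.position(u), tree.position(v)
        rv = g.nodes[v]["radius"]
        chain = [u]
        for k in range(intermediate_per_edge):
            frac = (k + 1) / (intermediate_per_edge + 1)
            g.add_node(next_id, position=pu + frac * (pv - pu), radius=rv)
            chain.append(next_id)
            next_id += 1
        chain.append(v)
        for a, b in zip(chain[:-1], chain[1:]):
            g.add_edge(a, b)

    junctions = sorted(
        v for v in tree.nodes() if len(tree.children(v)) >= 2 and v != tree.root
    )
    thin = 0.1 * min_true_radius
    for _ in range(spur_count):
        j = junctions[rng.integers(len(junctions))]
        pos = g.nodes[j]["position"] + rng.normal(scale=0.05 * tree.graph.nodes[j].get("radius", 100.0) + 50.0, size=3)
        g.add_node(next_id, position=pos, radius=thin)
        g.add_edge(j, next_id)
        next_id += 1
    for _ in range(loop_count):
        j1, j2 = rng.choice(junctions, size=2, replace=False)
        mid = 0.5 * (g.nodes[j1]["position"] + g.nodes[j2]["position"])
        g.add_node(next_id, position=mid, radius=thin)
        g.add_edge(j1, next_id)
        g.add_edge(next_id, j2)
        next_id += 1
    return g


def default_phantom(seed: int = 0, generations: int = 3):
    """Convenience: (mask, prebuilt tree) with the default study geometry."""
    mask = make_kidney_phantom(seed=seed)
    tree = make_prebuilt_tree(mask, generations=generations, seed=seed)
    return mask, tree
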