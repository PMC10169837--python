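"""Modified Global Constructive Optimization (GCO) of vascular trees.

GCO builds a vascular tree top-down: it starts from a *fully connected*
initialization — here, every sampled terminal wired straight to its
nearest node of the pre-built large-artery tree — and then alternates
four passes until the total cost settles:

* **relaxation** moves each optimizer-created branching node to the
  position minimizing the local cost (quasi-Newton/BFGS with the
  analytic gradient), one node at a time with its neighbors held fixed;
* **merging** contracts a vessel when relaxation has driven a node
  (nearly) onto a neighbor (shortest/second-shortest incident length
  below a threshold);
* **splitting** greedily hangs a cheap subset of an over-branched
  node's children under a new intermediate node, committing only on a
  strict cost decrease (the optimal subset problem is NP-hard; the
  greedy pair-then-grow approximation is O(n²));
* **pruning** cuts every initialization subtree back to a scheduled
  number of branch generations and reconnects the detached terminals to
  the nearest surviving node *of their own subtree*, coarse-to-fine
  (two generations at first, one more every other iteration).

The cost of a tree is the sum over branching nodes of

    C_local(v) = Σ_{e ∈ B_v} ( w_c π r_e² l_e + w_p Q_e² 8 μ l_e / (π r_e⁴) )

— a material (blood-volume) term plus a dissipated-power (Poiseuille)
term; every vessel is counted once per incident endpoint, i.e. the
total is exactly twice the per-vessel sum, and comparisons only ever
use one consistent convention.  Radii are never decision variables:
Murray's law and Kirchhoff flows are reimposed after every
topology-changing pass.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
from scipy import optimize as sopt
from scipy.spatial import cKDTree

from .hemodynamics import refresh_hemodynamics
from .sampling import PointSet
from .tree import VascularTree, TreeError, vessel_length

__all__ = [
    "GCOConfig",
    "initialize_from_prebuilt",
    "local_cost",
    "total_cost",
    "local_gradient",
    "relax",
    "merge_pass",
    "split_node",
    "prune_pass",
    "run_gco",
]

log = logging.getLogger(__name__)

_EPS_LEN = 1e-9  # μm; lengths below this count as coincident


@dataclass
class GCOConfig:
    """Physical constants and algorithm parameters (μm / s / N units).

    Defaults are the rat-kidney study conditions: material weight
    w_c = 5e-8 N μm⁻² s⁻¹ and power weight w_p = 1 put the two cost
    terms on the same scale; blood viscosity μ = 3.6e-15 N s μm⁻²
    (3.6 mPa·s); inlet flow Q₀ = 1.167e11 μm³/s (7 ml/min); inlet
    pressure p₀ = 100 mmHg; terminal radii ~ N(10.08, 0.14) μm.
    """

    w_c: float = 5e-8
    w_p: float = 1.0
    mu: float = 3.6e-15
    Q0: float = 1.167e11
    p0: float = 100.0
    leaf_radius_mean: float = 10.08
    leaf_radius_sd: float = 0.14
    merge_ratio: float = 0.2
    prune_initial_generations: int = 2
    prune_increment_every: int = 2
    max_iterations: int = 20
    refine_sweeps: int = 6
    convergence_rel_tol: float = 1e-3
    attach_to: str = "all"  # 'all' or 'ending' pre-built nodes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_c", "mu", "Q0", "p0", "leaf_radius_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.merge_ratio < 1:
            raise ValueError("merge_ratio must lie in (0, 1)")
        if self.attach_to not in ("all", "ending"):
            raise ValueError("attach_to must be 'all' or 'ending'")

    def to_dict(self) -> dict:
        return asdict(self)


#: Number of afferent arterioles in the full-scale rat kidney study.
FULL_SCALE_TERMINALS = 30_000


def scaled_inlet_flow(
    n_terminals: int,
    Q0_full: float = 1.167e11,
    n_full: int = FULL_SCALE_TERMINALS,
) -> float:
    """Inlet flow for a desk-scale run with ``n_terminals`` terminals.

    A scaled run models a proportionally perfused subsample of the
    kidney: each afferent arteriole keeps the full-scale per-terminal
    flow Q₀/30 000 ≈ 3.89e6 μm³/s, so the material and power cost terms
    stay on the same relative scale as in the full-scale problem and
    the pressure field stays physiologic.
    """
    return Q0_full / n_full * n_terminals


# ----------------------------------------------------------------------
# cost and gradient
# ----------------------------------------------------------------------
def _edge_coef(radius: float, flow: float, config: GCOConfig) -> float:
    """Per-unit-length cost coefficient of a vessel."""
    if radius <= 0:
        raise ValueError("vessel radius must be positive")
    return (
        config.w_c * np.pi * radius**2
        + config.w_p * flow**2 * 8.0 * config.mu / (np.pi * radius**4)
    )


def local_cost(tree: VascularTree, node: int, config: GCOConfig) -> float:
    """Material + power cost summed over the node's incident vessels."""
    g = tree.graph
    total = 0.0
    for u, v in tree.incident_vessels(node):
        e = g.edges[u, v]
        total += _edge_coef(e["radius"], e["flow"], config) * vessel_length(
            tree, (u, v)
        )
    return total


def total_cost(tree: VascularTree, config: GCOConfig) -> float:
    """Tree cost, each vessel counted once per incident endpoint (×2)."""
    g = tree.graph
    return 2.0 * sum(
        _edge_coef(g.edges[u, v]["radius"], g.edges[u, v]["flow"], config)
        * vessel_length(tree, (u, v))
        for u, v in g.edges
    )


def local_gradient(
    tree: VascularTree, node: int, config: GCOConfig
) -> np.ndarray:
    """Analytic gradient of the local cost w.r.t. the node position.

    ∇C = Σ_e coef_e · (v − n_e)/‖v − n_e‖; undefined when an incident
    vessel has zero length (raises so the caller can perturb).
    """
    g = tree.graph
    v_pos = tree.position(node)
    grad = np.zeros(3)
    for a, b in tree.incident_vessels(node):
        other = b if a == node else a
        e = g.edges[a, b]
        d = v_pos - tree.position(other)
        n = np.linalg.norm(d)
        if n < _EPS_LEN:
            raise ZeroDivisionError(
                f"zero-length vessel incident to node {node}; gradient undefined"
            )
        grad += _edge_coef(e["radius"], e["flow"], config) * d / n
    return grad


def _fermat_objective(x: np.ndarray, anchors: np.ndarray, coefs: np.ndarray):
    eps2 = 1e-12
    d = x - anchors
    n = np.sqrt(np.sum(d * d, axis=1) + eps2)
    return float(np.sum(coefs * n)), (coefs[:, None] * d / n[:, None]).sum(axis=0)


def _weighted_fermat_bfgs(
    anchors: np.ndarray, coefs: np.ndarray, x0: np.ndarray
) -> np.ndarray:
    """argmin_x Σ_i coefs[i]·‖x − anchors[i]‖ by quasi-Newton descent."""
    res = sopt.minimize(
        _fermat_objective, x0, args=(anchors, coefs), jac=True, method="BFGS"
    )
    return res.x if res.fun <= _fermat_objective(x0, anchors, coefs)[0] else x0


def _weighted_fermat_weiszfeld(
    anchors: np.ndarray,
    coefs: np.ndarray,
    x0: np.ndarray,
    n_iter: int = 12,
    tol2: float = 1e-4,
) -> np.ndarray:
    """Fast fixed-point solver for the same weighted-Fermat problem.

    Used inside the split search where thousands of candidate subsets
    are scored per sweep; the committed node is re-polished by the BFGS
    relaxation afterwards.  Anchor collisions are regularized; the
    iterate can only improve on the start because the Weiszfeld map is
    monotone in the objective away from anchor collisions.
    """
    x = x0.astype(float)
    for _ in range(n_iter):
        d = x - anchors
        d = np.sqrt((d * d).sum(axis=1)) + 1e-9
        w = coefs / d
        x_new = (w @ anchors) / w.sum()
        step = x_new - x
        x = x_new
        if step @ step < tol2:
            break
    if _fermat_objective(x, anchors, coefs)[0] <= _fermat_objective(x0, anchors, coefs)[0]:
        return x
    return x0


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------
def initialize_from_prebuilt(
    prebuilt: VascularTree,
    terminals: PointSet,
    config: GCOConfig,
    rng: np.random.Generator | None = None,
) -> VascularTree:
    """Wire every terminal straight to its nearest pre-built node.

    Each terminal becomes a leaf with a one-vessel connection to the
    nearest attachment candidate (all pre-built nodes by default, or
    only ending nodes with ``attach_to='ending'``; exact distance ties
    break toward the lower node id).  The leaf's ``subtree_label`` is
    the attachment node's id — the piece-wise-convex region it will stay
    inside for the whole optimization.  Terminal radii are drawn once
    from N(leaf_radius_mean, leaf_radius_sd), then flows and Murray
    radii are assigned.  Pre-built ending nodes that attract no
    terminals are dropped (they would be flow-less dead ends).
    """
    if prebuilt.n_nodes == 0:
        raise TreeError("empty pre-built tree")
    if len(terminals) == 0:
        raise ValueError("no terminals to attach")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    tree = prebuilt.copy()
    for v in tree.nodes():
        tree.graph.nodes[v]["prebuilt"] = True

    if config.attach_to == "ending":
        candidates = sorted(v for v in tree.nodes() if tree.is_leaf(v))
    else:
        candidates = sorted(tree.nodes())
    pos = np.array([tree.position(v) for v in candidates])
    kd = cKDTree(pos)
    kq = min(2, len(candidates))
    dists, idxs = kd.query(terminals.positions, k=kq)
    dists = np.atleast_2d(dists)
    idxs = np.atleast_2d(idxs)

    radii = rng.normal(
        config.leaf_radius_mean, config.leaf_radius_sd, size=len(terminals)
    )
    radii = np.clip(radii, 1e-3, None)

    for i, p in enumerate(terminals.positions):
        if kq == 2 and np.isclose(dists[i, 0], dists[i, 1]):
            attach = min(candidates[idxs[i, 0]], candidates[idxs[i, 1]])
        else:
            attach = candidates[idxs[i, 0]]
        leaf = tree.add_node(
            p, leaf_radius=float(radii[i]), subtree_label=attach, prebuilt=False
        )
        tree.add_vessel(attach, leaf)
        tree.graph.nodes[attach]["subtree_label"] = attach

    # drop flow-less pre-built dead ends (iteratively, chains included)
    while True:
        dead = [
            v
            for v in tree.leaves()
            if tree.is_prebuilt(v) and v != tree.root
        ]
        if not dead:
            break
        for v in dead:
            tree.graph.remove_node(v)
    tree.validate()
    refresh_hemodynamics(tree, config.Q0)
    return tree


# ----------------------------------------------------------------------
# relaxation
# ----------------------------------------------------------------------
def relax(tree: VascularTree, config: GCOConfig) -> VascularTree:
    """One deterministic sweep of per-node position optimization.

    Movable nodes (optimizer-created intermediates) are visited in id
    order; each is moved to the weighted-Fermat point of its neighbors
    under the cost coefficients, which can only lower the total cost.
    Failures leave the node unmoved.
    """
    g = tree.graph
    for node in sorted(tree.nodes()):
        if node not in g or not tree.is_movable(node):
            continue
        incident = tree.incident_vessels(node)
        anchors = np.array(
            [tree.position(b if a == node else a) for a, b in incident]
        )
        coefs = np.array(
            [
                _edge_coef(g.edges[a, b]["radius"], g.edges[a, b]["flow"], config)
                for a, b in incident
            ]
        )
        x0 = tree.position(node)
        try:
            best = _weighted_fermat_bfgs(anchors, coefs, x0)
        except Exception:  # pragma: no cover - optimizer hiccup: skip node
            log.warning("relaxation failed at node %s; leaving unmoved", node)
            continue
        tree.set_position(node, best)
    return tree


# ----------------------------------------------------------------------
# merging
# ----------------------------------------------------------------------
def merge_pass(tree: VascularTree, config: GCOConfig) -> VascularTree:
    """Contract near-degenerate vessels until no violation remains.

    At every internal node whose shortest incident vessel is shorter
    than ``merge_ratio`` times the second shortest, the shortest vessel
    is contracted — provided the node that would vanish is an
    optimizer-created intermediate (the root, terminals and pre-built
    nodes are never removed).  Deterministic sweeps repeat until a
    fixpoint, since one contraction can expose a new near-coincidence
    at the surviving node.  Flows/radii are reassigned afterwards.
    """
    any_change = False
    while True:
        changed = False
        for node in sorted(tree.nodes()):
            if node not in tree.graph or node == tree.root or tree.is_leaf(node):
                continue
            incident = tree.incident_vessels(node)
            if len(incident) < 2:
                continue
            lengths = sorted(
                ((vessel_length(tree, e), e) for e in incident),
                key=lambda t: t[0],
            )
            (l0, e0), (l1, _) = lengths[0], lengths[1]
            if l1 <= _EPS_LEN or l0 / l1 >= config.merge_ratio:
                continue
            u, v = e0
            # contracting removes the child endpoint v
            if v == tree.root or tree.is_leaf(v) or tree.is_prebuilt(v):
                continue
            tree.contract_vessel((u, v))
            changed = True
        any_change |= changed
        if not changed:
            break
    if any_change:
        refresh_hemodynamics(tree, config.Q0)
    return tree


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------
def _split_delta(
    tree: VascularTree,
    node: int,
    subset: list[int],
    config: GCOConfig,
) -> tuple[float, np.ndarray]:
    """Cost change of hanging ``subset`` under a new node, and its position.

    Upstream radii/flows are unaffected (the descendant set of ``node``
    is unchanged), so the delta is purely local: the subset's direct
    vessels are replaced by vessels from a new intermediate m, plus one
    vessel node→m carrying the subset's merged flow and Murray radius.
    """
    g = tree.graph
    v_pos = tree.position(node)
    child_pos = np.array([tree.position(c) for c in subset])
    coefs = np.array(
        [
            _edge_coef(g.edges[node, c]["radius"], g.edges[node, c]["flow"], config)
            for c in subset
        ]
    )
    base = float(
        np.sum(coefs * np.linalg.norm(child_pos - v_pos, axis=1))
    )
    r_new = float(np.cbrt(sum(g.edges[node, c]["radius"] ** 3 for c in subset)))
    q_new = float(sum(g.edges[node, c]["flow"] for c in subset))
    coef_new = _edge_coef(r_new, q_new, config)

    anchors = np.vstack([child_pos, v_pos])
    all_coefs = np.append(coefs, coef_new)
    x0 = anchors.mean(axis=0)
    m_pos = _weighted_fermat_weiszfeld(anchors, all_coefs, x0)
    new_cost = float(
        np.sum(all_coefs * np.linalg.norm(anchors - m_pos, axis=1))
    )
    return new_cost - base, m_pos


def split_node(
    tree: VascularTree, node: int, config: GCOConfig, force: bool = False
) -> bool:
    """Greedy one-node split; returns True if a split was committed.

    Children eligible for regrouping exclude pre-built nodes (the
    image-derived scaffold is immutable).  The cheapest child pair seeds
    the subset (O(n²) pair scan); children are then added one at a time
    while the cost keeps dropping; the split commits only on a strict
    total decrease.  The new node starts at the subset centroid, is
    locally relaxed, inherits the subtree label, and is movable.

    ``force=True`` commits the cheapest available split even at a cost
    increase — used to enforce the anatomical ≤4-children cap at nodes
    where no improving split exists.
    """
    if node not in tree.graph:
        return False
    kids = [c for c in tree.children(node) if not tree.is_prebuilt(c)]
    if len(kids) < 2 or len(tree.children(node)) < 3:
        return False

    best_pair, best_delta, best_pos = None, (np.inf if force else -1e-12), None
    for i in range(len(kids)):
        for j in range(i + 1, len(kids)):
            subset = [kids[i], kids[j]]
            delta, pos = _split_delta(tree, node, subset, config)
            if delta < best_delta:
                best_pair, best_delta, best_pos = subset, delta, pos
    if best_pair is None:
        return False

    subset, delta, m_pos = list(best_pair), best_delta, best_pos
    remaining = [c for c in kids if c not in subset]
    max_subset = len(tree.children(node)) - 1  # regrouping all children is a no-op chain
    improved = True
    while improved and remaining and len(subset) < max_subset:
        improved = False
        cand_best = None
        for c in remaining:
            d, pos = _split_delta(tree, node, subset + [c], config)
            if d < delta and (cand_best is None or d < cand_best[1]):
                cand_best = (c, d, pos)
        if cand_best is not None:
            subset.append(cand_best[0])
            delta, m_pos = cand_best[1], cand_best[2]
            remaining.remove(cand_best[0])
            improved = True

    if (not force and delta >= -1e-12) or len(subset) >= len(tree.children(node)):
        return False
    label = tree.graph.nodes[node].get("subtree_label")
    g = tree.graph
    r_new = float(np.cbrt(sum(g.edges[node, c]["radius"] ** 3 for c in subset)))
    q_new = float(sum(g.edges[node, c]["flow"] for c in subset))
    m = tree.insert_parent(node, subset, m_pos, prebuilt=False, subtree_label=label)
    # keep the sweep self-consistent before the end-of-pass refresh
    g.edges[node, m].update(radius=r_new, flow=q_new)
    return True


def split_sweep(tree: VascularTree, config: GCOConfig) -> VascularTree:
    """Apply greedy splits until no node admits an improving split."""
    queue = sorted(v for v in tree.nodes() if len(tree.children(v)) > 2)
    guard = 0
    while queue:
        node = queue.pop(0)
        if node not in tree.graph:
            continue
        if split_node(tree, node, config):
            guard += 1
            if guard > 20 * tree.n_nodes:  # pragma: no cover - safety valve
                log.warning("split sweep guard tripped; stopping early")
                break
            # the node may still be over-branched; the new node too
            for v in (node, max(tree.nodes())):
                if len(tree.children(v)) > 2:
                    queue.append(v)
    # hard anatomical cap: >4 children is not realistic, split regardless
    over = sorted(v for v in tree.nodes() if len(tree.children(v)) > 4)
    while over:
        node = over.pop(0)
        if node in tree.graph and len(tree.children(node)) > 4:
            if split_node(tree, node, config, force=True):
                if len(tree.children(node)) > 4:
                    over.append(node)
    refresh_hemodynamics(tree, config.Q0)
    return tree


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
def prune_pass(tree: VascularTree, iteration: int, config: GCOConfig) -> VascularTree:
    """Scheduled coarsening: cut each subtree to g(it) generations.

    g(it) = prune_initial_generations + it // prune_increment_every.
    Within each initialization subtree, vessels deeper than g edge
    generations below the attachment node are deleted; detached
    terminals are reconnected by a straight vessel to the nearest
    surviving node carrying their own subtree label (the attachment node
    always survives, so reconnection cannot fail).
    """
    g_max = (
        config.prune_initial_generations
        + iteration // config.prune_increment_every
    )
    graph = tree.graph
    attachments = sorted(
        v
        for v in tree.nodes()
        if graph.nodes[v].get("subtree_label") == v and tree.is_prebuilt(v)
    )
    doomed: set[int] = set()
    for a in attachments:
        # walk the optimizer-created structure below the attachment node
        stack = [(c, 1) for c in tree.children(a) if not tree.is_prebuilt(c)]
        while stack:
            v, depth = stack.pop()
            if depth > g_max:
                doomed.add(v)
                doomed.update(
                    w for w in nx.dfs_preorder_nodes(graph, v) if w != v
                )
                continue
            stack.extend((c, depth + 1) for c in tree.children(v))

    terminals = sorted(v for v in doomed if tree.is_leaf(v))
    graph.remove_nodes_from(doomed - set(terminals))
    for v in terminals:  # leaf whose parent survived: detach explicitly
        for p in list(graph.predecessors(v)):
            graph.remove_edge(p, v)

    # reconnect every detached terminal within its own subtree
    by_label: dict[int, list[int]] = {}
    for v in terminals:
        by_label.setdefault(graph.nodes[v]["subtree_label"], []).append(v)
    for label, leaves in by_label.items():
        targets = sorted(
            w
            for w in graph.nodes
            if graph.nodes[w].get("subtree_label") == label
            and w not in leaves
            and (graph.out_degree(w) > 0 or w == label)
            and "leaf_radius" not in graph.nodes[w]
        )
        tpos = np.array([tree.position(w) for w in targets])
        for v in leaves:
            d = np.linalg.norm(tpos - tree.position(v), axis=1)
            best = targets[int(np.argmin(d))]  # ties: lowest id (sorted)
            graph.add_edge(best, v)

    # drop optimizer intermediates left childless by the cut
    while True:
        dangling = [
            v
            for v in tree.leaves()
            if not tree.is_prebuilt(v)
            and "leaf_radius" not in graph.nodes[v]
            and v != tree.root
        ]
        if not dangling:
            break
        graph.remove_nodes_from(dangling)

    tree.validate()
    refresh_hemodynamics(tree, config.Q0)
    return tree


# ----------------------------------------------------------------------
# outer loop
# ----------------------------------------------------------------------
def run_gco(
    prebuilt: VascularTree,
    terminals: PointSet,
    config: GCOConfig,
) -> tuple[VascularTree, list[dict]]:
    """Full constructive optimization: initialize, then iterate to rest.

    Each outer iteration runs relax → merge → split and measures the
    total cost; if the relative change from the previous iteration is
    below ``convergence_rel_tol`` (or the iteration budget is spent) the
    loop ends there — the final iteration is never followed by a prune,
    so the returned tree is fully refined.  Otherwise a scheduled prune
    coarsens the tree and the loop continues.  Returns the tree (flows,
    Murray radii and validity invariants holding) and a per-iteration
    cost log.
    """
    rng = np.random.default_rng(config.seed)
    tree = initialize_from_prebuilt(prebuilt, terminals, config, rng)
    cost_log: list[dict] = []
    prev: float | None = None
    best: VascularTree | None = None
    best_cost = np.inf
    for it in range(config.max_iterations):
        # refine to an inner fixed point at the current prune scale so the
        # measured cost reflects the converged structure, not a half-rebuilt
        # one (refine_sweeps caps the inner loop)
        c = np.inf
        for _ in range(max(1, config.refine_sweeps)):
            relax(tree, config)
            merge_pass(tree, config)
            split_sweep(tree, config)
            c_new = total_cost(tree, config)
            done = abs(c - c_new) / c_new < config.convergence_rel_tol
            c = c_new
            if done:
                break
        # incumbent tracking: a prune+rebuild that lands slightly worse is
        # discarded and the next, coarser scale restarts from the best tree
        if c < best_cost:
            best, best_cost = tree.copy(), c
        else:
            tree, c = best.copy(), best_cost
        cost_log.append(
            {
                "iteration": it,
                "total_cost": c,
                "n_nodes": tree.n_nodes,
                "n_vessels": tree.n_vessels,
            }
        )
        log.info(
            "GCO iteration %d: cost %.6g, %d nodes, %d vessels",
            it,
            c,
            tree.n_nodes,
            tree.n_vessels,
        )
        converged = (
            prev is not None
            and abs(prev - c) / prev < config.convergence_rel_tol
        )
        if converged:
            break
        if it == config.max_iterations - 1:
            log.warning(
                "GCO stopped at the iteration budget without meeting the "
                "convergence tolerance; returning the current tree"
            )
            break
        prune_pass(tree, it, config)
        prev = c
    tree.validate()
    refresh_hemodynamics(tree, config.Q0)
    return tree, cost_log
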