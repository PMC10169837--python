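"""1-D hemodynamic closure: Kirchhoff flows, Murray radii, Poiseuille pressures.

Blood is treated as an incompressible Newtonian fluid in laminar flow
through straight rigid cylinders.  Three classic relations close the
system on any rooted tree:

* **Kirchhoff's first law** — the flow in a parent vessel equals the sum
  of its children's flows; the total inlet flow Q₀ is split equally over
  the N terminal vessels (afferent arterioles), Q_t = Q₀/N.
* **Murray's law** — at every branch point the parent radius cubed
  equals the sum of the children radii cubed, r_p³ = Σ r_c³.  Radii are
  therefore fully determined, bottom-up, by the terminal radii; they are
  never free variables of the optimizer.
* **Hagen–Poiseuille** — the pressure drop along a vessel is
  Δp = 8 μ l Q / (π r⁴), accumulated outward from the inlet pressure p₀
  by breadth-first traversal.  Branching losses are neglected.

All quantities use the internal μm/s/N system; pressures cross the API
boundary in mmHg through a single conversion constant (see
:mod:`renalvasc.units`).
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np

from . import units
from .tree import VascularTree, vessel_length

__all__ = [
    "assign_flows",
    "assign_radii_murray",
    "pressure_profile",
    "refresh_hemodynamics",
    "murray_parent_radius",
]


def murray_parent_radius(child_radii) -> float:
    """Cube-law parent radius: (Σ r³)^(1/3)."""
    r = np.asarray(child_radii, dtype=float)
    return float(np.cbrt(np.sum(r**3)))


def _reverse_topological(tree: VascularTree) -> list[int]:
    order = [tree.root]
    for _, v in nx.bfs_edges(tree.graph, tree.root):
        order.append(v)
    order.reverse()
    return order


def assign_flows(tree: VascularTree, Q0: float) -> VascularTree:
    """Set every vessel's flow in place (μm³/s) and return the tree.

    Terminal vessels each carry Q₀/N; internal vessels carry the number
    of terminals below them times Q₀/N, which is exactly the zero-addition
    rule.
    """
    if tree.n_vessels == 0:
        raise ValueError("tree has no terminal vessels")
    leaves = tree.leaves()
    qt = Q0 / len(leaves)
    n_below: dict[int, int] = {}
    for v in _reverse_topological(tree):
        kids = tree.children(v)
        n_below[v] = 1 if not kids else sum(n_below[c] for c in kids)
    g = tree.graph
    for u, v in g.edges:
        g.edges[u, v]["flow"] = n_below[v] * qt
    return tree


def assign_radii_murray(
    tree: VascularTree, leaf_radii: Mapping[int, float]
) -> VascularTree:
    """Set every vessel's radius in place (μm) by Murray's cube law.

    ``leaf_radii`` maps each leaf node id to its terminal-vessel radius.
    Degree-1 chain nodes pass the radius through unchanged (a single-term
    cube law).
    """
    g = tree.graph
    r_in: dict[int, float] = {}
    for v in _reverse_topological(tree):
        kids = tree.children(v)
        if not kids:
            try:
                r = float(leaf_radii[v])
            except KeyError:
                raise ValueError(f"missing radius for terminal node {v}") from None
            if r <= 0:
                raise ValueError(f"terminal radius must be positive, got {r}")
        else:
            r = murray_parent_radius([r_in[c] for c in kids])
        r_in[v] = r
        p = tree.parent(v)
        if p is not None:
            g.edges[p, v]["radius"] = r
    return tree


def pressure_profile(
    tree: VascularTree, p0_mmhg: float, mu: float
) -> dict[int, float]:
    """Per-node pressures (mmHg) by Poiseuille drops from the inlet.

    The root node sits at ``p0_mmhg``; walking outward, the pressure at a
    vessel's outlet is its inlet pressure minus 8 μ l Q / (π r⁴).
    Viscosity ``mu`` is in N s μm⁻².
    """
    g = tree.graph
    p: dict[int, float] = {tree.root: units.mmhg_to_n_per_um2(p0_mmhg)}
    for u, v in nx.bfs_edges(g, tree.root):
        e = g.edges[u, v]
        r, q = e["radius"], e["flow"]
        if r <= 0:
            raise ValueError(f"vessel ({u},{v}) has non-positive radius")
        drop = 8.0 * mu * vessel_length(tree, (u, v)) * q / (np.pi * r**4)
        p[v] = p[u] - drop
    return {v: units.n_per_um2_to_mmhg(pv) for v, pv in p.items()}


def refresh_hemodynamics(tree: VascularTree, Q0: float) -> VascularTree:
    """Recompute flows and Murray radii from the stored terminal radii.

    Every leaf node must carry a ``leaf_radius`` attribute (set once at
    initialization); topology-changing passes call this to keep radius
    and flow consistent with the current tree.
    """
    leaf_radii = {}
    for v in tree.leaves():
        r = tree.graph.nodes[v].get("leaf_radius")
        if r is None:
            raise ValueError(f"leaf {v} has no stored terminal radius")
        leaf_radii[v] = float(r)
    assign_flows(tree, Q0)
    assign_radii_murray(tree, leaf_radii)
    return tree
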