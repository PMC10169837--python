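"""Strahler ordering and per-order morphometric / hemodynamic tables.

Strahler ordering labels the vessels (edges) of a rooted tree by the
diameter hierarchy they form: terminal vessels (afferent arterioles) are
order 0, and a parent takes order j+1 when two or more of its daughters
share the maximal daughter order j, otherwise it inherits j.  The
per-order table aggregates radius, length, count, total cross-sectional
area, flow and outlet pressure — the standard way renal-casting studies
report arterial-tree anatomy, and therefore the natural comparison
surface against literature data.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .tree import VascularTree, vessel_length

__all__ = [
    "strahler_orders",
    "per_order_stats",
    "afferent_parent_orders",
    "tree_summary",
    "literature_reference_radii",
    "correlate_with_reference",
]


def strahler_orders(tree: VascularTree) -> dict[tuple[int, int], int]:
    """Strahler order of every vessel, keyed by (parent, child) edge."""
    g = tree.graph
    order: dict[tuple[int, int], int] = {}
    # children before parents
    seq = [tree.root] + [v for _, v in nx.bfs_edges(g, tree.root)]
    for v in reversed(seq):
        p = tree.parent(v)
        if p is None:
            continue
        child_orders = [order[(v, c)] for c in g.successors(v)]
        if not child_orders:
            order[(p, v)] = 0
        else:
            j = max(child_orders)
            order[(p, v)] = j + 1 if child_orders.count(j) >= 2 else j
    return order


def per_order_stats(
    tree: VascularTree,
    pressures: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Per-Strahler-order summary table.

    Rows are indexed by order (contiguous 0..max); columns: ``count``,
    ``radius_mean``/``radius_sd`` (μm), ``length_mean``/``length_sd``
    (μm), ``area_total_mm2`` (Σ π r², mm²), ``flow_mean`` (μm³/s) and,
    when a node→mmHg pressure map is supplied, ``pressure_mean`` (mmHg at
    vessel outlets).
    """
    if tree.n_vessels == 0:
        raise ValueError("empty tree")
    orders = strahler_orders(tree)
    g = tree.graph
    rows = []
    for (u, v), k in orders.items():
        e = g.edges[u, v]
        rows.append(
            {
                "order": k,
                "radius": e.get("radius", np.nan),
                "length": vessel_length(tree, (u, v)),
                "flow": e.get("flow", np.nan),
                "pressure": pressures.get(v, np.nan) if pressures else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    out = df.groupby("order").agg(
        count=("order", "size"),
        radius_mean=("radius", "mean"),
        radius_sd=("radius", "std"),
        length_mean=("length", "mean"),
        length_sd=("length", "std"),
        area_total_um2=("radius", lambda r: float(np.sum(np.pi * np.asarray(r) ** 2))),
        flow_mean=("flow", "mean"),
        pressure_mean=("pressure", "mean"),
    )
    out["area_total_mm2"] = out.pop("area_total_um2") / 1.0e6
    out = out.reindex(range(int(df["order"].max()) + 1), fill_value=0)
    return out


def afferent_parent_orders(tree: VascularTree) -> Counter:
    """Histogram of the Strahler orders of the terminals' parent vessels.

    For every terminal vessel (p, leaf) the order of p's own parent
    vessel is recorded; a terminal hanging directly off the root (no
    grandparent vessel) is counted under the root vessel's order.
    """
    orders = strahler_orders(tree)
    hist: Counter = Counter()
    for v in tree.leaves():
        p = tree.parent(v)
        gp = tree.parent(p) if p is not None else None
        if p is None:
            continue
        if gp is None:
            # terminal attached at the root: bin under the root vessel order
            root_orders = [orders[(tree.root, c)] for c in tree.children(tree.root)]
            hist[max(root_orders)] += 1
        else:
            hist[orders[(gp, p)]] += 1
    return hist


def tree_summary(tree: VascularTree) -> dict[str, int]:
    """Global counts: vessels, levels and Strahler orders.

    ``n_levels`` is the maximum number of vessels on any root-to-leaf
    path; ``n_strahler_orders`` counts distinct orders 0..max.
    """
    if tree.n_vessels == 0:
        return {"n_vessels": 0, "n_levels": 0, "n_strahler_orders": 0}
    depth = tree.depth_in_vessels()
    orders = strahler_orders(tree)
    return {
        "n_vessels": tree.n_vessels,
        "n_levels": max(depth[v] for v in tree.leaves()),
        "n_strahler_orders": max(orders.values()) + 1,
    }


def literature_reference_radii() -> pd.DataFrame:
    """Literature per-order mean radii for the rat renal arterial tree.

    Values digitized from published vascular-cast morphometry
    (Nordsletten et al. 2006, Am J Physiol); shipped purely as a
    reference table for correlation reporting, not produced by this
    package.
    """
    ref = importlib.resources.files("renalvasc").joinpath(
        "data/rat_renal_artery_literature.csv"
    )
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#").set_index("order")


def plot_order_stats(table: pd.DataFrame, path=None):
    """Radius/length/count/area vs Strahler order (count and radius in
    log scale, as conventional for vascular morphometry).

    Requires matplotlib (``pip install renalvasc[plots]``).  Returns the
    figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    panels = [
        ("radius_mean", "mean radius (μm)", True),
        ("length_mean", "mean length (μm)", False),
        ("count", "vessel count", True),
        ("area_total_mm2", "total cross-section (mm²)", False),
    ]
    for ax, (col, label, logy) in zip(axes.ravel(), panels):
        ax.plot(table.index, table[col], "o-")
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("Strahler order")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def correlate_with_reference(
    table: pd.DataFrame, reference: pd.DataFrame, column: str = "radius_mean"
) -> float:
    """Pearson r between per-order mean values and a reference table."""
    common = table.index.intersection(reference.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared orders to correlate")
    r, _ = sstats.pearsonr(
        table.loc[common, column], reference.loc[common, column]
    )
    return float(r)
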