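"""Shared fixtures: random rooted trees and a small kidney phantom."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from renalvasc.hemodynamics import refresh_hemodynamics
from renalvasc.tree import VascularTree


def make_random_tree(
    rng: np.random.Generator,
    n_nodes: int,
    span: float = 1000.0,
) -> VascularTree:
    """Random recursive tree with positions; no radii/flows."""
    g = nx.DiGraph()
    g.add_node(0, position=rng.uniform(-span, span, size=3))
    for v in range(1, n_nodes):
        parent = int(rng.integers(0, v))
        g.add_node(v, position=rng.uniform(-span, span, size=3))
        g.add_edge(parent, v)
    return VascularTree(g, 0)


def make_random_hemo_tree(
    rng: np.random.Generator,
    n_nodes: int,
    Q0: float = 1.0e9,
    span: float = 1000.0,
) -> VascularTree:
    """Random tree with terminal radii, Kirchhoff flows and Murray radii."""
    tree = make_random_tree(rng, n_nodes, span)
    for v in tree.leaves():
        tree.graph.nodes[v]["leaf_radius"] = float(rng.uniform(5.0, 15.0))
    refresh_hemodynamics(tree, Q0)
    return tree


@pytest.fixture(scope="session")
def coarse_phantom():
    """Low-resolution kidney mask + pre-built tree (fast, shared)."""
    from renalvasc.phantom import make_kidney_phantom, make_prebuilt_tree

    mask = make_kidney_phantom(voxel_size_um=200.0, seed=5)
    tree = make_prebuilt_tree(mask, generations=3, seed=5)
    return mask, tree


@pytest.fixture
def rng():
    return np.random.default_rng(20230509)
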