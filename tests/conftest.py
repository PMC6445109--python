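"""Shared fixtures and independent oracle helpers.

The oracle helpers deliberately avoid the package's own tree machinery:
they operate on networkx graphs built directly from dendropy node
objects, so agreement between package output and oracle output is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# random tree construction (independent of the package simulators)
# ---------------------------------------------------------------------------


def random_binary_tree(labels, rng, with_lengths=True, with_supports=False):
    """A random rooted binary tree over ``labels`` by sequential joining."""
    namespace = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        n = dendropy.Node()
        n.taxon = namespace.new_taxon(label=lab)
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        node.support = None
        if node.parent_node is not None and with_lengths:
            node.edge.length = float(rng.uniform(0.05, 1.0))
        if (
            with_supports
            and node.parent_node is not None
            and not node.is_leaf()
        ):
            node.support = float(rng.integers(0, 101))
    return tree


# ---------------------------------------------------------------------------
# graph-based oracles
# ---------------------------------------------------------------------------


def tree_graph(tree):
    """Undirected networkx graph of the tree; tips keyed by label."""
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        key = node.taxon.label if node.is_leaf() else id(node)
        g.add_node(key)
        if node.parent_node is not None:
            parent = node.parent_node
            pkey = parent.taxon.label if parent.is_leaf() else id(parent)
            g.add_edge(pkey, key)
    return g


def oracle_splits(tree):
    """All non-trivial unrooted splits via edge removal on the graph."""
    g = tree_graph(tree)
    tips = {n.taxon.label for n in tree.leaf_node_iter()}
    splits = set()
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(t for t in tips if t in comp)
        other = frozenset(tips - side)
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def oracle_is_monophyletic(tree, tip_subset):
    """Unrooted monophyly: some edge separates exactly ``tip_subset``."""
    g = tree_graph(tree)
    tips = {n.taxon.label for n in tree.leaf_node_iter()}
    target = frozenset(tip_subset)
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(t for t in tips if t in comp)
        if side == target or (frozenset(tips) - side) == target:
            return True
    return False


def oracle_quartet_topology(tree, a, b, c, d):
    """1 = ab|cd, 2 = ac|bd, 3 = ad|bc, 0 = unresolved.

    In a tree, the pairing whose two connecting paths share no node is
    the displayed quartet topology.
    """
    g = tree_graph(tree)
    paths = {
        pair: set(nx.shortest_path(g, *pair))
        for pair in [(a, b), (c, d), (a, c), (b, d), (a, d), (b, c)]
    }
    if not paths[(a, b)] & paths[(c, d)]:
        return 1
    if not paths[(a, c)] & paths[(b, d)]:
        return 2
    if not paths[(a, d)] & paths[(b, c)]:
        return 3
    return 0


def oracle_path_length(tree, a, b):
    """Sum of branch lengths on the tip-to-tip path."""
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        key = node.taxon.label if node.is_leaf() else id(node)
        if node.parent_node is not None:
            parent = node.parent_node
            pkey = parent.taxon.label if parent.is_leaf() else id(parent)
            g.add_edge(pkey, key, weight=node.edge.length or 0.0)
    return nx.shortest_path_length(g, a, b, weight="weight")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
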