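"""Newick I/O and tree surgery shared by every downstream stage.

Gene trees arrive as newick with bootstrap support on internal nodes
(either as internal-node labels or as comments); the functions here read
and write them, collapse poorly supported edges into polytomies, prune
taxa, and extract canonical unrooted bipartitions.  Everything downstream
(paralog classification, concordance counting, quartet support) works on
the ``Bipartition`` objects produced here, so rooting of the input trees
is display-only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

__all__ = [
    "TreeError",
    "Bipartition",
    "read_tree",
    "write_tree",
    "collapse_low_support",
    "extract_splits",
    "edge_leafsets",
    "prune_to_taxa",
    "tip_labels",
    "deroot",
]


class TreeError(ValueError):
    """Raised for malformed newick input or invalid tree operations."""


@dataclass(frozen=True)
class Bipartition:
    """A canonical unrooted split of a taxon set into two groups.

    The split is stored as the side that does *not* contain the
    lexicographically smallest label, so that equal splits compare and
    hash equal regardless of how the source tree was rooted.
    """

    taxa: frozenset
    side: frozenset

    @classmethod
    def from_sides(cls, side_a: Iterable[str], side_b: Iterable[str]) -> "Bipartition":
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeError("both sides of a bipartition must be non-empty")
        if a & b:
            raise TreeError(f"bipartition sides overlap: {sorted(a & b)}")
        taxa = a | b
        smallest = min(taxa)
        side = b if smallest in a else a
        return cls(taxa=taxa, side=side)

    @property
    def other_side(self) -> frozenset:
        return self.taxa - self.side

    @property
    def informative(self) -> bool:
        return len(self.side) >= 2 and len(self.other_side) >= 2

    def restrict(self, taxa: Iterable[str]) -> Optional["Bipartition"]:
        """Induced split on a taxon subset, or None if either side empties."""
        sub = frozenset(taxa) & self.taxa
        a = self.side & sub
        b = sub - self.side
        if not a or not b:
            return None
        return Bipartition.from_sides(a, b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True when the two splits cannot coexist in one tree.

        Both splits must be on the same taxon set; two splits are
        compatible iff at least one of the four pairwise side
        intersections is empty.
        """
        if self.taxa != other.taxa:
            raise TreeError("conflict test requires splits on the same taxon set")
        a1, b1 = self.side, self.other_side
        a2, b2 = other.side, other.other_side
        return bool(a1 & a2) and bool(a1 & b2) and bool(b1 & a2) and bool(b1 & b2)

    def __str__(self) -> str:
        left = ",".join(sorted(self.other_side))
        right = ",".join(sorted(self.side))
        return f"{left}|{right}"


_NUMBER_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _support_from_comments(node: dendropy.Node) -> Optional[float]:
    for comment in node.comments or []:
        text = comment.strip().lstrip("&")
        m = re.search(r"(?:support|label|posterior|prob)\s*=\s*(" + _NUMBER_RE.pattern + ")", text)
        if m:
            return float(m.group(1))
        if _NUMBER_RE.fullmatch(text):
            return float(text)
    return None


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string into a dendropy tree with ``node.support`` set.

    Internal-node labels that parse as numbers are interpreted as
    bootstrap supports, as are bare or ``support=`` comment annotations.
    If every support found is <= 1 the values are taken to be fractions
    and rescaled to percentages.  Duplicate tip labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen, dupes = set(), set()
    for lab in labels:
        if lab in seen:
            dupes.add(lab)
        seen.add(lab)
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")

    supports = []
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf():
            continue
        value = None
        if node.label is not None:
            try:
                value = float(node.label)
            except ValueError:
                value = None
        if value is None:
            value = _support_from_comments(node)
        if value is not None:
            node.support = value
            supports.append(value)

    if supports and all(s <= 1.0 for s in supports):
        for node in tree.preorder_node_iter():
            if node.support is not None:
                node.support *= 100.0
        supports = [s * 100.0 for s in supports]
    if any(s < 0.0 or s > 100.0 for s in supports):
        bad = [s for s in supports if s < 0.0 or s > 100.0]
        raise TreeError(f"support values outside [0, 100] after rescaling: {bad}")
    return tree


def _format_number(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_tree(tree: dendropy.Tree) -> str:
    """Serialize to newick with supports written as internal-node labels."""
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            support = getattr(node, "support", None)
            node.label = _format_number(support) if support is not None else None
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def copy_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep copy preserving branch lengths and supports."""
    return read_tree(write_tree(tree))


def collapse_low_support(tree: dendropy.Tree, threshold_percent: float = 33.0) -> dendropy.Tree:
    """Contract every internal edge with support strictly below the threshold.

    Edges without a support value are kept.  The input is not modified; a
    collapsed copy is returned.  The default threshold of 33% reflects the
    convention of discarding splits resolved in under a third of bootstrap
    replicates before coalescent summary analyses.
    """
    if not 0.0 <= threshold_percent <= 100.0:
        raise TreeError(f"threshold must be within [0, 100], got {threshold_percent}")
    out = copy_tree(tree)
    to_collapse = [
        node
        for node in out.preorder_node_iter()
        if not node.is_leaf()
        and node.parent_node is not None
        and getattr(node, "support", None) is not None
        and node.support < threshold_percent
    ]
    for node in to_collapse:
        parent = node.parent_node
        for child in list(node.child_nodes()):
            node.remove_child(child)
            parent.add_child(child)
        parent.remove_child(node)
    return out


def edge_leafsets(tree: dendropy.Tree) -> list:
    """Leaf-label set below each edge (one entry per non-root node).

    Includes the trivial tip edges; used both for split extraction and for
    unrooted monophyly checks.
    """
    below = {}
    sets = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            sets.append(below[node])
    return sets


def extract_splits(tree: dendropy.Tree, taxon_universe: Optional[Iterable[str]] = None) -> set:
    """Canonical informative unrooted splits of the tree, on its own tip set."""
    tips = tip_labels(tree)
    if taxon_universe is not None:
        universe = frozenset(taxon_universe)
        extra = tips - universe
        if extra:
            raise TreeError(f"tree tips not in taxon universe: {sorted(extra)}")
    splits = set()
    for leafset in edge_leafsets(tree):
        other = tips - leafset
        if len(leafset) >= 2 and len(other) >= 2:
            splits.add(Bipartition.from_sides(leafset, other))
    return splits


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; path lengths through removed degree-2
    nodes are preserved by summing branch lengths."""
    keep = frozenset(keep)
    survivors = keep & tip_labels(tree)
    if len(survivors) < 2:
        raise TreeError(
            f"pruning must leave at least 2 taxa; only {sorted(survivors)} present"
        )
    out = copy_tree(tree)
    out.retain_taxa_with_labels(list(survivors))
    out.suppress_unifurcations()
    # a lingering degree-1 root hides part of the tip-to-tip path
    root = out.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        root.remove_child(child)
        for grandchild in list(child.child_nodes()):
            child.remove_child(grandchild)
            if child.edge.length is not None and grandchild.edge.length is not None:
                grandchild.edge.length += child.edge.length
            root.add_child(grandchild)
        if not root.child_nodes():
            # two survivors collapsed to a single cherry under the old root
            root.add_child(child)
            break
        if child.is_leaf():
            root.add_child(child)
            break
    return out


def deroot(tree: dendropy.Tree) -> dendropy.Tree:
    """Collapse a bifurcating root into a trifurcation (in place).

    Under a reversible substitution model the root placement is not
    identifiable, and the two edges meeting at a bifurcating root are
    confounded; fitting is done on the derooted tree.
    """
    root = tree.seed_node
    children = root.child_nodes()
    if len(children) != 2:
        return tree
    internal = next((c for c in children if not c.is_leaf()), None)
    if internal is None:
        return tree
    other = children[0] if children[1] is internal else children[1]
    if internal.edge.length is not None:
        other.edge.length = (other.edge.length or 0.0) + internal.edge.length
    root.remove_child(internal)
    for child in list(internal.child_nodes()):
        internal.remove_child(child)
        root.add_child(child)
    return tree
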