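"""Quartet-frequency support and coalescent-unit branch lengths.

Around each internal species-tree branch, sampled quartets take one
taxon from each of the four subtrees the branch induces (the two child
clades below it, the sibling clade, and the remainder of the tree).  For
every gene tree resolving a sampled quartet, the displayed topology is
tallied; q1 is the frequency of the species-tree arrangement and q2/q3
its two alternatives.  Under the multispecies coalescent the expected
concordant frequency for an internal branch of length t coalescent units
is q1 = 1 - (2/3) e^(-t), so the branch length is recovered as

    t = -ln( (3/2) (1 - q1) )      for q1 > 1/3,  else 0,

capped at a configurable maximum as q1 -> 1 (the estimate diverges).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
import pandas as pd

from .trees import Bipartition, TreeError, tip_labels

__all__ = [
    "QuartetSupport",
    "internal_branches",
    "quartet_frequencies",
    "quartet_support_table",
    "coalescent_branch_length",
]

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_CAP = 10.0


@dataclass
class QuartetSupport:
    """Quartet topology frequencies around one internal branch."""

    branch_id: str
    split: Bipartition
    q1: float
    q2: float
    q3: float
    n_informative: int
    coalescent_length: float

    def __post_init__(self):
        if self.n_informative > 0:
            total = self.q1 + self.q2 + self.q3
            if abs(total - 1.0) > 1e-9:
                raise TreeError(f"quartet frequencies sum to {total}, expected 1")
        if self.coalescent_length < 0:
            raise TreeError("coalescent length must be non-negative")


def coalescent_branch_length(q1: float, cap: float = DEFAULT_LENGTH_CAP) -> float:
    """Invert q1 = 1 - (2/3) e^(-t) to coalescent units.

    q1 <= 1/3 carries no signal above a hard polytomy and maps to 0 (the
    boundary of the MLE); values approaching 1 are capped at ``cap``.
    """
    if not 0.0 <= q1 <= 1.0:
        raise TreeError(f"q1 must be in [0, 1], got {q1}")
    if q1 <= 1.0 / 3.0:
        if q1 < 1.0 / 3.0:
            logger.warning(
                "q1 = %.4f is below 1/3; returning 0 (MLE boundary)", q1
            )
        return 0.0
    inner = 1.5 * (1.0 - q1)
    if inner <= np.exp(-cap):
        return cap
    return float(min(-np.log(inner), cap))


def _clades(tree: dendropy.Tree) -> Dict[int, frozenset]:
    clades = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clades[id(node)] = frozenset([node.taxon.label])
        else:
            clades[id(node)] = frozenset().union(
                *(clades[id(c)] for c in node.child_nodes())
            )
    return clades


def internal_branches(species_tree: dendropy.Tree):
    """Scorable internal branches with their four induced taxon groups.

    Returns a list of (split, [group_a, group_b, group_sibling,
    group_rest]).  Branches incident to the root are excluded: on the
    unrooted tree they have no fourth subtree.
    """
    taxa = tip_labels(species_tree)
    clades = _clades(species_tree)
    branches = []
    for node in species_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        parent = node.parent_node
        if parent.parent_node is None:
            continue  # root-adjacent: no taxa beyond the sibling subtree
        children = node.child_nodes()
        if len(children) != 2:
            raise TreeError("species tree must be binary for quartet support")
        group_a = sorted(clades[id(children[0])])
        group_b = sorted(clades[id(children[1])])
        siblings = [c for c in parent.child_nodes() if c is not node]
        group_s = sorted(frozenset().union(*(clades[id(s)] for s in siblings)))
        group_r = sorted(taxa - clades[id(parent)])
        split = Bipartition.from_sides(clades[id(node)], taxa - clades[id(node)])
        branches.append((split, [group_a, group_b, group_s, group_r]))
    return branches


def _gene_split_masks(gene_trees: Sequence[dendropy.Tree], taxa: Sequence[str]):
    """Per gene: (taxon bit map, list of split masks) for fast quartet tests."""
    bit = {t: 1 << i for i, t in enumerate(sorted(taxa))}
    prepared = []
    for gt in gene_trees:
        gtaxa = tip_labels(gt)
        masks = []
        clades = _clades(gt)
        for node in gt.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = clades[id(node)]
            if len(below) >= 2 and len(gtaxa - below) >= 2:
                masks.append(sum(bit[t] for t in below))
        present = sum(bit[t] for t in gtaxa)
        prepared.append((present, sorted(set(masks))))
    return bit, prepared


def _quartet_topology(mask_a, mask_b, mask_c, mask_d, split_masks) -> int:
    """0 = unresolved, 1 = ab|cd, 2 = ac|bd, 3 = ad|bc."""
    for m in split_masks:
        ia, ib = bool(m & mask_a), bool(m & mask_b)
        ic, id_ = bool(m & mask_c), bool(m & mask_d)
        if ia == ib and ic == id_ and ia != ic:
            return 1
        if ia == ic and ib == id_ and ia != ib:
            return 2
        if ia == id_ and ib == ic and ia != ib:
            return 3
    return 0


def quartet_frequencies(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    branch: Union[Bipartition, int],
    max_quartets_per_branch: int = 100,
    seed: int = 0,
    length_cap: float = DEFAULT_LENGTH_CAP,
) -> QuartetSupport:
    """Quartet support for one internal branch.

    ``branch`` is either the branch's unrooted split or its index in
    ``internal_branches`` order.  All quartets are enumerated when their
    number does not exceed ``max_quartets_per_branch``; otherwise that
    many quartets are sampled uniformly (seeded, with replacement).
    """
    if max_quartets_per_branch < 1:
        raise TreeError("max_quartets_per_branch must be >= 1")
    branches = internal_branches(species_tree)
    if isinstance(branch, int):
        if not 0 <= branch < len(branches):
            raise TreeError(f"branch index {branch} out of range")
        split, groups = branches[branch]
    else:
        match = [b for b in branches if b[0] == branch]
        if not match:
            raise TreeError(
                f"split {branch} is not a scorable internal branch of the species tree"
            )
        split, groups = match[0]
    if any(len(g) < 1 for g in groups):
        raise TreeError(f"branch {split} has an empty induced subtree")

    taxa = sorted(tip_labels(species_tree))
    bit, prepared = _gene_split_masks(gene_trees, taxa)

    n_combos = int(np.prod([len(g) for g in groups]))
    if n_combos <= max_quartets_per_branch:
        quartets = list(itertools.product(*groups))
    else:
        rng = np.random.default_rng(seed)
        quartets = [
            tuple(g[rng.integers(len(g))] for g in groups)
            for _ in range(max_quartets_per_branch)
        ]

    tally = np.zeros(4, dtype=np.int64)
    for a, b, c, d in quartets:
        masks = (bit[a], bit[b], bit[c], bit[d])
        need = masks[0] | masks[1] | masks[2] | masks[3]
        for present, split_masks in prepared:
            if present & need != need:
                continue
            tally[_quartet_topology(*masks, split_masks)] += 1

    n_inf = int(tally[1:].sum())
    if n_inf > 0:
        q1, q2, q3 = (tally[1:] / n_inf).tolist()
    else:
        q1 = q2 = q3 = 0.0
    return QuartetSupport(
        branch_id=str(split),
        split=split,
        q1=q1,
        q2=q2,
        q3=q3,
        n_informative=n_inf,
        coalescent_length=coalescent_branch_length(q1, cap=length_cap) if n_inf else 0.0,
    )


def quartet_support_table(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
    max_quartets_per_branch: int = 100,
    seed: int = 0,
    length_cap: float = DEFAULT_LENGTH_CAP,
) -> pd.DataFrame:
    """Quartet support for every scorable internal branch, as a table."""
    rows = []
    for idx, _ in enumerate(internal_branches(species_tree)):
        qs = quartet_frequencies(
            species_tree,
            gene_trees,
            idx,
            max_quartets_per_branch=max_quartets_per_branch,
            seed=seed + idx,
            length_cap=length_cap,
        )
        rows.append(
            {
                "branch": qs.branch_id,
                "q1": qs.q1,
                "q2": qs.q2,
                "q3": qs.q3,
                "n_informative": qs.n_informative,
                "coalescent_length": qs.coalescent_length,
            }
        )
    return pd.DataFrame(rows)
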