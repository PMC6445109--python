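"""Bipartition concordance analysis of gene trees against a species tree.

For every internal split of the species tree, each gene tree is scored
as concordant (it contains the species split restricted to the gene's
taxa), conflicting (it contains a split incompatible with the restricted
species split), uninformative (it contains neither — e.g. a polytomy
spans the split), or missing (too few overlapping taxa to decide: fewer
than two on either side of the restricted split).  Conflicting genes'
incompatible splits are pooled to report the most frequent alternative
bipartition per node.

A polytomy asserts nothing incompatible and therefore never counts as
conflict; conflict requires an explicit incompatible split.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import pandas as pd

from .trees import Bipartition, TreeError, extract_splits, tip_labels

__all__ = [
    "NodeConcordance",
    "ConcordanceSummary",
    "node_concordance",
    "dominant_alternative",
]

CATEGORIES = ("concordant", "conflicting", "uninformative", "missing")


def dominant_alternative(
    conflicting_splits: Iterable[Bipartition],
) -> Optional[Tuple[Bipartition, int]]:
    """Most frequent alternative split in a multiset, or None if empty.

    Ties are broken by the canonical (lexicographic) string form of the
    split, so the result is deterministic.
    """
    counts = Counter(conflicting_splits)
    if not counts:
        return None
    best = min(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return best[0], best[1]


@dataclass
class NodeConcordance:
    """Concordance counts for one internal species-tree split."""

    node_id: str
    split: Bipartition
    n_concordant: int
    n_conflicting: int
    n_uninformative: int
    n_missing: int
    dominant_alternative: Optional[Bipartition]
    dominant_count: int

    @property
    def total(self) -> int:
        return (
            self.n_concordant + self.n_conflicting + self.n_uninformative + self.n_missing
        )


@dataclass
class ConcordanceSummary:
    """Per-node concordance table over a fixed set of gene trees."""

    nodes: List[NodeConcordance]
    n_genes: int

    def __post_init__(self):
        for node in self.nodes:
            if node.total != self.n_genes:
                raise TreeError(
                    f"count conservation violated at {node.node_id}: "
                    f"{node.total} != {self.n_genes}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": [n.node_id for n in self.nodes],
                "split": [str(n.split) for n in self.nodes],
                "concordant": [n.n_concordant for n in self.nodes],
                "conflicting": [n.n_conflicting for n in self.nodes],
                "uninformative": [n.n_uninformative for n in self.nodes],
                "missing": [n.n_missing for n in self.nodes],
                "dominant_alternative": [
                    str(n.dominant_alternative) if n.dominant_alternative else ""
                    for n in self.nodes
                ],
                "dominant_count": [n.dominant_count for n in self.nodes],
            }
        )

    def as_dict(self) -> Dict[str, object]:
        return {
            "n_genes": self.n_genes,
            "nodes": self.to_dataframe().to_dict(orient="records"),
        }


def _score_gene(
    species_split: Bipartition,
    gene_taxa: frozenset,
    gene_splits: Sequence[Bipartition],
) -> Tuple[str, List[Bipartition]]:
    restricted = species_split.restrict(gene_taxa)
    if (
        restricted is None
        or len(restricted.side) < 2
        or len(restricted.other_side) < 2
    ):
        return "missing", []
    conflicts = []
    for g in gene_splits:
        if g == restricted:
            return "concordant", []
        if g.conflicts_with(restricted):
            conflicts.append(g)
    if conflicts:
        return "conflicting", conflicts
    return "uninformative", []


def node_concordance(
    species_tree: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
) -> ConcordanceSummary:
    """Score every internal species-tree split against all gene trees.

    Gene-tree tips (after paralog reduction) must be a subset of the
    species-tree tips.  Each conflicting gene contributes each of its
    distinct incompatible splits once to the alternative tally; pooled
    alternatives are compared by canonical form.
    """
    species_taxa = tip_labels(species_tree)
    species_splits = sorted(extract_splits(species_tree), key=str)
    if not gene_trees:
        raise TreeError("no gene trees supplied")

    genes = []
    for k, gt in enumerate(gene_trees):
        gtaxa = tip_labels(gt)
        extra = gtaxa - species_taxa
        if extra:
            raise TreeError(
                f"gene tree {k} has tips not in the species tree: {sorted(extra)}"
            )
        genes.append((gtaxa, sorted(extract_splits(gt), key=str)))

    nodes = []
    for idx, split in enumerate(species_splits):
        counts = dict.fromkeys(CATEGORIES, 0)
        alternatives: Counter = Counter()
        for gtaxa, gsplits in genes:
            category, conflicts = _score_gene(split, gtaxa, gsplits)
            counts[category] += 1
            for c in set(conflicts):
                alternatives[c] += 1
        best = dominant_alternative(list(alternatives.elements()))
        nodes.append(
            NodeConcordance(
                node_id=f"node{idx + 1}",
                split=split,
                n_concordant=counts["concordant"],
                n_conflicting=counts["conflicting"],
                n_uninformative=counts["uninformative"],
                n_missing=counts["missing"],
                dominant_alternative=best[0] if best else None,
                dominant_count=best[1] if best else 0,
            )
        )
    return ConcordanceSummary(nodes=nodes, n_genes=len(gene_trees))
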