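"""Type I / Type II paralog classification and gene retention rules.

Target-capture assemblies can return several gene copies per species.
On a gene tree whose tips are ``species<delim><copy>`` labels, copies of
one species that form a clade on the *unrooted* tree are Type I paralogs
(recent duplicates or alleles); copies that do not are Type II paralogs
(ancient gene or genome duplications).  The retention rules are:

* all multi-copy species Type I  -> keep the gene, one random copy per
  such species (seeded);
* Type II paralogs in 1..threshold species (default 5) -> keep the gene,
  remove every copy of those species (Type I species still reduced to a
  single random copy);
* Type II paralogs in more than threshold species -> drop the gene.

Monophyly is assessed on the unrooted tree so that an arbitrary root
placement cannot change a species' paralog type; two copies adjacent
across the root are therefore Type I.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import dendropy
import numpy as np

from .alignments import CodonAlignment
from .trees import TreeError, copy_tree, edge_leafsets, tip_labels

__all__ = [
    "ParalogError",
    "ParalogReport",
    "parse_tip_label",
    "species_copies",
    "classify_paralogs",
    "apply_retention_rules",
    "apply_report_to_tree",
    "apply_report_to_alignment",
    "has_abnormal_internal_branch",
    "filter_gene",
]

SINGLE = "single-copy"
TYPE_I = "Type I"
TYPE_II = "Type II"


class ParalogError(ValueError):
    """Raised for unparseable tip labels or inconsistent reports."""


def parse_tip_label(label: str, copy_delimiter: str = ".") -> Tuple[str, Optional[str]]:
    """Split a tip label into (species, copy suffix).

    A label without the delimiter is a bare species id.  With the
    delimiter, the text after its last occurrence must be a copy index
    (digits); otherwise the label is unparseable.
    """
    if not label:
        raise ParalogError("empty tip label")
    if copy_delimiter not in label:
        return label, None
    species, _, suffix = label.rpartition(copy_delimiter)
    if not species or not suffix.isdigit():
        raise ParalogError(
            f"cannot parse tip label {label!r} into species{copy_delimiter}copy"
        )
    return species, suffix


def species_copies(tree: dendropy.Tree, copy_delimiter: str = ".") -> Dict[str, List[str]]:
    """Map species id -> sorted list of its tip labels."""
    copies: Dict[str, List[str]] = {}
    for leaf in tree.leaf_node_iter():
        species, _ = parse_tip_label(leaf.taxon.label, copy_delimiter)
        copies.setdefault(species, []).append(leaf.taxon.label)
    return {s: sorted(labs) for s, labs in copies.items()}


def classify_paralogs(tree: dendropy.Tree, copy_delimiter: str = ".") -> Dict[str, str]:
    """Per-species classification into single-copy / Type I / Type II.

    A multi-copy species is Type I iff some edge of the unrooted tree
    separates exactly that species' copies from everything else
    (equivalently, the copy set or its complement is an edge leaf set).
    """
    copies = species_copies(tree, copy_delimiter)
    tips = tip_labels(tree)
    leafsets = set(edge_leafsets(tree))
    classification = {}
    for species, labels in copies.items():
        if len(labels) == 1:
            classification[species] = SINGLE
            continue
        group = frozenset(labels)
        mono = group in leafsets or (tips - group) in leafsets
        classification[species] = TYPE_I if mono else TYPE_II
    return classification


@dataclass
class ParalogReport:
    """Outcome of the retention rules for one gene."""

    gene: str
    classification: Dict[str, str]
    action: str  # keep_as_is | keep_random_copy | prune_type2_taxa | drop_gene
    pruned_species: List[str]
    chosen_copies: Dict[str, str]  # Type I species -> retained tip label
    type2_taxon_threshold: int
    seed: int

    def __post_init__(self):
        n_type2 = sum(1 for t in self.classification.values() if t == TYPE_II)
        if (self.action == "drop_gene") != (n_type2 > self.type2_taxon_threshold):
            raise ParalogError(
                f"inconsistent report for {self.gene}: {n_type2} Type II species "
                f"with threshold {self.type2_taxon_threshold} but action {self.action}"
            )
        if (self.action == "prune_type2_taxa") != (
            0 < n_type2 <= self.type2_taxon_threshold
        ):
            raise ParalogError(f"inconsistent pruning action for {self.gene}")
        if bool(self.pruned_species) != (self.action == "prune_type2_taxa"):
            raise ParalogError(
                f"pruned list must be non-empty iff action is prune_type2_taxa "
                f"({self.gene})"
            )


def apply_retention_rules(
    classification: Dict[str, str],
    copies: Dict[str, List[str]],
    gene: str = "gene",
    type2_taxon_threshold: int = 5,
    seed: int = 0,
) -> ParalogReport:
    """Decide the gene's fate and pick retained copies (seeded).

    ``copies`` is the ``species_copies`` map for the same tree.  The
    random copy for each Type I species is drawn uniformly with a
    dedicated generator, so the same seed always selects the same copies.
    """
    rng = np.random.default_rng(seed)
    type2 = sorted(s for s, t in classification.items() if t == TYPE_II)
    type1 = sorted(s for s, t in classification.items() if t == TYPE_I)
    chosen = {}
    for s in type1:
        labels = copies[s]
        chosen[s] = labels[int(rng.integers(len(labels)))]
    if len(type2) > type2_taxon_threshold:
        action = "drop_gene"
        pruned: List[str] = []
        chosen = {}
    elif type2:
        action = "prune_type2_taxa"
        pruned = type2
    elif type1:
        action = "keep_random_copy"
        pruned = []
    else:
        action = "keep_as_is"
        pruned = []
    return ParalogReport(
        gene=gene,
        classification=classification,
        action=action,
        pruned_species=pruned,
        chosen_copies=chosen,
        type2_taxon_threshold=type2_taxon_threshold,
        seed=seed,
    )


def _retained_labels(report: ParalogReport, copies: Dict[str, List[str]]):
    """(kept tip labels, rename map tip label -> bare species id)."""
    keep, rename = [], {}
    for species, labels in copies.items():
        if species in report.pruned_species:
            continue
        if report.classification.get(species) == TYPE_I:
            label = report.chosen_copies[species]
            keep.append(label)
            rename[label] = species
        else:
            keep.append(labels[0])
            if labels[0] != species:
                rename[labels[0]] = species
    return keep, rename


def apply_report_to_tree(
    tree: dendropy.Tree, report: ParalogReport, copy_delimiter: str = "."
) -> Optional[dendropy.Tree]:
    """Filtered gene tree with one tip per retained species (or None if
    the gene is dropped).  Retained copies are relabelled to bare species
    ids."""
    if report.action == "drop_gene":
        return None
    copies = species_copies(tree, copy_delimiter)
    keep, rename = _retained_labels(report, copies)
    out = copy_tree(tree)
    if set(keep) != tip_labels(out):
        from .trees import prune_to_taxa

        out = prune_to_taxa(out, keep)
    for leaf in out.leaf_node_iter():
        if leaf.taxon.label in rename:
            leaf.taxon.label = rename[leaf.taxon.label]
    return out


def apply_report_to_alignment(
    aln: CodonAlignment, report: ParalogReport, copy_delimiter: str = "."
) -> Optional[CodonAlignment]:
    if report.action == "drop_gene":
        return None
    copies: Dict[str, List[str]] = {}
    for t in aln.ids:
        species, _ = parse_tip_label(t, copy_delimiter)
        copies.setdefault(species, []).append(t)
    copies = {s: sorted(v) for s, v in copies.items()}
    keep, rename = _retained_labels(report, copies)
    return aln.select_taxa(keep).rename_taxa(rename)


def has_abnormal_internal_branch(tree: dendropy.Tree, fold: float = 10.0) -> bool:
    """Optional orthology screen: flag trees where some internal branch
    exceeds ``fold`` times the median internal branch length.  The fold
    default is a labelled guess; the filter is off by default in the
    pipeline."""
    internal = [
        n.edge.length
        for n in tree.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf() and n.edge.length is not None
    ]
    if len(internal) < 2:
        return False
    med = float(np.median(internal))
    if med <= 0:
        return False
    return max(internal) > fold * med


def filter_gene(
    tree: dendropy.Tree,
    alignment: Optional[CodonAlignment] = None,
    gene: str = "gene",
    copy_delimiter: str = ".",
    type2_taxon_threshold: int = 5,
    seed: int = 0,
):
    """Classify, decide, and apply in one call.

    Returns ``(report, filtered_tree, filtered_alignment)``; the latter
    two are None when the gene is dropped.
    """
    classification = classify_paralogs(tree, copy_delimiter)
    copies = species_copies(tree, copy_delimiter)
    report = apply_retention_rules(
        classification,
        copies,
        gene=gene,
        type2_taxon_threshold=type2_taxon_threshold,
        seed=seed,
    )
    new_tree = apply_report_to_tree(tree, report, copy_delimiter)
    new_aln = (
        apply_report_to_alignment(alignment, report, copy_delimiter)
        if alignment is not None and new_tree is not None
        else None
    )
    return report, new_tree, new_aln
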