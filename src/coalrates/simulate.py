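"""Synthetic gene trees, codon alignments, paralogs, and missing data.

This module makes every downstream stage testable at desk scale without
any external download.  It provides:

* a multispecies-coalescent (MSC) simulator producing gene trees for one
  haploid sample per species, with species-tree branch lengths in
  coalescent units (time scaled by 2N generations) — lineage pairs
  coalesce at rate 1 per pair per unit within each branch;
* an M0 codon-sequence simulator (no indels, no stop codons);
* paralog injection (Type I: a sister copy of the species' own tip;
  Type II: a copy attached elsewhere in the tree);
* a three-compartment benchmark whose generating parameters imply exact
  mt:pt:nu dS and dN tree-depth ratio triples, plus whole-taxon locus
  dropout to emulate target-capture missingness.

All generators are seed-deterministic: the same configuration yields
byte-identical newick and FASTA output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from . import codon as _codon
from .alignments import CodonAlignment
from .codon import (
    CODONS,
    COMPARTMENTS,
    _Spectral,
    build_codon_rate_matrix,
    flat_frequencies,
    flux_proportions,
    _check_freqs,
)
from .trees import TreeError, copy_tree, read_tree, tip_labels, write_tree

__all__ = [
    "SimulationError",
    "SimulationConfig",
    "CompartmentParams",
    "BenchmarkLocus",
    "CompartmentBenchmark",
    "balanced_species_tree",
    "simulate_msc_gene_trees",
    "simulate_codon_alignment",
    "inject_paralogs",
    "make_compartment_benchmark",
]


class SimulationError(ValueError):
    """Raised for invalid simulation configuration."""


def balanced_species_tree(n_taxa: int = 16, edge_length: float = 1.0) -> str:
    """A balanced rooted binary species tree with uniform branch lengths."""
    if n_taxa < 2:
        raise SimulationError("need at least 2 taxa")
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]

    def build(block: List[str]) -> str:
        if len(block) == 1:
            return f"{block[0]}:{edge_length}"
        mid = (len(block) + 1) // 2
        return f"({build(block[:mid])},{build(block[mid:])}):{edge_length}"

    mid = (n_taxa + 1) // 2
    return f"({build(labels[:mid])},{build(labels[mid:])});"


# ---------------------------------------------------------------------------
# multispecies coalescent
# ---------------------------------------------------------------------------


def _node_ages(tree: dendropy.Tree) -> Dict[int, float]:
    ages: Dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            ages[id(node)] = max(
                ages[id(c)] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return ages


def _validate_species_tree(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            raise SimulationError(
                "species tree must be binary and rooted; found a node with "
                f"{len(node.child_nodes())} children"
            )


def _coalesce_one(
    species_tree: dendropy.Tree,
    ages: Dict[int, float],
    rng: np.random.Generator,
) -> dendropy.Tree:
    namespace = dendropy.TaxonNamespace()
    pools: Dict[int, List[Tuple[dendropy.Node, float]]] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            leaf = dendropy.Node()
            leaf.taxon = namespace.new_taxon(label=node.taxon.label)
            pool = [(leaf, 0.0)]
        else:
            pool = []
            for child in node.child_nodes():
                pool.extend(pools.pop(id(child)))
        start = ages[id(node)]
        at_root = node.parent_node is None
        end = np.inf if at_root else start + (node.edge.length or 0.0)
        tau = start
        while len(pool) >= 2:
            k = len(pool)
            tau += rng.exponential(1.0 / (k * (k - 1) / 2.0))
            if tau > end:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            node_j, age_j = pool.pop(j)
            node_i, age_i = pool.pop(i)
            parent = dendropy.Node()
            parent.add_child(node_i)
            node_i.edge.length = tau - age_i
            parent.add_child(node_j)
            node_j.edge.length = tau - age_j
            pool.append((parent, tau))
        pools[id(node)] = pool
    (root, _), = pools[id(species_tree.seed_node)]
    gene_tree = dendropy.Tree(taxon_namespace=namespace)
    gene_tree.seed_node = root
    gene_tree.is_rooted = True
    for n in gene_tree.preorder_node_iter():
        n.support = None
    return gene_tree


def simulate_msc_gene_trees(
    species_tree: Union[str, dendropy.Tree],
    n_genes: int,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> List[dendropy.Tree]:
    """Independent gene trees under the MSC, one haploid sample per species.

    Species-tree branch lengths are in coalescent units (2N generations).
    Lineages that fail to coalesce within a branch are handed to the
    parent branch; the root branch extends to infinity.
    """
    if isinstance(species_tree, str):
        species_tree = read_tree(species_tree)
    _validate_species_tree(species_tree)
    if n_genes < 1:
        raise SimulationError(f"n_genes must be >= 1, got {n_genes}")
    if rng is None:
        rng = np.random.default_rng(seed)
    ages = _node_ages(species_tree)
    return [_coalesce_one(species_tree, ages, rng) for _ in range(n_genes)]


# ---------------------------------------------------------------------------
# codon sequence evolution
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: dendropy.Tree,
    kappa: float,
    omega: float,
    codon_freqs: Optional[np.ndarray] = None,
    length_codons: int = 300,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    locus: str = "locus",
    compartment: Optional[str] = None,
) -> CodonAlignment:
    """Evolve codon sequences along a tree under M0.

    Branch lengths are expected substitutions per codon.  The root codon
    at each site is drawn from the equilibrium frequencies and evolved
    down every branch with the exact transition probabilities, so the
    output contains no stop codons and no indels.
    """
    if length_codons < 1:
        raise SimulationError(f"length_codons must be >= 1, got {length_codons}")
    pi = _check_freqs(codon_freqs if codon_freqs is not None else flat_frequencies())
    if rng is None:
        rng = np.random.default_rng(seed)
    q = build_codon_rate_matrix(kappa, omega, pi)
    spec = _Spectral(q, pi)

    states: Dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = rng.choice(len(CODONS), size=length_codons, p=pi)
            continue
        t = node.edge.length
        if t is None:
            raise SimulationError("tree has branches without lengths")
        p = spec.prob(float(t))
        p = p / p.sum(axis=1, keepdims=True)
        parent_states = states[id(node.parent_node)]
        child = np.empty(length_codons, dtype=np.int64)
        for s in np.unique(parent_states):
            mask = parent_states == s
            child[mask] = rng.choice(len(CODONS), size=int(mask.sum()), p=p[s])
        states[id(node)] = child

    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        seqs.append("".join(CODONS[s] for s in states[id(leaf)]))
    return CodonAlignment(ids=ids, seqs=seqs, locus=locus, compartment=compartment)


# ---------------------------------------------------------------------------
# paralog injection
# ---------------------------------------------------------------------------


def _mean_tip_edge(tree: dendropy.Tree) -> float:
    lengths = [
        leaf.edge.length for leaf in tree.leaf_node_iter() if leaf.edge.length is not None
    ]
    return float(np.mean(lengths)) if lengths else 1.0


def _attach_copy(tree: dendropy.Tree, edge_node: dendropy.Node, label: str,
                 pendant: float) -> None:
    """Insert a new node halfway along the edge above ``edge_node`` and
    hang a new tip off it."""
    parent = edge_node.parent_node
    length = edge_node.edge.length
    half = None if length is None else 0.5 * length
    parent.remove_child(edge_node)
    joint = dendropy.Node()
    parent.add_child(joint)
    joint.edge.length = half
    joint.support = None
    joint.add_child(edge_node)
    edge_node.edge.length = half
    new_tip = dendropy.Node()
    new_tip.taxon = tree.taxon_namespace.new_taxon(label=label)
    joint.add_child(new_tip)
    new_tip.edge.length = pendant


def inject_paralogs(
    gene_tree: dendropy.Tree,
    species: str,
    paralog_type: str,
    seed: int = 0,
    copy_delimiter: str = ".",
) -> dendropy.Tree:
    """Add a second gene copy for one species.

    Type I attaches the copy as sister to the species' existing tip
    (mimicking a recent duplicate or allele); Type II attaches it to an
    edge at least two nodes away from the tip (an ancient duplication),
    and the attachment is verified to classify as Type II on the unrooted
    tree.  Both copies are relabelled ``species<delim>1`` and
    ``species<delim>2``.  The tip count increases by exactly one.
    """
    from .paralogs import classify_paralogs  # local import avoids a cycle

    if paralog_type not in ("I", "II"):
        raise SimulationError(f"paralog_type must be 'I' or 'II', got {paralog_type!r}")
    if species not in tip_labels(gene_tree):
        raise SimulationError(f"species {species!r} not present in the gene tree")
    rng = np.random.default_rng(seed)
    label1 = f"{species}{copy_delimiter}1"
    label2 = f"{species}{copy_delimiter}2"
    base = write_tree(gene_tree)

    if paralog_type == "I":
        out = read_tree(base)
        tip = next(l for l in out.leaf_node_iter() if l.taxon.label == species)
        length = tip.edge.length
        half = None if length is None else 0.5 * length
        parent = tip.parent_node
        parent.remove_child(tip)
        joint = dendropy.Node()
        joint.support = None
        parent.add_child(joint)
        joint.edge.length = half
        joint.add_child(tip)
        tip.edge.length = half
        tip.taxon.label = label1
        new_tip = dendropy.Node()
        new_tip.taxon = out.taxon_namespace.new_taxon(label=label2)
        joint.add_child(new_tip)
        new_tip.edge.length = half
        return out

    # Type II: try candidate edges in seeded random order, keeping the
    # first attachment that classifies as Type II on the unrooted tree.
    template = read_tree(base)
    nodes = list(template.preorder_node_iter())
    tip_idx = next(
        i for i, n in enumerate(nodes) if n.is_leaf() and n.taxon.label == species
    )
    tip_node = nodes[tip_idx]
    parent_ids = {id(tip_node), id(tip_node.parent_node)}
    candidates = [
        i
        for i, n in enumerate(nodes)
        if n.parent_node is not None
        and id(n) not in parent_ids
        and id(n.parent_node) not in {id(tip_node)}
    ]
    if not candidates:
        raise SimulationError("tree too small for a Type II attachment")
    for k in rng.permutation(len(candidates)):
        out = read_tree(base)
        out_nodes = list(out.preorder_node_iter())
        target = out_nodes[candidates[k]]
        _attach_copy(out, target, label2, _mean_tip_edge(out))
        tip = next(l for l in out.leaf_node_iter() if l.taxon.label == species)
        tip.taxon.label = label1
        classes = classify_paralogs(out, copy_delimiter=copy_delimiter)
        if classes.get(species) == "Type II":
            return out
    raise SimulationError(
        f"no attachment point yields a Type II paralog for {species!r}"
    )


# ---------------------------------------------------------------------------
# compartment benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentParams:
    """Generating M0 parameters for one genomic compartment."""

    kappa: float
    omega: float
    depth_scaling: float  # branch-length multiplier relative to mt


@dataclass
class SimulationConfig:
    """Conditions for the three-compartment rate benchmark.

    ``ds_ratios`` / ``dn_ratios`` are the target mt:pt:nu tree-depth
    ratio triples (mt entry must be exactly 1).  Per-compartment omega
    and branch scalings are derived from them so that the generating
    parameters imply the configured triples exactly:
    omega_c = omega_mt * (dn_c / ds_c) and the branch scaling compensates
    for the omega-dependence of the synonymous substitution fraction.
    ``base_rate`` converts the species tree's coalescent-unit branch
    lengths to mitochondrial substitutions per codon.
    """

    species_tree: Optional[str] = None
    n_genes: int = 10
    codon_length: int = 300
    kappa: float = 2.0
    omega_mt: float = 0.4
    ds_ratios: Tuple[float, float, float] = (1.0, 5.7, 7.4)
    dn_ratios: Tuple[float, float, float] = (1.0, 1.3, 4.2)
    base_rate: float = 0.03
    missing_fraction: float = 0.0
    seed: int = 0
    copy_delimiter: str = "."

    def __post_init__(self):
        if self.species_tree is None:
            self.species_tree = balanced_species_tree(16, 1.0)
        if self.n_genes < 1:
            raise SimulationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.codon_length < 1:
            raise SimulationError(f"codon_length must be >= 1, got {self.codon_length}")
        if not self.kappa > 0 or not self.omega_mt > 0:
            raise SimulationError("kappa and omega_mt must be > 0")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise SimulationError(
                f"missing_fraction must be in [0, 1), got {self.missing_fraction}"
            )
        for name, triple in (("ds_ratios", self.ds_ratios), ("dn_ratios", self.dn_ratios)):
            if len(triple) != 3 or triple[0] != 1:
                raise SimulationError(
                    f"{name} must be a triple starting at exactly 1, got {triple}"
                )
            if any(r <= 0 for r in triple):
                raise SimulationError(f"{name} entries must be positive")

    def m0_params(self) -> Dict[str, CompartmentParams]:
        pi = flat_frequencies()

        def rho_s(omega: float) -> float:
            q = build_codon_rate_matrix(self.kappa, omega, pi)
            return flux_proportions(q, pi)[0]

        rho_mt = rho_s(self.omega_mt)
        params = {}
        for comp, ds, dn in zip(COMPARTMENTS, self.ds_ratios, self.dn_ratios):
            omega_c = self.omega_mt * dn / ds
            scaling = ds * rho_mt / rho_s(omega_c)
            params[comp] = CompartmentParams(
                kappa=self.kappa, omega=omega_c, depth_scaling=scaling
            )
        return params


@dataclass
class BenchmarkLocus:
    locus: str
    compartment: str
    tree: dendropy.Tree       # branch lengths in substitutions/codon
    alignment: CodonAlignment


@dataclass
class CompartmentBenchmark:
    """Per-compartment loci plus the true generating ratio triples."""

    loci: Dict[str, List[BenchmarkLocus]]
    true_depth_ratios_ds: Tuple[float, float, float]
    true_depth_ratios_dn: Tuple[float, float, float]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        for name, triple in (
            ("true_depth_ratios_ds", self.true_depth_ratios_ds),
            ("true_depth_ratios_dn", self.true_depth_ratios_dn),
        ):
            if triple[0] != 1:
                raise SimulationError(f"{name} must start at exactly 1, got {triple}")

    def all_loci(self) -> List[BenchmarkLocus]:
        return [loc for comp in COMPARTMENTS for loc in self.loci[comp]]

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for loc in self.all_loci():
            (outdir / f"{loc.locus}.nwk").write_text(write_tree(loc.tree))
            with open(outdir / f"{loc.locus}.fasta", "w") as fh:
                loc.alignment.to_fasta(fh)
        with open(outdir / "benchmark.json", "w") as fh:
            json.dump(
                {
                    "true_depth_ratios_ds": list(self.true_depth_ratios_ds),
                    "true_depth_ratios_dn": list(self.true_depth_ratios_dn),
                    "metadata": self.metadata,
                },
                fh,
                indent=2,
            )
        with open(outdir / "compartments.tsv", "w") as fh:
            fh.write("locus\tcompartment\n")
            for loc in self.all_loci():
                fh.write(f"{loc.locus}\t{loc.compartment}\n")


def make_compartment_benchmark(config: SimulationConfig) -> CompartmentBenchmark:
    """Generate the three-compartment rate benchmark.

    Every locus in compartment ``c`` evolves on the species-tree topology
    with branch lengths ``coalescent_length * base_rate * depth_scaling_c``
    (substitutions per codon) under M0 with the compartment's omega, so
    the generating parameters imply the configured dS and dN depth-ratio
    triples exactly; only the sequence simulation is stochastic.  Missing
    data is injected as whole-taxon locus dropout with an exact global
    cell budget of ``missing_fraction``.
    """
    species = read_tree(config.species_tree)
    params = config.m0_params()
    rng = np.random.default_rng(config.seed)
    pi = flat_frequencies()

    loci: Dict[str, List[BenchmarkLocus]] = {c: [] for c in COMPARTMENTS}
    n_taxa = len(tip_labels(species))
    for comp in COMPARTMENTS:
        par = params[comp]
        for g in range(config.n_genes):
            tree = copy_tree(species)
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length = (
                        (node.edge.length or 0.0) * config.base_rate * par.depth_scaling
                    )
            locus_id = f"{comp}_{g + 1:03d}"
            aln = simulate_codon_alignment(
                tree,
                kappa=par.kappa,
                omega=par.omega,
                codon_freqs=pi,
                length_codons=config.codon_length,
                rng=rng,
                locus=locus_id,
                compartment=comp,
            )
            loci[comp].append(
                BenchmarkLocus(locus=locus_id, compartment=comp, tree=tree, alignment=aln)
            )

    # whole-taxon locus dropout with an exact global cell budget
    all_loci = [loc for comp in COMPARTMENTS for loc in loci[comp]]
    n_cells = len(all_loci) * n_taxa
    budget = int(round(config.missing_fraction * n_cells))
    dropped = 0
    if budget > 0:
        taxa_sorted = sorted(tip_labels(species))
        cells = [(i, t) for i in range(len(all_loci)) for t in taxa_sorted]
        removed: Dict[int, set] = {i: set() for i in range(len(all_loci))}
        max_drop = n_taxa - 4  # keep every locus analysable
        for k in rng.permutation(len(cells)):
            if dropped >= budget:
                break
            i, taxon = cells[k]
            if len(removed[i]) >= max_drop:
                continue
            removed[i].add(taxon)
            dropped += 1
        from .trees import prune_to_taxa

        for i, loc in enumerate(all_loci):
            if not removed[i]:
                continue
            keep = sorted(set(loc.alignment.ids) - removed[i])
            loc.alignment = loc.alignment.select_taxa(keep)
            loc.tree = prune_to_taxa(loc.tree, keep)

    metadata = {
        "n_genes_per_compartment": config.n_genes,
        "codon_length": config.codon_length,
        "n_taxa": n_taxa,
        "kappa": config.kappa,
        "base_rate": config.base_rate,
        "seed": config.seed,
        "compartment_params": {
            c: {"kappa": p.kappa, "omega": p.omega, "depth_scaling": p.depth_scaling}
            for c, p in params.items()
        },
        "requested_missing_fraction": config.missing_fraction,
        "realized_missing_fraction": dropped / n_cells,
    }
    return CompartmentBenchmark(
        loci=loci,
        true_depth_ratios_ds=tuple(config.ds_ratios),
        true_depth_ratios_dn=tuple(config.dn_ratios),
        metadata=metadata,
    )
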