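"""Configuration-driven orchestration of the analysis stages.

Two pipelines are provided.  The conflict pipeline runs
support-collapsing -> paralog filtering -> bipartition concordance ->
quartet support against a fixed species tree.  The rates pipeline runs
stop-codon masking -> outgroup pruning -> per-locus M0 fitting -> dS/dN
tree depths -> cross-compartment ratio triples.  Either pipeline can
read its inputs from disk or generate them with the synthetic module
(``simulate`` block in the config).  All randomness flows from one root
seed; every report embeds the config hash and seed, and reports contain
no timestamps so identical configs yield byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .alignments import CodonAlignment, replace_stop_codons
from .codon import ds_dn_tree_depth, fit_m0, genome_rate_ratios
from .concordance import node_concordance
from .paralogs import filter_gene
from .quartets import quartet_support_table
from .simulate import SimulationConfig, make_compartment_benchmark, simulate_msc_gene_trees
from .trees import collapse_low_support, prune_to_taxa, read_tree, tip_labels, write_tree

__all__ = ["PipelineError", "RunConfig", "run_conflict_pipeline", "run_rates_pipeline"]

TREE_SUFFIXES = (".nwk", ".tre", ".newick", ".tree")


class PipelineError(ValueError):
    """Raised for invalid run configuration or unreadable input."""


@dataclass
class RunConfig:
    """Declarative run configuration.

    Exactly one of the file-input fields (``gene_trees_dir`` etc.) or the
    ``simulate`` block must be provided.  Threshold defaults follow the
    conventions used throughout: bootstrap collapsing below 33% and a
    five-taxon Type II retention limit.
    """

    outdir: str = "coalrates_out"
    seed: int = 0
    species_tree_path: Optional[str] = None
    gene_trees_dir: Optional[str] = None
    alignments_dir: Optional[str] = None
    compartment_map_path: Optional[str] = None
    simulate: Optional[Dict] = None
    bootstrap_collapse: float = 33.0
    type2_taxon_threshold: int = 5
    copy_delimiter: str = "."
    max_quartets_per_branch: int = 100
    outgroups: List[str] = field(default_factory=list)
    drop_abnormal_branches: bool = False
    freqs: str = "f3x4"

    def __post_init__(self):
        has_files = self.gene_trees_dir is not None or self.alignments_dir is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise PipelineError(
                "exactly one of file inputs (gene_trees_dir/alignments_dir) "
                "or a simulate block must be configured"
            )
        if not 0.0 <= self.bootstrap_collapse <= 100.0:
            raise PipelineError("bootstrap_collapse must be within [0, 100]")
        if self.type2_taxon_threshold < 0:
            raise PipelineError("type2_taxon_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def as_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _log(outdir: Path, lines: Sequence[str]) -> None:
    with open(outdir / "run.log", "a") as fh:
        for line in lines:
            fh.write(line + "\n")


def _load_gene_trees(config: RunConfig):
    directory = Path(config.gene_trees_dir)
    if not directory.is_dir():
        raise PipelineError(f"gene tree directory not found: {directory}")
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in TREE_SUFFIXES
    )
    if not paths:
        raise PipelineError(f"no gene trees found in {directory}")
    trees = []
    for p in paths:
        try:
            trees.append((p.stem, read_tree(p.read_text())))
        except Exception as exc:
            raise PipelineError(f"unreadable gene tree {p}: {exc}") from exc
    return trees


def _conflict_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        newick = sim.get("species_tree")
        if newick is None:
            raise PipelineError("simulate block needs a species_tree newick")
        species_tree = read_tree(newick)
        n_genes = int(sim.get("n_genes", 100))
        gene_trees = simulate_msc_gene_trees(
            species_tree, n_genes, seed=config.seed
        )
        named = [(f"gene{i + 1:04d}", t) for i, t in enumerate(gene_trees)]
        return species_tree, named
    if config.species_tree_path is None:
        raise PipelineError("species_tree_path is required for the conflict pipeline")
    species_path = Path(config.species_tree_path)
    if not species_path.is_file():
        raise PipelineError(f"species tree not found: {species_path}")
    return read_tree(species_path.read_text()), _load_gene_trees(config)


def run_conflict_pipeline(config: RunConfig) -> Dict[str, object]:
    """Collapse -> paralog filter -> concordance -> quartet support."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_tree, named_trees = _conflict_inputs(config)

    paralog_rows = []
    filtered = []
    for i, (name, tree) in enumerate(named_trees):
        collapsed = collapse_low_support(tree, config.bootstrap_collapse)
        report, new_tree, _ = filter_gene(
            collapsed,
            gene=name,
            copy_delimiter=config.copy_delimiter,
            type2_taxon_threshold=config.type2_taxon_threshold,
            seed=config.seed + i,
        )
        paralog_rows.append(
            {
                "gene": name,
                "action": report.action,
                "pruned_taxa": ",".join(report.pruned_species),
                "species_types": ";".join(
                    f"{s}:{t}" for s, t in sorted(report.classification.items())
                    if t != "single-copy"
                ),
            }
        )
        if new_tree is not None:
            filtered.append(new_tree)
    if not filtered:
        raise PipelineError("all gene trees were dropped by the paralog filter")

    summary = node_concordance(species_tree, filtered)
    quartets = quartet_support_table(
        species_tree,
        filtered,
        max_quartets_per_branch=config.max_quartets_per_branch,
        seed=config.seed,
    )

    pd.DataFrame(paralog_rows).to_csv(outdir / "paralog_report.tsv", sep="\t", index=False)
    summary.to_dataframe().to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    with open(outdir / "concordance.json", "w") as fh:
        json.dump(
            {"config_hash": config.config_hash(), "seed": config.seed,
             **summary.as_dict()},
            fh, indent=2,
        )
    quartets.to_csv(outdir / "quartets.tsv", sep="\t", index=False)
    _log(
        outdir,
        [
            f"coalrates {__version__} conflict pipeline",
            f"config_hash={config.config_hash()} seed={config.seed}",
            f"genes_in={len(named_trees)} genes_retained={len(filtered)}",
            f"bootstrap_collapse={config.bootstrap_collapse} "
            f"type2_taxon_threshold={config.type2_taxon_threshold}",
        ],
    )
    return {
        "species_tree": species_tree,
        "gene_trees": filtered,
        "concordance": summary,
        "quartets": quartets,
        "paralog_reports": paralog_rows,
    }


def _rates_inputs(config: RunConfig):
    if config.simulate is not None:
        sim_cfg = SimulationConfig(
            **{**{"seed": config.seed}, **dict(config.simulate)}
        )
        bench = make_compartment_benchmark(sim_cfg)
        return [
            (loc.locus, loc.compartment, loc.tree, loc.alignment)
            for loc in bench.all_loci()
        ]
    if config.alignments_dir is None or config.compartment_map_path is None:
        raise PipelineError(
            "rates pipeline needs alignments_dir and compartment_map_path"
        )
    cmap = pd.read_csv(config.compartment_map_path, sep="\t")
    if not {"locus", "compartment"} <= set(cmap.columns):
        raise PipelineError("compartment map must have locus and compartment columns")
    directory = Path(config.alignments_dir)
    loci = []
    for row in cmap.itertuples():
        fasta = directory / f"{row.locus}.fasta"
        nwk = directory / f"{row.locus}.nwk"
        for p in (fasta, nwk):
            if not p.is_file():
                raise PipelineError(f"missing input file: {p}")
        aln = CodonAlignment.from_fasta(str(fasta), locus=row.locus,
                                        compartment=row.compartment)
        tree = read_tree(nwk.read_text())
        loci.append((row.locus, row.compartment, tree, aln))
    if not loci:
        raise PipelineError("compartment map lists no loci")
    return loci


def run_rates_pipeline(config: RunConfig) -> Dict[str, object]:
    """Stop-codon masking -> outgroup pruning -> M0 fits -> depth ratios."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci = _rates_inputs(config)

    records = []
    rows = []
    for locus, comp, tree, aln in loci:
        aln = replace_stop_codons(aln)
        if config.outgroups:
            keep = sorted(set(aln.ids) - set(config.outgroups))
            aln = aln.select_taxa(keep)
            tree = prune_to_taxa(tree, keep)
        fit = fit_m0(aln, tree, freqs=config.freqs)
        rec = ds_dn_tree_depth(fit, locus=locus, compartment=comp)
        records.append(rec)
        rows.append(
            {
                "locus": locus,
                "compartment": comp,
                "ds_depth": rec.ds_depth,
                "dn_depth": rec.dn_depth,
                "omega": fit.omega,
                "kappa": fit.kappa,
                "logL": fit.log_likelihood,
            }
        )
    ratios = genome_rate_ratios(records)

    pd.DataFrame(rows).to_csv(outdir / "gene_rates.tsv", sep="\t", index=False)
    with open(outdir / "rate_ratios.json", "w") as fh:
        json.dump(
            {"config_hash": config.config_hash(), "seed": config.seed,
             "depth_mode": "treelength", **ratios.as_dict()},
            fh, indent=2,
        )
    _log(
        outdir,
        [
            f"coalrates {__version__} rates pipeline",
            f"config_hash={config.config_hash()} seed={config.seed}",
            f"n_loci={len(loci)}",
        ],
    )
    return {"records": records, "ratios": ratios, "per_gene": rows}
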