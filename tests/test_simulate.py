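"""MSC simulator, codon simulator, paralog injection, benchmark generator."""

import numpy as np
import pytest

from coalrates.alignments import STOP_CODONS, missing_fraction
from coalrates.simulate import (
    SimulationConfig,
    SimulationError,
    balanced_species_tree,
    inject_paralogs,
    make_compartment_benchmark,
    simulate_codon_alignment,
    simulate_msc_gene_trees,
)
from coalrates.trees import (
    Bipartition,
    extract_splits,
    read_tree,
    tip_labels,
    write_tree,
)


class TestMSC:
    def test_one_sample_per_species(self):
        species = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        trees = simulate_msc_gene_trees(species, 5, seed=0)
        assert len(trees) == 5
        for t in trees:
            assert tip_labels(t) == frozenset("ABCD")

    def test_nonbinary_species_tree_rejected(self):
        with pytest.raises(SimulationError):
            simulate_msc_gene_trees(read_tree("(A:1,B:1,C:1);"), 5)

    def test_n_genes_validated(self):
        species = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(SimulationError):
            simulate_msc_gene_trees(species, 0)

    def test_seed_determinism_byte_identical(self):
        species = read_tree("((A:1,B:1):2,(C:1,D:1):0.5);")
        a = [write_tree(t) for t in simulate_msc_gene_trees(species, 20, seed=7)]
        b = [write_tree(t) for t in simulate_msc_gene_trees(species, 20, seed=7)]
        assert a == b
        c = [write_tree(t) for t in simulate_msc_gene_trees(species, 20, seed=8)]
        assert a != c

    def test_zero_internal_branch_topologies_uniform(self):
        """t = 0: the three resolved quartet topologies each ~ 1/3."""
        species = read_tree("((A:1,B:1):0.0,(C:1,D:1):0.0);")
        trees = simulate_msc_gene_trees(species, 6000, seed=2)
        counts = {"AB": 0, "AC": 0, "AD": 0}
        for t in trees:
            (split,) = extract_splits(t)
            partner = next(x for x in "BCD" if x in split.side) \
                if "A" in split.side else \
                next(x for x in "BCD" if x not in split.side)
            counts[f"A{partner}"] += 1
        se3 = 3 * np.sqrt((1 / 3) * (2 / 3) / 6000)
        for v in counts.values():
            assert abs(v / 6000 - 1 / 3) < se3

    def test_gene_tree_branch_lengths_nonnegative(self):
        species = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        for t in simulate_msc_gene_trees(species, 50, seed=3):
            for n in t.preorder_node_iter():
                if n.parent_node is not None:
                    assert n.edge.length >= 0


class TestCodonSimulator:
    def test_zero_branch_lengths_identical_sequences(self):
        tree = read_tree("((A:0,B:0):0,(C:0,D:0):0);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=50, seed=1)
        assert len(set(aln.seqs)) == 1

    def test_never_contains_stop_codons(self):
        tree = read_tree("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        aln = simulate_codon_alignment(tree, 2.0, 1.5, length_codons=500, seed=2)
        for seq in aln.seqs:
            codons = {seq[3 * i : 3 * i + 3] for i in range(len(seq) // 3)}
            assert not codons & STOP_CODONS

    def test_bad_frequencies_rejected(self):
        tree = read_tree("(A:0.1,B:0.1);")
        with pytest.raises(Exception, match="frequencies"):
            simulate_codon_alignment(
                tree, 2.0, 0.3, codon_freqs=np.full(61, 0.02), length_codons=10
            )

    def test_seed_determinism(self):
        tree = read_tree("((A:0.2,B:0.2):0.1,C:0.2);")
        a = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=60, seed=5)
        b = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=60, seed=5)
        assert a.to_fasta_text() == b.to_fasta_text()


class TestInjection:
    def test_tip_count_increases_by_one(self, rng):
        tree = read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        for ptype in ("I", "II"):
            out = inject_paralogs(tree, "C", ptype, seed=4)
            assert len(tip_labels(out)) == len(tip_labels(tree)) + 1
            assert {f"C.1", f"C.2"} <= tip_labels(out)

    def test_species_absent_rejected(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(SimulationError):
            inject_paralogs(tree, "Z", "I")

    def test_custom_delimiter(self):
        tree = read_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        out = inject_paralogs(tree, "A", "I", copy_delimiter="_")
        assert {"A_1", "A_2"} <= tip_labels(out)


class TestBenchmark:
    def test_metadata_stores_exact_triples(self):
        cfg = SimulationConfig(n_genes=1, codon_length=30, seed=0)
        bench = make_compartment_benchmark(cfg)
        assert bench.true_depth_ratios_ds == (1.0, 5.7, 7.4)
        assert bench.true_depth_ratios_dn == (1.0, 1.3, 4.2)

    def test_ratio_triple_must_start_at_one(self):
        with pytest.raises(SimulationError):
            SimulationConfig(ds_ratios=(2.0, 5.7, 7.4))

    def test_equal_triples_give_identical_compartment_params(self):
        cfg = SimulationConfig(ds_ratios=(1.0, 1.0, 1.0), dn_ratios=(1.0, 1.0, 1.0))
        params = cfg.m0_params()
        assert params["mt"] == params["pt"] == params["nu"]

    def test_derived_omegas_scale_with_dn_over_ds(self):
        cfg = SimulationConfig()
        params = cfg.m0_params()
        assert params["mt"].omega == 0.4
        assert params["pt"].omega == pytest.approx(0.4 * 1.3 / 5.7)
        assert params["nu"].omega == pytest.approx(0.4 * 4.2 / 7.4)

    def test_seed_determinism(self):
        cfg1 = SimulationConfig(n_genes=2, codon_length=30, seed=9)
        cfg2 = SimulationConfig(n_genes=2, codon_length=30, seed=9)
        b1 = make_compartment_benchmark(cfg1)
        b2 = make_compartment_benchmark(cfg2)
        for l1, l2 in zip(b1.all_loci(), b2.all_loci()):
            assert l1.alignment.to_fasta_text() == l2.alignment.to_fasta_text()
            assert write_tree(l1.tree) == write_tree(l2.tree)

    def test_missing_fraction_realized_within_one_percent(self):
        cfg = SimulationConfig(n_genes=10, codon_length=30,
                               missing_fraction=0.2, seed=3)
        bench = make_compartment_benchmark(cfg)
        n_taxa = bench.metadata["n_taxa"]
        total = 3 * cfg.n_genes * n_taxa
        present = sum(len(l.alignment.ids) for l in bench.all_loci())
        realized = 1.0 - present / total
        assert abs(realized - 0.2) <= 0.01
        assert realized == pytest.approx(bench.metadata["realized_missing_fraction"])

    def test_missing_taxa_removed_from_tree_and_alignment(self):
        cfg = SimulationConfig(n_genes=4, codon_length=30,
                               missing_fraction=0.3, seed=5)
        bench = make_compartment_benchmark(cfg)
        for loc in bench.all_loci():
            assert tip_labels(loc.tree) == frozenset(loc.alignment.ids)
            assert len(loc.alignment.ids) >= 4

    def test_write_bundle(self, tmp_path):
        cfg = SimulationConfig(n_genes=1, codon_length=30, seed=0)
        make_compartment_benchmark(cfg).write(tmp_path)
        assert (tmp_path / "benchmark.json").is_file()
        assert (tmp_path / "compartments.tsv").is_file()
        assert (tmp_path / "mt_001.fasta").is_file()
        assert (tmp_path / "nu_001.nwk").is_file()
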