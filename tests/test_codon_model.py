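"""M0 rate matrix, likelihood (vs enumeration), fitting, and dS/dN depths."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.linalg import expm

from coalrates.alignments import CodonAlignment
from coalrates.codon import (
    CODONS,
    CodonModelError,
    M0Fit,
    M0Likelihood,
    build_codon_rate_matrix,
    _Spectral,
    ds_dn_tree_depth,
    f3x4_frequencies,
    fit_m0,
    flat_frequencies,
    flux_proportions,
    m0_loglik,
    synonymous_site_proportion,
)
from coalrates.simulate import simulate_codon_alignment
from coalrates.trees import read_tree

PI = flat_frequencies()


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", [(2.0, 0.4), (5.0, 1.0), (0.5, 3.0)])
    def test_rows_sum_to_zero(self, kappa, omega):
        q = build_codon_rate_matrix(kappa, omega, PI)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    @pytest.mark.parametrize("kappa,omega", [(2.0, 0.4), (5.0, 1.0), (0.5, 3.0)])
    def test_mean_rate_normalised_to_one(self, kappa, omega):
        q = build_codon_rate_matrix(kappa, omega, PI)
        assert abs(-(PI * np.diag(q)).sum() - 1.0) < 1e-12

    def test_detailed_balance_all_pairs(self, rng):
        pi = rng.dirichlet(np.ones(61))
        q = build_codon_rate_matrix(2.3, 0.7, pi)
        flux = pi[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-12

    @pytest.mark.parametrize("kappa,omega", [(-1.0, 0.4), (2.0, 0.0), (0.0, 0.2)])
    def test_invalid_parameters_rejected(self, kappa, omega):
        with pytest.raises(CodonModelError):
            build_codon_rate_matrix(kappa, omega, PI)

    def test_unnormalised_frequencies_rejected(self):
        with pytest.raises(CodonModelError):
            build_codon_rate_matrix(2.0, 0.4, np.full(61, 0.02))

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_matrices_stochastic(self, t):
        q = build_codon_rate_matrix(2.0, 0.3, PI)
        p = _Spectral(q, PI).prob(t)
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-10
        assert p.min() >= 0.0

    def test_neutral_flux_equals_site_proportion(self):
        # at omega=1 the synonymous flux proportion IS the opportunity
        q1 = build_codon_rate_matrix(2.0, 1.0, PI)
        rho_s, _ = flux_proportions(q1, PI)
        assert rho_s == pytest.approx(synonymous_site_proportion(2.0, PI), abs=1e-12)


def enumeration_loglik(aln, topology, lengths, kappa, omega, pi):
    """Direct sum over all internal-state assignments (4-taxon balanced
    rooted topology ((A,B),(C,D)) with internal branch lengths t_ab, t_cd).

    Independent of the package's pruning: uses scipy expm and einsum.
    """
    q = build_codon_rate_matrix(kappa, omega, pi)
    p = {name: expm(q * t) for name, t in lengths.items()}
    from coalrates.codon import CODON_INDEX

    total = 0.0
    n_sites = aln.n_codons
    seq = {t: s for t, s in zip(aln.ids, aln.seqs)}
    for site in range(n_sites):
        obs = {t: CODON_INDEX[seq[t][3 * site : 3 * site + 3]] for t in aln.ids}
        la = p["A"][:, obs["A"]]
        lb = p["B"][:, obs["B"]]
        lc = p["C"][:, obs["C"]]
        ld = p["D"][:, obs["D"]]
        # sum over root state r, internal states x (anc. of A,B) and y
        site_lik = np.einsum(
            "r,rx,x,x,ry,y,y->",
            pi, p["i1"], la, lb, p["i2"], lc, ld,
        )
        total += np.log(site_lik)
    return total


class TestLikelihood:
    def test_matches_internal_state_enumeration(self):
        tree = read_tree("((A:0.2,B:0.35):0.15,(C:0.1,D:0.4):0.25);")
        aln = CodonAlignment(
            ids=["A", "B", "C", "D"],
            seqs=["ATGAAACAT", "ATGAAGCAC", "ATAAAACAT", "CTGAAACAT"],
        )
        engine = M0Likelihood(aln, tree, pi=PI)
        ll = engine.loglik(2.0, 0.3, engine.initial_lengths)
        expected = enumeration_loglik(
            aln,
            "((A,B),(C,D))",
            {"A": 0.2, "B": 0.35, "C": 0.1, "D": 0.4, "i1": 0.15, "i2": 0.25},
            2.0,
            0.3,
            PI,
        )
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_duplicated_pattern_doubles_contribution(self):
        tree = read_tree("(A:0.2,B:0.3,C:0.1);")
        single = CodonAlignment(ids=list("ABC"), seqs=["ATG", "ATA", "CTG"])
        double = CodonAlignment(ids=list("ABC"), seqs=["ATGATG", "ATAATA", "CTGCTG"])
        e1 = M0Likelihood(single, tree, pi=PI)
        e2 = M0Likelihood(double, tree, pi=PI)
        ll1 = e1.loglik(2.0, 0.3, e1.initial_lengths)
        ll2 = e2.loglik(2.0, 0.3, e2.initial_lengths)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_zero_lengths_identical_sequences_closed_form(self):
        tree = read_tree("(A:0.0,B:0.0,C:0.0);")
        aln = CodonAlignment(ids=list("ABC"), seqs=["ATGAAA"] * 3)
        ll = m0_loglik(aln, tree, kappa=2.0, omega=0.3, pi=PI)
        assert ll == pytest.approx(2 * np.log(1 / 61), abs=1e-9)

    def test_gaps_treated_as_missing(self):
        tree = read_tree("(A:0.2,B:0.3,C:0.1);")
        aln = CodonAlignment(ids=list("ABC"), seqs=["ATG", "AT-", "CTG"])
        pruned = CodonAlignment(ids=list("AC"), seqs=["ATG", "CTG"])
        e_full = M0Likelihood(aln, tree, pi=PI)
        ll_full = e_full.loglik(2.0, 0.3, e_full.initial_lengths)
        # marginalising the all-missing tip equals the likelihood of the
        # induced two-taxon tree (path length 0.2 + 0.3... B removed: A-C)
        two = read_tree("(A:0.2,C:0.1);")
        e_two = M0Likelihood(pruned, two, pi=PI)
        ll_two = e_two.loglik(2.0, 0.3, e_two.initial_lengths)
        assert ll_full == pytest.approx(ll_two, abs=1e-9)

    def test_stop_codon_rejected(self):
        tree = read_tree("(A:0.1,B:0.1);")
        aln = CodonAlignment(ids=list("AB"), seqs=["TAA", "ATG"])
        with pytest.raises(CodonModelError, match="stop"):
            M0Likelihood(aln, tree, pi=PI)

    def test_taxa_mismatch_rejected(self):
        tree = read_tree("(A:0.1,B:0.1,X:0.1);")
        aln = CodonAlignment(ids=list("ABC"), seqs=["ATG"] * 3)
        with pytest.raises(CodonModelError):
            M0Likelihood(aln, tree, pi=PI)

    def test_branch_gradient_matches_finite_differences(self, rng):
        tree = read_tree("((A:0.2,B:0.3):0.15,(C:0.1,D:0.25):0.05);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=40, seed=5)
        engine = M0Likelihood(aln, tree, pi=PI)
        lengths = engine.initial_lengths
        _, grad = engine.loglik_and_branch_grad(2.0, 0.3, lengths)
        h = 1e-6
        for i in range(len(lengths)):
            up, down = lengths.copy(), lengths.copy()
            up[i] += h
            down[i] -= h
            fd = (engine.loglik(2.0, 0.3, up) - engine.loglik(2.0, 0.3, down)) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=1e-5)


class TestFit:
    def test_identical_sequences_zero_branch_lengths(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        aln = CodonAlignment(ids=list("ABCD"), seqs=["ATGAAACATCCG"] * 4)
        fit = fit_m0(aln, tree, freqs="flat")
        assert fit.branch_lengths.max() <= 1e-6

    def test_mle_at_least_as_good_as_truth(self):
        tree = read_tree("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=300, seed=8)
        fit = fit_m0(aln, tree, freqs="flat")
        from coalrates.trees import copy_tree, deroot

        engine = M0Likelihood(aln, deroot(copy_tree(tree)), pi=PI)
        ll_truth = engine.loglik(2.0, 0.3, engine.initial_lengths)
        assert fit.log_likelihood >= ll_truth - 1e-6

    def test_deterministic(self):
        tree = read_tree("((A:0.2,B:0.2):0.1,C:0.2);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=100, seed=9)
        f1 = fit_m0(aln, tree, freqs="flat")
        f2 = fit_m0(aln, tree, freqs="flat")
        assert f1.kappa == f2.kappa and f1.omega == f2.omega
        assert np.array_equal(f1.branch_lengths, f2.branch_lengths)

    def test_two_taxon_distance_recovery(self):
        """t = 0.5 substitutions/codon, 50k codons: within 5 percent."""
        tree = read_tree("(A:0.25,B:0.25);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=50_000, seed=10)
        fit = fit_m0(aln, tree, freqs="flat")
        assert fit.tree_length == pytest.approx(0.5, rel=0.05)

    def test_omega_hat_increases_with_simulated_omega(self, rng):
        tree = read_tree("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        means = []
        for omega in (0.1, 0.5, 1.0):
            hats = []
            for rep in range(20):
                aln = simulate_codon_alignment(
                    tree, 2.0, omega, length_codons=200,
                    seed=int(rng.integers(2**31)),
                )
                hats.append(fit_m0(aln, tree, freqs="flat").omega)
            means.append(np.mean(hats))
        assert means[0] < means[1] < means[2]


def counting_ds_dn(seq_a, seq_b, kappa):
    """Pathway-counting (Nei-Gojobori style) dS/dN with kappa-weighted
    mutational opportunity and Jukes-Cantor correction.  Stop-codon
    mutations are excluded from opportunity and from pathways."""
    stops = {"TAA", "TAG", "TGA"}
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    aa = lambda codon: str(Seq(codon).translate())

    def syn_sites(codon):
        total = 0.0
        for pos in range(3):
            num = den = 0.0
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut in stops:
                    continue
                w = kappa if (codon[pos], alt) in ts_pairs else 1.0
                den += w
                if aa(mut) == aa(codon):
                    num += w
            total += num / den if den else 0.0
        return total

    n_codons = len(seq_a) // 3
    S = N = Sd = Nd = 0.0
    for k in range(n_codons):
        ca, cb = seq_a[3 * k : 3 * k + 3], seq_b[3 * k : 3 * k + 3]
        s_sites = 0.5 * (syn_sites(ca) + syn_sites(cb))
        S += s_sites
        N += 3.0 - s_sites
        if ca == cb:
            continue
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        path_sd, path_nd, n_paths = 0.0, 0.0, 0
        for order in itertools.permutations(diffs):
            cur, sd, nd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in stops:
                    ok = False
                    break
                if aa(nxt) == aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                path_sd += sd
                path_nd += nd
                n_paths += 1
        if n_paths:
            Sd += path_sd / n_paths
            Nd += path_nd / n_paths
    ps, pn = Sd / S, Nd / N
    jc = lambda p: -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return jc(ps), jc(pn)


class TestDepths:
    def test_omega_one_depths_equal(self):
        q = build_codon_rate_matrix(2.3, 1.0, PI)
        rho_s, rho_n = flux_proportions(q, PI)
        fit = M0Fit(
            kappa=2.3, omega=1.0, pi=PI,
            tree=read_tree("(A:0.2,B:0.3);"),
            branch_lengths=np.array([0.2, 0.3]),
            log_likelihood=0.0, rho_syn=rho_s, rho_nonsyn=rho_n,
            syn_site_proportion=synonymous_site_proportion(2.3, PI),
        )
        rec = ds_dn_tree_depth(fit)
        assert rec.dn_depth == pytest.approx(rec.ds_depth, rel=1e-9)

    def test_zero_lengths_zero_depths(self):
        q = build_codon_rate_matrix(2.0, 0.5, PI)
        rho_s, rho_n = flux_proportions(q, PI)
        fit = M0Fit(
            kappa=2.0, omega=0.5, pi=PI,
            tree=read_tree("(A:0.0,B:0.0);"),
            branch_lengths=np.zeros(2),
            log_likelihood=0.0, rho_syn=rho_s, rho_nonsyn=rho_n,
            syn_site_proportion=synonymous_site_proportion(2.0, PI),
        )
        rec = ds_dn_tree_depth(fit)
        assert rec.ds_depth == 0.0 and rec.dn_depth == 0.0

    def test_dn_over_ds_equals_omega(self):
        tree = read_tree("((A:0.2,B:0.2):0.1,C:0.2);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=200, seed=12)
        fit = fit_m0(aln, tree, freqs="flat")
        rec = ds_dn_tree_depth(fit)
        assert rec.dn_depth / rec.ds_depth == pytest.approx(fit.omega, rel=1e-9)

    def test_matches_counting_oracle_two_sequences(self):
        """ML depths vs an independent pathway-counting estimate."""
        tree = read_tree("(A:0.25,B:0.25);")
        aln = simulate_codon_alignment(tree, 2.0, 0.3, length_codons=50_000, seed=13)
        fit = fit_m0(aln, tree, freqs="flat")
        rec = ds_dn_tree_depth(fit)
        ds_count, dn_count = counting_ds_dn(aln.seqs[0], aln.seqs[1], kappa=2.0)
        assert rec.ds_depth == pytest.approx(ds_count, rel=0.10)
        assert rec.dn_depth == pytest.approx(dn_count, rel=0.10)

    def test_height_mode_uses_longest_path(self):
        q = build_codon_rate_matrix(2.0, 0.5, PI)
        rho_s, rho_n = flux_proportions(q, PI)
        fit = M0Fit(
            kappa=2.0, omega=0.5, pi=PI,
            tree=read_tree("((A:0.4,B:0.1):0.2,C:0.1);"),
            branch_lengths=np.array([0.4, 0.1, 0.2, 0.1]),
            log_likelihood=0.0, rho_syn=rho_s, rho_nonsyn=rho_n,
            syn_site_proportion=synonymous_site_proportion(2.0, PI),
        )
        full = ds_dn_tree_depth(fit)
        height = ds_dn_tree_depth(fit, depth_mode="height")
        assert height.ds_depth == pytest.approx(full.ds_depth * 0.6 / 0.8)


class TestFrequencies:
    def test_f3x4_sums_to_one_and_prefers_observed(self):
        aln = CodonAlignment(ids=["A", "B"], seqs=["ATGATGATG", "ATGATGATA"])
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        from coalrates.codon import CODON_INDEX

        assert pi[CODON_INDEX["ATG"]] > pi[CODON_INDEX["CCC"]]
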