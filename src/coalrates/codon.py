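"""M0 codon-model likelihood, fitting, and dS/dN tree depths.

The model is the single-ratio Goldman-Yang codon model (M0): a 61-state
continuous-time Markov chain over the sense codons of the universal
genetic code, with instantaneous rates

    q_ij = 0                      more than one nucleotide change
         = pi_j                   synonymous transversion
         = kappa * pi_j           synonymous transition
         = omega * pi_j           non-synonymous transversion
         = omega * kappa * pi_j   non-synonymous transition

scaled so one unit of branch length is one expected substitution per
codon.  Likelihoods are computed by Felsenstein pruning with the
transition matrices obtained from the spectral decomposition of the
reversible generator; branch lengths, kappa, and omega are optimised by
L-BFGS-B with analytic branch-length gradients.

Fitted trees are converted to synonymous and non-synonymous tree depths
per site using the mutational-opportunity convention: with rho_S the
equilibrium proportion of substitutions that are synonymous and S_prop
the kappa-weighted proportion of synonymous mutational opportunity
(rho_S evaluated at omega = 1),

    dS = T * rho_S / (3 * S_prop),   dN = T * rho_N / (3 * (1 - S_prop))

where T is the summed branch length of the tree in substitutions per
codon.  At omega = 1 both depths equal T / 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import minimize

from .alignments import STOP_CODONS, CodonAlignment
from .trees import copy_tree, deroot, tip_labels

__all__ = [
    "CODONS",
    "CodonModelError",
    "M0Fit",
    "RateDepthRecord",
    "GenomeRateRatios",
    "build_codon_rate_matrix",
    "flux_proportions",
    "synonymous_site_proportion",
    "f3x4_frequencies",
    "flat_frequencies",
    "M0Likelihood",
    "m0_loglik",
    "fit_m0",
    "ds_dn_tree_depth",
    "genome_rate_ratios",
    "COMPARTMENTS",
]

COMPARTMENTS = ("mt", "pt", "nu")

_CODE = CodonTable.unambiguous_dna_by_id[1]
CODONS: List[str] = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
]
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = [_CODE.forward_table[c] for c in CODONS]

_PURINES = {"A", "G"}


def _classify_pairs() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    synonymous = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return single, transition, synonymous


_SINGLE, _TRANSITION, _SYNONYMOUS = _classify_pairs()


class CodonModelError(ValueError):
    """Raised for invalid codon-model parameters or inputs."""


def _check_freqs(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise CodonModelError(f"codon frequencies must have shape (61,), got {pi.shape}")
    if np.any(pi < 0):
        raise CodonModelError("codon frequencies must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise CodonModelError(f"codon frequencies sum to {pi.sum()!r}, expected 1")
    return pi


def flat_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Empirical codon frequencies from position-specific nucleotide counts.

    Frequencies of A/C/G/T are tallied separately at the three codon
    positions (gaps/ambiguities ignored), codon frequencies are the
    product over positions with stop codons removed, and the result is
    renormalised with a small floor so no sense codon has zero mass.
    """
    pos_counts = np.zeros((3, 4))
    base_index = {b: k for k, b in enumerate("ACGT")}
    for seq in aln.seqs:
        for pos in range(3):
            for ch in seq[pos::3]:
                k = base_index.get(ch)
                if k is not None:
                    pos_counts[pos, k] += 1
    if np.any(pos_counts.sum(axis=1) == 0):
        raise CodonModelError("alignment has no unambiguous data at some codon position")
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, base_index[c[0]]]
            * pos_freqs[1, base_index[c[1]]]
            * pos_freqs[2, base_index[c[2]]]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


def build_codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """The scaled 61x61 M0 generator (rows sum to 0, mean rate 1)."""
    if not kappa > 0:
        raise CodonModelError(f"kappa must be > 0, got {kappa}")
    if not omega > 0:
        raise CodonModelError(f"omega must be > 0, got {omega}")
    pi = _check_freqs(pi)
    rate = np.where(_SINGLE, np.tile(pi, (N_CODONS, 1)), 0.0)
    rate = rate * np.where(_TRANSITION, kappa, 1.0)
    rate = rate * np.where(_SYNONYMOUS | ~_SINGLE, 1.0, omega)
    np.fill_diagonal(rate, 0.0)
    np.fill_diagonal(rate, -rate.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(rate)))
    if mean_rate <= 0:
        raise CodonModelError("degenerate rate matrix (zero mean rate)")
    return rate / mean_rate


def flux_proportions(q: np.ndarray, pi: np.ndarray) -> Tuple[float, float]:
    """Equilibrium proportions of substitutions that are synonymous /
    non-synonymous under a scaled generator."""
    pi = _check_freqs(pi)
    flux = pi[:, None] * q
    total = float(flux[_SINGLE].sum())
    rho_s = float(flux[_SINGLE & _SYNONYMOUS].sum()) / total
    return rho_s, 1.0 - rho_s


def synonymous_site_proportion(kappa: float, pi: np.ndarray) -> float:
    """Kappa-weighted proportion of mutational opportunity that is
    synonymous: the synonymous flux proportion of the neutral
    (omega = 1) chain with the same kappa and frequencies."""
    q1 = build_codon_rate_matrix(kappa, 1.0, pi)
    rho_s, _ = flux_proportions(q1, pi)
    return rho_s


class _Spectral:
    """Spectral decomposition of a reversible generator, for fast P(t)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(np.maximum(pi, 1e-300))
        b = (sq[:, None] * q) / sq[None, :]
        b = 0.5 * (b + b.T)
        self.w, v = np.linalg.eigh(b)
        self.left = v / sq[:, None]     # D^{-1/2} V
        self.right = v.T * sq[None, :]  # V^T D^{1/2}

    def prob(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        return np.clip(p, 1e-300, None)


class M0Likelihood:
    """Felsenstein-pruning likelihood engine for one alignment + topology.

    Site patterns are compressed once at construction; ``loglik`` and
    ``loglik_and_branch_grad`` then evaluate the model at arbitrary
    (kappa, omega, branch lengths).  Branch lengths are indexed by the
    postorder position of the child node (see ``branch_nodes``).
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree,
                 pi: Optional[np.ndarray] = None):
        tree_taxa = tip_labels(tree)
        aln_taxa = frozenset(aln.ids)
        if tree_taxa != aln_taxa:
            raise CodonModelError(
                "alignment taxa and tree tips differ: "
                f"only-in-tree={sorted(tree_taxa - aln_taxa)}, "
                f"only-in-alignment={sorted(aln_taxa - tree_taxa)}"
            )
        self.pi = _check_freqs(pi if pi is not None else f3x4_frequencies(aln))
        n_codons = aln.n_codons
        if aln.n_taxa < 2:
            raise CodonModelError("need at least 2 sequences")

        codes = np.empty((aln.n_taxa, n_codons), dtype=np.int32)
        for row, seq in enumerate(aln.seqs):
            for site in range(n_codons):
                codon = seq[3 * site : 3 * site + 3]
                idx = CODON_INDEX.get(codon)
                if idx is None:
                    if codon in STOP_CODONS:
                        raise CodonModelError(
                            f"stop codon {codon} at codon {site + 1} of "
                            f"{aln.ids[row]}; mask stops before fitting"
                        )
                    idx = -1  # gap or ambiguity -> missing
                codes[row, site] = idx
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.pattern_weights = weights.astype(float)
        self.n_sites = n_codons

        self.nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(self.nodes)
        node_pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [node_pos[id(c)] for c in n.child_nodes()] for n in self.nodes
        ]
        self.is_tip = [n.is_leaf() for n in self.nodes]
        self.branch_nodes = list(range(self.n_nodes - 1))  # all but root
        row_of = {t: r for r, t in enumerate(aln.ids)}
        self.tip_codes = [
            patterns[row_of[n.taxon.label]] if n.is_leaf() else None for n in self.nodes
        ]
        self.initial_lengths = np.array(
            [
                self.nodes[i].edge.length if self.nodes[i].edge.length is not None else np.nan
                for i in self.branch_nodes
            ]
        )
        self.tree = tree

    # -- internals -----------------------------------------------------

    def _tip_partial(self, p: np.ndarray, codes: np.ndarray) -> np.ndarray:
        missing = codes < 0
        safe = np.where(missing, 0, codes)
        f = p[:, safe].T.copy()
        f[missing] = 1.0
        return f

    def _forward(self, probs: List[np.ndarray]):
        """Postorder pass; returns per-node partials and log scale factors."""
        npat = self.pattern_weights.size
        F: List[Optional[np.ndarray]] = [None] * self.n_nodes
        D: List[Optional[np.ndarray]] = [None] * self.n_nodes
        C: List[Optional[np.ndarray]] = [None] * self.n_nodes
        root = self.n_nodes - 1
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                C[i] = np.zeros(npat)
                F[i] = self._tip_partial(probs[i], self.tip_codes[i])
                continue
            d = np.ones((npat, N_CODONS))
            c = np.zeros(npat)
            for ch in self.children[i]:
                d = d * F[ch]
                c = c + C[ch]
            scale = d.max(axis=1)
            scale[scale <= 0] = 1.0
            d = d / scale[:, None]
            c = c + np.log(scale)
            D[i], C[i] = d, c
            if i != root:
                F[i] = d @ probs[i].T
        return F, D, C

    def _site_logliks(self, D, C) -> np.ndarray:
        root = self.n_nodes - 1
        lik = (D[root] * self.pi).sum(axis=1)
        return np.log(np.maximum(lik, 1e-300)) + C[root]

    def _probs(self, kappa: float, omega: float,
               lengths: np.ndarray) -> Tuple[List[np.ndarray], np.ndarray, _Spectral]:
        q = build_codon_rate_matrix(kappa, omega, self.pi)
        spec = _Spectral(q, self.pi)
        probs: List[Optional[np.ndarray]] = [None] * self.n_nodes
        for k, i in enumerate(self.branch_nodes):
            probs[i] = spec.prob(float(lengths[k]))
        return probs, q, spec

    # -- public API ----------------------------------------------------

    def loglik(self, kappa: float, omega: float, lengths: np.ndarray) -> float:
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths < 0) or np.any(~np.isfinite(lengths)):
            raise CodonModelError("branch lengths must be finite and non-negative")
        probs, _, _ = self._probs(kappa, omega, lengths)
        F, D, C = self._forward(probs)
        return float(self.pattern_weights @ self._site_logliks(D, C))

    def loglik_and_branch_grad(
        self, kappa: float, omega: float, lengths: np.ndarray
    ) -> Tuple[float, np.ndarray]:
        """Log-likelihood and its gradient w.r.t. every branch length.

        Uses the standard outer-partial (preorder) recursion; the cost is
        a small multiple of a single likelihood evaluation.
        """
        lengths = np.asarray(lengths, dtype=float)
        probs, q, _ = self._probs(kappa, omega, lengths)
        F, D, C = self._forward(probs)
        site_ll = self._site_logliks(D, C)
        ll = float(self.pattern_weights @ site_ll)

        npat = self.pattern_weights.size
        root = self.n_nodes - 1
        branch_pos = {node: k for k, node in enumerate(self.branch_nodes)}
        grad = np.zeros(len(self.branch_nodes))

        # outer partials W (scaled), processed root-down
        stack = [(root, self.pi[None, :].repeat(npat, axis=0), np.zeros(npat))]
        while stack:
            u, w_u, d_u = stack.pop()
            for v in self.children[u]:
                w_v = w_u.copy()
                d_v = d_u.copy()
                for s in self.children[u]:
                    if s != v:
                        w_v = w_v * F[s]
                        d_v = d_v + C[s]
                qp = q @ probs[v]
                if self.is_tip[v]:
                    codes = self.tip_codes[v]
                    missing = codes < 0
                    safe = np.where(missing, 0, codes)
                    a = qp[:, safe].T.copy()
                    a[missing] = 0.0  # rows of QP sum to zero
                    c_dv = np.zeros(npat)
                else:
                    a = D[v] @ qp.T
                    c_dv = C[v]
                g_pat = (w_v * a).sum(axis=1)
                factor = np.exp(d_v + c_dv - site_ll)
                grad[branch_pos[v]] = float(
                    (self.pattern_weights * g_pat * factor).sum()
                )
                if not self.is_tip[v]:
                    u_v = w_v @ probs[v]
                    scale = u_v.max(axis=1)
                    scale[scale <= 0] = 1.0
                    u_v = u_v / scale[:, None]
                    stack.append((v, u_v, d_v + np.log(scale)))
        return ll, grad


@dataclass
class M0Fit:
    """Maximum-likelihood M0 parameter estimates for one locus."""

    kappa: float
    omega: float
    pi: np.ndarray
    tree: dendropy.Tree          # fitted branch lengths, subs/codon
    branch_lengths: np.ndarray
    log_likelihood: float
    rho_syn: float
    rho_nonsyn: float
    syn_site_proportion: float
    n_iterations: int = 0

    @property
    def tree_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def tree_height(self) -> float:
        """Maximum root-to-tip path length of the fitted tree."""
        heights = {id(self.tree.seed_node): 0.0}
        best = 0.0
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            h = heights[id(node.parent_node)] + (node.edge.length or 0.0)
            heights[id(node)] = h
            if node.is_leaf():
                best = max(best, h)
        return best


def m0_loglik(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    kappa: float,
    omega: float,
    pi: Optional[np.ndarray] = None,
) -> float:
    """M0 log-likelihood at the tree's own branch lengths."""
    engine = M0Likelihood(aln, tree, pi=pi)
    lengths = engine.initial_lengths
    if np.any(np.isnan(lengths)):
        raise CodonModelError("tree has branches without lengths")
    return engine.loglik(kappa, omega, lengths)


def fit_m0(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    freqs: Union[str, np.ndarray] = "f3x4",
    kappa0: float = 2.0,
    omega0: float = 0.4,
    t0: float = 0.1,
    max_iter: int = 1000,
) -> M0Fit:
    """Fit kappa, omega and all branch lengths by maximum likelihood.

    The topology is fixed (branch lengths of the input tree are ignored;
    all start from ``t0``).  Parameters are optimised on the log scale by
    L-BFGS-B with analytic branch-length gradients and central-difference
    gradients for kappa and omega.  Deterministic given inputs.
    """
    if isinstance(freqs, str):
        if freqs == "f3x4":
            pi = f3x4_frequencies(aln)
        elif freqs == "flat":
            pi = flat_frequencies()
        else:
            raise CodonModelError(f"unknown frequency model {freqs!r}")
    else:
        pi = _check_freqs(np.asarray(freqs, dtype=float))

    work = deroot(copy_tree(tree))
    engine = M0Likelihood(aln, work, pi=pi)
    n_branches = len(engine.branch_nodes)

    h = 1e-5

    def objective(x: np.ndarray) -> Tuple[float, np.ndarray]:
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        lengths = np.exp(x[2:])
        ll, g_t = engine.loglik_and_branch_grad(kappa, omega, lengths)
        g = np.empty_like(x)
        g[0] = (
            engine.loglik(kappa * np.exp(h), omega, lengths)
            - engine.loglik(kappa * np.exp(-h), omega, lengths)
        ) / (2 * h)
        g[1] = (
            engine.loglik(kappa, omega * np.exp(h), lengths)
            - engine.loglik(kappa, omega * np.exp(-h), lengths)
        ) / (2 * h)
        g[2:] = g_t * lengths  # chain rule through log
        return -ll, -g

    x0 = np.concatenate(
        [[np.log(kappa0), np.log(omega0)], np.full(n_branches, np.log(t0))]
    )
    bounds = (
        [(np.log(1e-3), np.log(1e3))] * 2
        + [(np.log(1e-9), np.log(50.0))] * n_branches
    )
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6},
    )
    if res.status == 1:
        raise CodonModelError(
            f"M0 fit did not converge in {max_iter} iterations: {res.message}; "
            f"last logL={-res.fun:.6f}"
        )
    kappa_hat, omega_hat = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    lengths_hat = np.exp(res.x[2:])
    for k, i in enumerate(engine.branch_nodes):
        engine.nodes[i].edge.length = float(lengths_hat[k])
    q = build_codon_rate_matrix(kappa_hat, omega_hat, pi)
    rho_s, rho_n = flux_proportions(q, pi)
    return M0Fit(
        kappa=kappa_hat,
        omega=omega_hat,
        pi=pi,
        tree=work,
        branch_lengths=lengths_hat,
        log_likelihood=float(-res.fun),
        rho_syn=rho_s,
        rho_nonsyn=rho_n,
        syn_site_proportion=synonymous_site_proportion(kappa_hat, pi),
        n_iterations=int(res.nit),
    )


@dataclass
class RateDepthRecord:
    """Per-locus tree depth in dS and dN substitutions per site."""

    locus: str
    compartment: Optional[str]
    ds_depth: float
    dn_depth: float
    omega: float
    depth_mode: str = "treelength"

    def __post_init__(self):
        if self.ds_depth < 0 or self.dn_depth < 0:
            raise CodonModelError("depths must be non-negative")


def ds_dn_tree_depth(
    fit: M0Fit,
    locus: str = "locus",
    compartment: Optional[str] = None,
    depth_mode: str = "treelength",
) -> RateDepthRecord:
    """Convert a fitted M0 tree into dS / dN depths per site.

    ``depth_mode='treelength'`` (default) sums all branch lengths;
    ``'height'`` uses the maximum root-to-tip path instead.
    """
    s_prop = fit.syn_site_proportion
    if s_prop <= 0.0 or s_prop >= 1.0:
        raise CodonModelError(f"degenerate synonymous site proportion {s_prop}")
    if depth_mode == "treelength":
        total = fit.tree_length
    elif depth_mode == "height":
        total = fit.tree_height
    else:
        raise CodonModelError(f"unknown depth_mode {depth_mode!r}")
    ds = total * fit.rho_syn / (3.0 * s_prop)
    dn = total * fit.rho_nonsyn / (3.0 * (1.0 - s_prop))
    return RateDepthRecord(
        locus=locus,
        compartment=compartment,
        ds_depth=ds,
        dn_depth=dn,
        omega=fit.omega,
        depth_mode=depth_mode,
    )


@dataclass
class GenomeRateRatios:
    """Compartment-mean depths and mt-normalised ratio triples."""

    mean_ds: Dict[str, float]
    mean_dn: Dict[str, float]
    mean_omega: Dict[str, float]
    ds_ratios: Tuple[float, float, float]
    dn_ratios: Tuple[float, float, float]
    statistic: str = "mean"

    def as_dict(self) -> Dict[str, object]:
        return {
            "mean_ds": self.mean_ds,
            "mean_dn": self.mean_dn,
            "mean_omega": self.mean_omega,
            "ds_ratios_mt_pt_nu": list(self.ds_ratios),
            "dn_ratios_mt_pt_nu": list(self.dn_ratios),
            "ds_ratios_display": [f"{r:.1f}" for r in self.ds_ratios],
            "dn_ratios_display": [f"{r:.1f}" for r in self.dn_ratios],
            "statistic": self.statistic,
        }


def genome_rate_ratios(
    records: Iterable[RateDepthRecord], statistic: str = "mean"
) -> GenomeRateRatios:
    """mt:pt:nu ratio triples of average dS and dN tree depths.

    Depths are averaged per compartment (arithmetic mean by default,
    median optional) and divided by the mitochondrial average, so the mt
    entry is exactly 1 by construction.
    """
    if statistic not in ("mean", "median"):
        raise CodonModelError(f"unknown statistic {statistic!r}")
    groups: Dict[str, List[RateDepthRecord]] = {c: [] for c in COMPARTMENTS}
    for rec in records:
        if rec.compartment not in groups:
            raise CodonModelError(
                f"record {rec.locus!r} has unknown compartment {rec.compartment!r}"
            )
        groups[rec.compartment].append(rec)
    empty = [c for c, recs in groups.items() if not recs]
    if empty:
        raise CodonModelError(f"no records for compartment(s): {empty}")
    agg = np.mean if statistic == "mean" else np.median
    mean_ds = {c: float(agg([r.ds_depth for r in recs])) for c, recs in groups.items()}
    mean_dn = {c: float(agg([r.dn_depth for r in recs])) for c, recs in groups.items()}
    mean_omega = {c: float(agg([r.omega for r in recs])) for c, recs in groups.items()}
    if mean_ds["mt"] <= 0 or mean_dn["mt"] <= 0:
        raise CodonModelError("mitochondrial mean depth is zero; ratios undefined")
    ds_ratios = tuple(mean_ds[c] / mean_ds["mt"] for c in COMPARTMENTS)
    dn_ratios = tuple(mean_dn[c] / mean_dn["mt"] for c in COMPARTMENTS)
    return GenomeRateRatios(
        mean_ds=mean_ds,
        mean_dn=mean_dn,
        mean_omega=mean_omega,
        ds_ratios=ds_ratios,
        dn_ratios=dn_ratios,
        statistic=statistic,
    )
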