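# Methods

This note documents the models implemented in `coalrates`, the design
choices made where conventions differ between tools, and what the
synthetic benchmark does and does not demonstrate.

## Multispecies coalescent simulator

Gene trees are simulated under the standard MSC with one haploid
lineage sampled per species.  Species-tree branch lengths are in
coalescent units (time divided by 2N generations); within each branch,
k lineages coalesce at total rate k(k−1)/2 (rate 1 per pair per unit),
and lineages remaining at the top of a branch are handed to the parent
branch.  The root branch extends to infinity.  There is no migration,
no gene flow, and no rate variation; the simulator's purpose is to
produce gene-tree discordance with known expectations (the quartet
concordance probability 1 − (2/3)e^(−t)), not to model any real clade's
history — no coalescent-scale parameters are available for the data
sets that motivated the package, so all simulated branch lengths are
free choices.

For non-ultrametric species trees, node times are taken as the longest
root-ward path from the tips; coalescent waiting times are then applied
per branch.

## Tree handling

* Newick supports are read either as internal-node labels or as
  comments (`[&support=…]`, or a bare number).  If every support in a
  tree is ≤ 1 the values are interpreted as fractions and rescaled to
  percentages — newick dialects differ and the inputs rarely declare
  their scale.
* Support collapsing contracts edges with support *strictly below* the
  threshold (default 33%), so an edge with support exactly 33 is kept.
  Collapsing is idempotent and never changes the tip set.
* All split-based comparisons (paralog monophyly, concordance, quartet
  tallies) are performed on unrooted splits, canonicalised as the side
  not containing the lexicographically smallest label.  Root placement
  is treated as display-only; for concordance this choice affects only
  nodes adjacent to the root.

## Paralog classification and retention

A multi-copy species is Type I iff some edge of the unrooted gene tree
separates exactly that species' copies from everything else; otherwise
Type II.  Evaluating monophyly on the unrooted tree means two copies
adjacent across an arbitrary root are Type I.  Retention: all
multi-copy species Type I → keep the gene with a seeded uniform random
copy per species; Type II in 1–5 species → keep the gene, removing
every copy of those species; Type II in more than 5 species → drop the
gene.  The boundary (5 kept, 6 dropped) is exact and tested.

An optional orthology screen flags genes whose longest internal branch
exceeds 10× the median internal branch.  The 10× factor is a labelled
guess — no numeric criterion is established for "abnormally long"
internal branches — and the filter is off by default.

## Concordance semantics

For a species split S and a gene tree g, S is first restricted to g's
taxa; if fewer than two taxa survive on either side the gene is
*missing* for that node.  The gene is *concordant* if it contains the
restricted split, *conflicting* if it contains a split incompatible
with it (two splits on the same taxon set are incompatible iff all four
pairwise side intersections are non-empty), and otherwise
*uninformative*.  Two consequences of this definition: a polytomy never
conflicts (it asserts nothing incompatible), and mere absence of the
concordant split is not conflict.  The four counts sum to the number of
gene trees at every node; this conservation is asserted at run time.

Each conflicting gene contributes each of its distinct incompatible
splits once to the node's alternative tally; alternatives are pooled
across genes by canonical form (each split expressed on its own gene's
taxon set) and the most frequent one is reported, with ties broken by
the lexicographic string form so the result is deterministic.

## Quartet support and coalescent branch lengths

An internal branch induces four subtrees: the two child clades, the
sibling clade, and the rest of the tree; branches incident to the root
have no fourth subtree on the unrooted topology and are not scorable.
Quartets take one taxon from each subtree.  When the number of quartets
for a branch is at most `max_quartets_per_branch` (default 100) they
are enumerated exhaustively; otherwise that many are sampled uniformly
with replacement from a seeded generator (full enumeration is O(n⁴) and
infeasible at ~140 tips; exhaustive mode covers small trees).  Each
gene tree displaying all four taxa contributes the topology it
resolves; q₁ + q₂ + q₃ = 1 over informative (quartet, gene) pairs.

Branch lengths invert q₁ = 1 − (2/3)e^(−t).  q₁ ≤ 1/3 is the boundary
of the maximum-likelihood estimate and maps to 0 with a logged warning;
the estimate diverges as q₁ → 1 and is capped (default 10 coalescent
units).

## M0 codon model

The generator over the 61 sense codons of the universal genetic code
has rates proportional to π_j for synonymous transversions, κπ_j for
synonymous transitions, ωπ_j and ωκπ_j for their non-synonymous
counterparts, and 0 for multi-nucleotide changes; it is scaled so one
unit of branch length is one expected substitution per codon.  Only the
universal code is supported.  Codon frequencies default to empirical
F3x4 (position-specific nucleotide frequencies, stop codons removed,
floored at 1e-10 and renormalised); flat frequencies are available.

Likelihoods use Felsenstein pruning over compressed site patterns with
per-pattern scaling.  Gaps and ambiguous codons are missing data
(all-ones partial likelihoods); stop codons in input are an error —
mask them first (`replace_stop_codons` replaces TAA/TAG/TGA with
`---`).  Transition matrices come from the spectral decomposition of
the reversible generator (symmetrised with π^{1/2}), with entries
clipped to a tiny positive floor so zero-length branches cannot produce
−∞ likelihoods for conflicting patterns.

Fitting maximises over log κ, log ω, and log branch lengths with
L-BFGS-B (bounds 10⁻³–10³ for κ and ω, 10⁻⁹–50 per branch; fixed
starting values κ = 2, ω = 0.4, t = 0.1, so fits are deterministic).
Branch-length gradients are analytic (outer-partial recursion, costing
a small multiple of one likelihood evaluation); κ and ω gradients use
central differences on the log scale.  Trees are derooted before
fitting because the two edges at a bifurcating root are confounded
under a reversible model.  Convergence failure after the iteration cap
raises with the optimizer trace.

### dS and dN tree depths

With ρ_S the equilibrium proportion of substitutions that are
synonymous under the fitted generator and S̄ the synonymous proportion
of mutational opportunity (ρ_S evaluated at ω = 1, same κ and π), a
tree of total length T substitutions/codon has

    dS = T · ρ_S / (3 S̄),    dN = T · ρ_N / (3 (1 − S̄)).

This is the mutational-opportunity site-normalisation; by construction
dN/dS = ω exactly, and ω = 1 gives dS = dN = T/3.  "Tree depth" is the
**sum of all branch lengths** by default; the maximum root-to-tip path
is available as `depth_mode="height"` and the choice is recorded in
every record.  Whether the quantity reported by earlier analyses was
tree length or maximal depth is not documented anywhere we could
verify; tree length is the headline because it uses every branch of the
fitted tree.  Compartment summaries are arithmetic means by default
(median optional); ratio triples are normalised by the mitochondrial
mean, so the mt entry is exactly 1.

## Compartment benchmark

The benchmark generates loci for mt/pt/nu whose *generating parameters*
imply configured dS and dN depth-ratio triples exactly.  Given the
mitochondrial ω (default 0.4) and target triples (a, b per
compartment), the compartment ω is ω_c = ω_mt·(b_c/a_c) and the branch
scaling s_c = a_c·ρ_S(ω_mt)/ρ_S(ω_c), which compensates for the
ω-dependence of the synonymous substitution fraction.  Every locus in a
compartment evolves on the species-tree topology with branch lengths
`coalescent_length × base_rate × s_c`; the trees are deterministic and
only sequence evolution is stochastic.  This isolates the rates stage:
using MSC-drawn gene trees would make the per-locus generating tree
lengths random, and the implied ratios would then hold only in
expectation.  MSC discordance is exercised separately by the conflict
stages.

Defaults: a balanced 16-taxon species tree with unit branches, 10 loci
per compartment, 300 codons per locus, κ = 2, flat codon frequencies,
base rate 0.03 substitutions/codon per coalescent unit (mitochondrial
tree length 0.9, nuclear ≈ 5.2 — squarely in the range where 300-codon
M0 fits are stable).  At these sizes the recovered triples are within a
few percent of truth and the package's acceptance checks require ±15%.

Missing data is injected as whole-taxon locus dropout (mirroring locus
dropout in target capture rather than scattered gaps): a global cell
budget of `missing_fraction × loci × taxa` is allocated to random
(locus, taxon) cells, capped so every locus keeps at least 4 taxa, so
the realised fraction matches the request to within rounding.

## What the synthetic data does not emulate

Alignment and trimming error, among-site and among-lineage rate
variation (M0 has a single ω and the simulator a single rate), codon
usage and GC heterogeneity, RNA editing, gene flow and hybridisation,
and capture efficiency gradients across the phylogeny.  Tests passing
on this generator therefore demonstrate correctness of the estimators
under their own model assumptions — not robustness to the violations
real organellar and nuclear data exhibit.  Desk-scale problem sizes
(4–16 taxa, 10⁴ gene trees, 300–2000 codons, 30 loci) were chosen so
the full suite and the acceptance script each run in about a minute on
one CPU while keeping Monte-Carlo error well inside the stated
tolerances.

## Other recorded choices

* Parsimony-informative characters count unambiguous nucleotides only
  (a column needs ≥ 2 states each in ≥ 2 sequences); missing characters
  are `-`, `N`, `?`.  PIC percentages are computed after stop-codon
  masking, and the supermatrix report records this.
* Supermatrix concatenation orders loci lexicographically (so it is
  invariant to input order), gap-fills absent taxa, and emits 1-based
  inclusive RAxML-style codon-position partitions.
* The pipelines derive all stage seeds from one root seed and embed the
  config hash and seed in every report; reports contain no timestamps,
  so identical configs produce byte-identical output.
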