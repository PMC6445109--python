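"""In-frame alignments, summary statistics, and supermatrix assembly.

The central container is :class:`CodonAlignment`, a plain in-frame
nucleotide matrix over ``{A, C, G, T, -}`` (N/? tolerated as missing).
Statistics implemented here are the bookkeeping used when describing a
target-capture data set: stop-codon masking, parsimony-informative
character fractions, missing-character fractions, pairwise p-distance,
and concatenation into a supermatrix with codon-position partitions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "CodonAlignment",
    "SupermatrixReport",
    "STOP_CODONS",
    "replace_stop_codons",
    "parsimony_informative",
    "missing_fraction",
    "pairwise_p_distance",
    "concatenate_supermatrix",
    "write_phylip",
    "write_nexus",
    "write_raxml_partitions",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_MISSING = set("-Nn?")
_STATES = "ACGT"


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


@dataclass
class CodonAlignment:
    """An aligned nucleotide matrix for one locus.

    Sequences are upper-cased on construction.  ``compartment`` records
    the genomic origin of the locus (``mt``/``pt``/``nu``) when known.
    """

    ids: List[str]
    seqs: List[str]
    locus: str = "locus"
    compartment: Optional[str] = None

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_codons(self) -> int:
        if self.length % 3 != 0:
            raise AlignmentError(f"length {self.length} not divisible by 3")
        return self.length // 3

    def sequence(self, taxon: str) -> str:
        return self.seqs[self.ids.index(taxon)]

    def select_taxa(self, keep: Iterable[str]) -> "CodonAlignment":
        keep = set(keep)
        idx = [i for i, t in enumerate(self.ids) if t in keep]
        if not idx:
            raise AlignmentError("no taxa left after selection")
        return CodonAlignment(
            ids=[self.ids[i] for i in idx],
            seqs=[self.seqs[i] for i in idx],
            locus=self.locus,
            compartment=self.compartment,
        )

    def rename_taxa(self, mapping: Dict[str, str]) -> "CodonAlignment":
        return CodonAlignment(
            ids=[mapping.get(t, t) for t in self.ids],
            seqs=list(self.seqs),
            locus=self.locus,
            compartment=self.compartment,
        )

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n_taxa, self.length
        )

    @classmethod
    def from_fasta(cls, path_or_handle, locus: str = "locus",
                   compartment: Optional[str] = None) -> "CodonAlignment":
        records = list(SeqIO.parse(path_or_handle, "fasta"))
        if not records:
            raise AlignmentError(f"no sequences found in {path_or_handle}")
        return cls(
            ids=[r.id for r in records],
            seqs=[str(r.seq) for r in records],
            locus=locus,
            compartment=compartment,
        )

    def to_fasta(self, path_or_handle) -> None:
        records = [
            SeqRecord(Seq(s), id=t, description="") for t, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, path_or_handle, "fasta")

    def to_fasta_text(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()


def replace_stop_codons(aln: CodonAlignment) -> CodonAlignment:
    """Mask every TAA/TAG/TGA codon with ``---``; everything else untouched."""
    n_codons = aln.n_codons  # raises if not in frame
    new_seqs = []
    for seq in aln.seqs:
        codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
        new_seqs.append("".join("---" if c in STOP_CODONS else c for c in codons))
    return CodonAlignment(ids=list(aln.ids), seqs=new_seqs,
                          locus=aln.locus, compartment=aln.compartment)


def _state_counts(aln: CodonAlignment) -> np.ndarray:
    """Per-column counts of the four unambiguous states, shape (4, length)."""
    arr = aln.to_array()
    return np.stack([(arr == s.encode()).sum(axis=0) for s in _STATES])


def parsimony_informative(aln: CodonAlignment) -> Tuple[int, float]:
    """Count and percentage of parsimony-informative columns.

    A column is informative iff at least two distinct unambiguous
    nucleotide states each occur in at least two sequences; gaps and
    ambiguity codes never count as states.
    """
    if aln.length == 0:
        raise AlignmentError("empty alignment")
    counts = _state_counts(aln)
    informative = ((counts >= 2).sum(axis=0) >= 2)
    n = int(informative.sum())
    return n, 100.0 * n / aln.length


def column_classes(aln: CodonAlignment) -> Dict[str, int]:
    """Columns split into invariant / variable-uninformative / informative."""
    counts = _state_counts(aln)
    present = (counts > 0).sum(axis=0)
    informative = (counts >= 2).sum(axis=0) >= 2
    invariant = present <= 1
    return {
        "invariant": int(invariant.sum()),
        "uninformative_variable": int((~invariant & ~informative).sum()),
        "informative": int(informative.sum()),
    }


def missing_fraction(aln: CodonAlignment) -> float:
    """Percent of cells that are gap, N, or ? over taxa x length."""
    arr = aln.to_array()
    miss = np.zeros(arr.shape, dtype=bool)
    for ch in "-N?":
        miss |= arr == ch.encode()
    return 100.0 * float(miss.mean())


def pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites among unambiguously compared sites."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences differ in length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_a = np.zeros(a.shape, dtype=bool)
    valid_b = np.zeros(b.shape, dtype=bool)
    for s in _STATES:
        valid_a |= a == s.encode()
        valid_b |= b == s.encode()
    comparable = valid_a & valid_b
    n = int(comparable.sum())
    if n == 0:
        raise AlignmentError("no comparable (unambiguous, ungapped) sites")
    return float((a[comparable] != b[comparable]).sum()) / n


@dataclass
class SupermatrixReport:
    """Summary of a concatenated supermatrix.

    ``locus_partitions`` are 1-based inclusive (locus, start, end) ranges
    that tile the supermatrix; ``codon_partitions`` further split each
    locus range by codon position in RAxML ``start-end\\3`` convention.
    """

    total_length: int
    n_taxa: int
    locus_partitions: List[Tuple[str, int, int]]
    percent_informative: float
    percent_missing: float
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def codon_partitions(self) -> List[Tuple[str, int, int, int]]:
        out = []
        for locus, start, end in self.locus_partitions:
            for pos in (1, 2, 3):
                out.append((f"{locus}_pos{pos}", start + pos - 1, end, 3))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_length": self.total_length,
                "n_taxa": self.n_taxa,
                "locus_partitions": self.locus_partitions,
                "percent_informative": self.percent_informative,
                "percent_missing": self.percent_missing,
                "metadata": self.metadata,
            },
            indent=2,
        )


def concatenate_supermatrix(
    alignments: Sequence[CodonAlignment],
    taxon_universe: Optional[Iterable[str]] = None,
) -> Tuple[CodonAlignment, SupermatrixReport]:
    """Concatenate per-locus alignments over a shared taxon set.

    Loci are ordered lexicographically by locus id (so the result is
    invariant to input order), absent taxa are filled with gap blocks,
    and the report carries the partition table plus PIC/missing
    percentages computed on the assembled matrix.
    """
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    ids = [a.locus for a in alignments]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate locus ids: {dupes}")
    ordered = sorted(alignments, key=lambda a: a.locus)
    union = set()
    for aln in ordered:
        union.update(aln.ids)
    if taxon_universe is not None:
        universe = sorted(set(taxon_universe))
        extra = union - set(universe)
        if extra:
            raise AlignmentError(f"taxa outside the universe: {sorted(extra)}")
    else:
        universe = sorted(union)

    rows = {t: [] for t in universe}
    partitions = []
    offset = 0
    for aln in ordered:
        start = offset + 1
        end = offset + aln.length
        partitions.append((aln.locus, start, end))
        gap_block = "-" * aln.length
        present = dict(zip(aln.ids, aln.seqs))
        for t in universe:
            rows[t].append(present.get(t, gap_block))
        offset = end

    supermatrix = CodonAlignment(
        ids=list(universe),
        seqs=["".join(rows[t]) for t in universe],
        locus="supermatrix",
    )
    _, pic = parsimony_informative(supermatrix)
    report = SupermatrixReport(
        total_length=supermatrix.length,
        n_taxa=len(universe),
        locus_partitions=partitions,
        percent_informative=pic,
        percent_missing=missing_fraction(supermatrix),
        metadata={"n_loci": len(ordered),
                  "pic_computed_after_stop_masking": True},
    )
    return supermatrix, report


def write_phylip(aln: CodonAlignment, handle) -> None:
    """Relaxed phylip: full names, two-space separator."""
    handle.write(f"{aln.n_taxa} {aln.length}\n")
    width = max(len(t) for t in aln.ids)
    for t, s in zip(aln.ids, aln.seqs):
        handle.write(f"{t.ljust(width)}  {s}\n")


def write_nexus(aln: CodonAlignment, handle) -> None:
    handle.write("#NEXUS\nbegin data;\n")
    handle.write(f"  dimensions ntax={aln.n_taxa} nchar={aln.length};\n")
    handle.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
    width = max(len(t) for t in aln.ids)
    for t, s in zip(aln.ids, aln.seqs):
        safe = t if " " not in t else f"'{t}'"
        handle.write(f"    {safe.ljust(width)}  {s}\n")
    handle.write("  ;\nend;\n")


def write_raxml_partitions(report: SupermatrixReport, handle) -> None:
    for name, start, end, step in report.codon_partitions:
        handle.write(f"DNA, {name} = {start}-{end}\\{step}\n")
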