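"""Sequence records, genomic intervals and pairwise-alignment primitives.

Every later pipeline stage (element discovery, subtype classification,
motif anchoring, construct design) reuses the alignment and identity
helpers defined here.  Coordinates are held 0-based half-open internally;
the 1-based inclusive style used in genome-browser locus strings
(``chr19:37,866,177-37,867,144``) appears only at the formatting boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.SeqIO.FastaIO import SimpleFastaParser

NUCLEOTIDES = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default affine scoring: match +2, mismatch -1, gap open -4, gap extend -1.
DEFAULT_SCORING = {
    "match": 2.0,
    "mismatch": -1.0,
    "gap_open": -4.0,
    "gap_extend": -1.0,
}


class FastaParseError(ValueError):
    """Malformed FASTA input (empty sequence, bad characters, no header)."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the {A,C,G,T,N} alphabet."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - set(NUCLEOTIDES)
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """Contig-anchored, strand-aware half-open interval (0-based)."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))

    def to_locus_string(self) -> str:
        """1-based inclusive browser style, e.g. ``chr19:37,866,177-37,867,144``."""
        return f"{self.contig}:{self.start + 1:,}-{self.end:,}"


def interval_from_locus_string(s: str, strand: str = "+") -> GenomicInterval:
    """Parse a 1-based inclusive locus string back to internal coordinates."""
    contig, span = s.split(":")
    lo, hi = (int(x.replace(",", "")) for x in span.split("-"))
    return GenomicInterval(contig, lo - 1, hi, strand)


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment; ungapping each row recovers the inputs."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")

    def ungapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def normalize_sequence(raw: str, where: str = "") -> str:
    """Uppercase, map U to T and validate the nucleotide alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise AlphabetError(
            f"invalid characters {sorted(bad)}" + (f" in {where}" if where else "")
        )
    return seq


def reverse_complement(seq: str) -> str:
    seq = normalize_sequence(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalized :class:`SequenceRecord`s.

    Sequences are uppercased, U is mapped to T and anything outside
    {A,C,G,T,N} is rejected.  Empty sequences and duplicate ids raise
    :class:`FastaParseError` naming the offending header line.
    """
    with open(path) as fh:
        text = fh.read()
    # header -> line number, for error messages
    header_lines = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            header_lines.setdefault(line[1:].split()[0] if line[1:].split() else "", lineno)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for title, raw_seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        if not parts:
            raise FastaParseError(f"{path}: empty FASTA header")
        rid = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        line = header_lines.get(rid, "?")
        if not raw_seq:
            raise FastaParseError(
                f"{path}:{line}: empty sequence for record {rid!r}"
            )
        if rid in seen:
            raise FastaParseError(f"{path}:{line}: duplicate record id {rid!r}")
        seen.add(rid)
        try:
            seq = normalize_sequence(raw_seq, where=f"record {rid!r}")
        except AlphabetError as exc:
            raise FastaParseError(f"{path}:{line}: {exc}") from exc
        records.append(SequenceRecord(id=rid, seq=seq, description=desc))
    if not records and text.strip():
        raise FastaParseError(f"{path}:1: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as multi-FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _make_aligner(scoring: dict | None, free_target_ends: bool) -> Align.PairwiseAligner:
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc["match"]
    aligner.mismatch_score = sc["mismatch"]
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    if free_target_ends:
        # overhangs of the first ("target") sequence align to end gaps in
        # the second row at no cost
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def _first_alignment(aligner, a: str, b: str) -> PairwiseAlignment:
    aln = next(iter(aligner.align(a, b)))
    return PairwiseAlignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                             score=float(aln.score))


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: dict | None = None,
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of two sequences.

    The first optimal alignment in the aligner's deterministic enumeration
    order is returned, so results are reproducible run to run.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else normalize_sequence(a)
    sb = b.seq if isinstance(b, SequenceRecord) else normalize_sequence(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    return _first_alignment(_make_aligner(scoring, False), sa, sb)


def semiglobal_align(
    target: str,
    query: str,
    scoring: dict | None = None,
) -> PairwiseAlignment:
    """Global in the query, end-gap-free in the target.

    Used when locating a consensus (query) inside a padded genomic
    candidate window (target): overhangs of the window are not penalized.
    """
    return _first_alignment(
        _make_aligner(scoring, True),
        normalize_sequence(target),
        normalize_sequence(query),
    )


def gap_stripped_identity(aln: PairwiseAlignment) -> float:
    """Percent identity over columns where neither row has a gap.

    ``N`` never counts as a match (conservative identity).  Raises
    :class:`ValueError` when no gap-free column exists.
    """
    matches = 0
    columns = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        columns += 1
        if x == y and x != "N":
            matches += 1
    if columns == 0:
        raise ValueError("identity undefined: no gap-free columns")
    return 100.0 * matches / columns


def percent_identity(a: SequenceRecord | str, b: SequenceRecord | str,
                     scoring: dict | None = None) -> float:
    """Convenience: gap-stripped identity of the optimal global alignment."""
    return gap_stripped_identity(global_align(a, b, scoring))


def write_bed6(intervals: Sequence[tuple[GenomicInterval, str, float]], path) -> None:
    """Write (interval, name, score) triples as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
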