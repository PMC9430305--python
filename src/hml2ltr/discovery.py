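"""K-mer–seeded discovery of LTR-like loci against subtype consensus references.

The search mirrors the BLAT-style scheme used for genome-wide mining of
HML-2 long terminal repeats: the genome is indexed with overlapping 11-mers
at a stride of 5 (heavily repeated k-mers dropped), each consensus is
scanned at stride 1 in both orientations, co-linear seed runs are chained
into candidate windows, and each candidate is re-aligned to the consensus
to produce identity/coverage-scored hits with trimmed boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sequence_io import (
    GenomicInterval,
    PairwiseAlignment,
    SequenceRecord,
    gap_stripped_identity,
    reverse_complement,
    semiglobal_align,
)

log = logging.getLogger(__name__)


@dataclass
class DiscoveryConfig:
    """Tunables for the seed-chain-extend search."""

    k: int = 11
    step: int = 5
    min_seeds: int = 8
    chain_gap: int = 100          # max diagonal drift within one chain (nt)
    identity_floor: float = 60.0  # percent; candidates below are discarded
    max_kmer_freq: int = 1000     # repeat filter: drop k-mers above this count
    pad: int = 50                 # candidate window padding (nt)
    collapse_overlap: float = 0.5 # reciprocal overlap for merging hits


@dataclass
class KmerIndex:
    k: int
    step: int
    table: dict[str, list[tuple[str, int]]]
    contig_lengths: dict[str, int]


@dataclass
class ElementHit:
    interval: GenomicInterval
    subtype: str
    identity: float
    coverage: float
    n_seeds: int

    @property
    def score(self) -> float:
        return self.identity * self.coverage


def build_index(genome: list[SequenceRecord], k: int = 11, step: int = 5,
                max_kmer_freq: int = 1000) -> KmerIndex:
    """Index every k-mer starting at a multiple of ``step`` in each contig.

    K-mers containing N are excluded; k-mers seen more than
    ``max_kmer_freq`` times (repeat-heavy) are dropped from the table.
    Contigs shorter than k are skipped with a warning.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if step < 1:
        raise ValueError("step must be >= 1")
    table: dict[str, list[tuple[str, int]]] = {}
    lengths: dict[str, int] = {}
    for rec in genome:
        lengths[rec.id] = len(rec.seq)
        if len(rec.seq) < k:
            log.warning("contig %s shorter than k=%d; skipped", rec.id, k)
            continue
        seq = rec.seq
        for off in range(0, len(seq) - k + 1, step):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append((rec.id, off))
    if max_kmer_freq is not None:
        table = {km: locs for km, locs in table.items() if len(locs) <= max_kmer_freq}
    return KmerIndex(k=k, step=step, table=table, contig_lengths=lengths)


def _chain_seeds(seeds: list[tuple[int, int]], gap: int, min_seeds: int,
                 qlen: int, contig_len: int, pad: int) -> list[tuple[int, int, int]]:
    """Cluster (genome_offset, query_offset) seeds into candidate spans.

    Seeds are grouped by diagonal (genome − query offset) bands of width
    ``gap``; each band with >= min_seeds seeds yields one candidate span
    covering the full consensus projection, padded and clipped.
    Returns (start, end, n_seeds) tuples.
    """
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = [by_diag[0]]
    cur_diag = by_diag[0][0] - by_diag[0][1]
    for s in by_diag[1:]:
        d = s[0] - s[1]
        if d - cur_diag <= gap:
            cur.append(s)
        else:
            clusters.append(cur)
            cur = [s]
        cur_diag = d
    clusters.append(cur)
    out = []
    for cl in clusters:
        if len(cl) < min_seeds:
            continue
        starts = [g - q for g, q in cl]
        start = max(0, min(starts) - pad)
        end = min(contig_len, max(starts) + qlen + pad)
        if end > start:
            out.append((start, end, len(cl)))
    return out


def seed_and_chain(index: KmerIndex, consensus: SequenceRecord,
                   config: DiscoveryConfig | None = None
                   ) -> list[tuple[GenomicInterval, int]]:
    """Scan the consensus (stride 1, both orientations) and chain seed runs.

    Returns candidate intervals with their supporting seed counts.  The
    strand of each candidate records the orientation of the genomic copy
    relative to the consensus.
    """
    cfg = config or DiscoveryConfig(k=index.k, step=index.step)
    k = index.k
    candidates: list[tuple[GenomicInterval, int]] = []
    for strand, query in (("+", consensus.seq),
                          ("-", reverse_complement(consensus.seq))):
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for q in range(0, len(query) - k + 1):
            kmer = query[q : q + k]
            for contig, g in index.table.get(kmer, ()):
                per_contig.setdefault(contig, []).append((g, q))
        for contig, seeds in per_contig.items():
            spans = _chain_seeds(seeds, cfg.chain_gap, cfg.min_seeds,
                                 len(query), index.contig_lengths[contig],
                                 cfg.pad)
            for start, end, n in spans:
                candidates.append(
                    (GenomicInterval(contig, start, end, strand), n)
                )
    return candidates


def extend_and_score(candidate: GenomicInterval, n_seeds: int,
                     consensus: SequenceRecord, subtype: str,
                     genome: dict[str, str],
                     config: DiscoveryConfig | None = None) -> ElementHit | None:
    """Align the candidate window to the consensus; trim, score or discard.

    The window sequence (reverse-complemented for − strand candidates) is
    aligned end-gap-free in the window so the consensus locates itself
    within the padding; boundaries are trimmed to the outermost aligned
    consensus positions.  Candidates under the identity floor return None.
    """
    cfg = config or DiscoveryConfig()
    contig_seq = genome[candidate.contig]
    window = contig_seq[candidate.start : candidate.end]
    if candidate.strand == "-":
        window = reverse_complement(window)
    aln = semiglobal_align(window, consensus.seq)
    try:
        identity = gap_stripped_identity(aln)
    except ValueError:
        return None
    if identity < cfg.identity_floor:
        log.info("candidate %s discarded: identity %.1f below floor",
                 candidate.to_locus_string(), identity)
        return None
    # trim to outermost window positions aligned to consensus bases
    wpos = -1
    first = last = None
    cons_cols = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            wpos += 1
        if y != "-" and x != "-":
            if first is None:
                first = wpos
            last = wpos
            cons_cols += 1
    if first is None:
        return None
    coverage = cons_cols / len(consensus.seq)
    if candidate.strand == "+":
        start = candidate.start + first
        end = candidate.start + last + 1
    else:
        # window positions count from the right end of the genomic span
        end = candidate.end - first
        start = candidate.end - (last + 1)
    return ElementHit(
        interval=GenomicInterval(candidate.contig, start, end, candidate.strand),
        subtype=subtype,
        identity=identity,
        coverage=coverage,
        n_seeds=n_seeds,
    )


def _collapse(hits: list[ElementHit], threshold: float) -> list[ElementHit]:
    """Merge hits with reciprocal overlap above threshold, keeping the best."""
    hits = sorted(hits, key=lambda h: (-h.score, h.subtype,
                                       h.interval.contig, h.interval.start))
    kept: list[ElementHit] = []
    for h in hits:
        if any(h.interval.reciprocal_overlap(k.interval) > threshold
               for k in kept):
            continue
        kept.append(h)
    return kept


def discover_elements(genome: list[SequenceRecord],
                      refs: list["object"],
                      config: DiscoveryConfig | None = None) -> list[ElementHit]:
    """Full seed → chain → extend → collapse pipeline over all references.

    ``refs`` is a list of ConsensusReference (subtype + record).  Hits from
    different references overlapping reciprocally by more than the collapse
    threshold are reduced to the single hit with the highest
    identity × coverage; output is sorted by (contig, start).
    """
    if not refs:
        raise ValueError("at least one consensus reference is required")
    cfg = config or DiscoveryConfig()
    index = build_index(genome, cfg.k, cfg.step, cfg.max_kmer_freq)
    contig_seqs = {rec.id: rec.seq for rec in genome}
    hits: list[ElementHit] = []
    for ref in refs:
        for cand, n in seed_and_chain(index, ref.record, cfg):
            hit = extend_and_score(cand, n, ref.record, ref.subtype,
                                   contig_seqs, cfg)
            if hit is not None:
                hits.append(hit)
    kept = _collapse(hits, cfg.collapse_overlap)
    return sorted(kept, key=lambda h: (h.interval.contig, h.interval.start))
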