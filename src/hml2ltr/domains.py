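"""GREAT-style basal-plus-extension regulatory domains and gene association.

Each gene gets a basal domain of 5,000 bp upstream / 1,000 bp downstream
of its TSS (strand-aware); the domain is then extended in both directions
up to 1 Mb, stopping at the nearest neighboring gene's basal domain or the
contig edge.  An LTR element is associated with every gene whose extended
domain contains the element's midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discovery import ElementHit
from .sequence_io import GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    tss: int        # 0-based position of the transcription start site
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    tss: int
    strand: str
    basal: GenomicInterval
    extended: GenomicInterval


def _basal_bounds(g: GeneModel, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - up, g.tss + down
    return g.tss - down, g.tss + up


def build_regulatory_domains(
    genes: list[GeneModel],
    contig_lengths: dict[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1000000,
) -> list[RegulatoryDomain]:
    """Basal + extension domains per the stated association rule.

    Extension on each side reaches the nearest of: the neighboring gene's
    basal boundary, ``max_ext`` beyond the own basal boundary, or the
    contig edge.  Basal domains of different genes may overlap; the
    extended domain never shrinks below the basal one.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene set")
    domains: list[RegulatoryDomain] = []
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, group in by_contig.items():
        clen = contig_lengths[contig]
        group = sorted(group, key=lambda g: _basal_bounds(g, basal_up, basal_down)[0])
        bounds = [_basal_bounds(g, basal_up, basal_down) for g in group]
        clipped = [(max(0, s), min(clen, e)) for s, e in bounds]
        for i, g in enumerate(group):
            bstart, bend = clipped[i]
            left = max(bstart - max_ext, 0)
            if i > 0:
                left = max(left, clipped[i - 1][1])
            right = min(bend + max_ext, clen)
            if i + 1 < len(group):
                right = min(right, clipped[i + 1][0])
            ext_start = min(left, bstart)
            ext_end = max(right, bend)
            domains.append(RegulatoryDomain(
                gene_id=g.gene_id,
                tss=g.tss,
                strand=g.strand,
                basal=GenomicInterval(contig, bstart, bend, g.strand),
                extended=GenomicInterval(contig, ext_start, ext_end, g.strand),
            ))
    return sorted(domains, key=lambda d: (d.basal.contig, d.basal.start))


def associate_elements(
    elements: list[ElementHit],
    domains: list[RegulatoryDomain],
    whole_element: bool = False,
) -> dict[str, list[tuple[str, int]]]:
    """Element → [(gene_id, signed distance to TSS)] association map.

    By default an element associates with every gene whose extended domain
    contains the element midpoint; with ``whole_element=True`` any overlap
    of the element interval suffices.  Distances are midpoint − TSS,
    negated for − strand genes so that negative always means upstream of
    the gene.  Element strand is ignored.
    """
    out: dict[str, list[tuple[str, int]]] = {}
    for idx, el in enumerate(elements):
        key = f"{el.subtype}|{el.interval.to_locus_string()}"
        assoc: list[tuple[str, int]] = []
        mid = el.interval.midpoint
        for dom in domains:
            if dom.extended.contig != el.interval.contig:
                continue
            if whole_element:
                hit = el.interval.overlap(dom.extended) > 0
            else:
                hit = dom.extended.start <= mid < dom.extended.end
            if hit:
                dist = mid - dom.tss
                if dom.strand == "-":
                    dist = -dist
                assoc.append((dom.gene_id, dist))
        out[key] = sorted(assoc)
    return out


def overlap_sets(gene_sets: dict[str, set[str]]) -> dict[str, int]:
    """Three-way Venn region counts for per-subtype associated-gene sets.

    Keys are the sorted subtype names joined by ``&`` for intersections
    and the bare name for the exclusive regions; counts over the 7 regions
    sum to the size of the union.
    """
    if len(gene_sets) != 3:
        raise ValueError("overlap_sets expects exactly three gene sets")
    a_name, b_name, c_name = sorted(gene_sets)
    a, b, c = gene_sets[a_name], gene_sets[b_name], gene_sets[c_name]
    regions = {
        a_name: a - b - c,
        b_name: b - a - c,
        c_name: c - a - b,
        f"{a_name}&{b_name}": (a & b) - c,
        f"{a_name}&{c_name}": (a & c) - b,
        f"{b_name}&{c_name}": (b & c) - a,
        f"{a_name}&{b_name}&{c_name}": a & b & c,
    }
    return {k: len(v) for k, v in regions.items()}
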