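"""IUPAC consensus-motif scanning and per-subtype frequency statistics.

The transcription-factor binding sites that differentiate the LTR5Hs
promoter from the older subtypes are reported as exact consensus strings —
TATAAA (TATA box), AGGGAAAAACCG (NF-κB), GGGCTGG (TP53-1), GGGCAGC
(TP53-2), TGTATGCATAT (POU2F1) — scored within the −263..0
enhancer/core-promoter section.  Matching is exact IUPAC-degenerate on the
LTR sense strand; frequencies are percent of usable elements carrying at
least one match in the section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .frame import (
    AnchoringError,
    CoordinateFrame,
    FrameMap,
    SectionMissing,
    SectionSpec,
    anchor_to_frame,
    extract_section,
)
from .sequence_io import SequenceRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: the wild-type motif registry of the −263..0 section
CANONICAL_MOTIFS = {
    "TATA": "TATAAA",
    "NF-kB": "AGGGAAAAACCG",
    "TP53-1": "GGGCTGG",
    "TP53-2": "GGGCAGC",
    "POU2F1": "TGTATGCATAT",
}


@dataclass(frozen=True)
class MotifDef:
    """An IUPAC consensus motif, optionally restricted to a section."""

    name: str
    consensus: str
    region: SectionSpec | None = None
    source: str = "wildtype"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty motif consensus")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name!r}: non-IUPAC characters {bad}")


def canonical_motif_defs(region: SectionSpec | None = None) -> list[MotifDef]:
    return [MotifDef(name, cons, region=region)
            for name, cons in CANONICAL_MOTIFS.items()]


def scan_motif(seq: str, motif: MotifDef | str) -> list[int]:
    """All 0-based start positions of IUPAC-degenerate matches.

    Overlapping matches are all reported; scanning is on the given (sense)
    strand only.  A target N never satisfies a non-N motif position.
    """
    consensus = motif.consensus if isinstance(motif, MotifDef) else motif
    allowed = [IUPAC[c] for c in consensus]
    m = len(allowed)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(base in allow for base, allow in zip(window, allowed)):
            hits.append(i)
    return hits


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (matches printed-percentage style)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


@dataclass
class SectionExtraction:
    """Anchored section sequences plus the exclusion audit."""

    section: SectionSpec
    seqs: dict[str, str]               # element id -> section subsequence
    excluded: dict[str, str]           # element id -> reason


def extract_sections(elements: list[SequenceRecord], frame: CoordinateFrame,
                     section: SectionSpec,
                     min_coverage: float = 0.80) -> SectionExtraction:
    """Anchor every element and pull out its copy of the section.

    Elements that fail anchoring or whose section coverage is below the
    floor are excluded and enumerated, never silently dropped.
    """
    seqs: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for el in elements:
        try:
            fmap = anchor_to_frame(el, frame)
            seqs[el.id] = extract_section(fmap, section, min_coverage)
        except (AnchoringError, SectionMissing) as exc:
            excluded[el.id] = str(exc)
    return SectionExtraction(section=section, seqs=seqs, excluded=excluded)


def motif_frequency_table(
    sections_by_subtype: dict[str, SectionExtraction],
    motifs: list[MotifDef],
) -> pd.DataFrame:
    """Per-(subtype, motif) presence percentages.

    An element counts as present when its extracted section contains at
    least one match.  Subtypes with zero usable elements are omitted.
    Percentages are rounded half-up to two decimals.
    """
    rows = []
    for subtype in sorted(sections_by_subtype):
        ext = sections_by_subtype[subtype]
        n_total = len(ext.seqs)
        if n_total == 0:
            continue
        for motif in motifs:
            n_present = sum(bool(scan_motif(s, motif))
                            for s in ext.seqs.values())
            rows.append({
                "subtype": subtype,
                "motif": motif.name,
                "n_total": n_total,
                "n_present": n_present,
                "percent": _round2(100.0 * n_present / n_total),
            })
    return pd.DataFrame(rows)


def cooccurrence_frequency(ext: SectionExtraction, motif_a: MotifDef,
                           motif_b: MotifDef) -> tuple[int, float]:
    """(count, percent) of elements carrying both motifs in the section."""
    n_total = len(ext.seqs)
    if n_total == 0:
        raise ValueError("no usable elements")
    count = sum(
        bool(scan_motif(s, motif_a)) and bool(scan_motif(s, motif_b))
        for s in ext.seqs.values()
    )
    return count, _round2(100.0 * count / n_total)


@dataclass
class ConservationMatrix:
    """Per-column base counts and information content of anchored sequences."""

    counts: pd.DataFrame       # columns A,C,G,T; one row per position
    information: np.ndarray    # bits, in [0, 2]


def conservation_matrix(seqs: list[str]) -> ConservationMatrix:
    """WebLogo-style column statistics for positionally anchored sequences.

    Information content per column is ``2 − H`` bits with H the Shannon
    entropy of the base frequencies over non-gap, non-N observations (no
    small-sample correction).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be anchored to equal length")
    length = len(seqs[0])
    bases = "ACGT"
    counts = np.zeros((length, 4), dtype=int)
    for s in seqs:
        for i, ch in enumerate(s):
            j = bases.find(ch)
            if j >= 0:
                counts[i, j] += 1
    info = np.zeros(length)
    for i in range(length):
        total = counts[i].sum()
        if total == 0:
            info[i] = 0.0
            continue
        freqs = counts[i] / total
        h = -sum(f * math.log2(f) for f in freqs if f > 0)
        info[i] = 2.0 - h
    return ConservationMatrix(
        counts=pd.DataFrame(counts, columns=list(bases)),
        information=info,
    )
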