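"""Length screening and consensus-identity subtype assignment.

Discovered elements are kept for downstream statistics only if they span
at least 60% of the full-length family consensus of their subtype — the
same screen that reduces the raw genome-wide hit set to the curated
LTR5A/LTR5B/LTR5Hs element panels.  Subtype assignment for arbitrary
sequences is by highest gap-stripped identity to the subtype consensuses.
"""

from __future__ import annotations

from dataclasses import dataclass

from .discovery import ElementHit
from .sequence_io import (
    SequenceRecord,
    gap_stripped_identity,
    global_align,
)

SUBTYPES = ("LTR5A", "LTR5B", "LTR5Hs")


@dataclass(frozen=True)
class ConsensusReference:
    """A subtype consensus; its full length is the screening denominator."""

    subtype: str
    record: SequenceRecord

    @property
    def full_length(self) -> int:
        return len(self.record.seq)


def length_screen(hits: list[ElementHit],
                  refs: list[ConsensusReference],
                  frac: float = 0.60) -> list[ElementHit]:
    """Keep hits whose span is >= ``frac`` of their subtype's consensus length.

    Order is preserved; the operation is idempotent.
    """
    by_subtype = {r.subtype: r.full_length for r in refs}
    kept = []
    for h in hits:
        if h.subtype not in by_subtype:
            raise KeyError(f"no reference for subtype {h.subtype!r}")
        if len(h.interval) >= frac * by_subtype[h.subtype]:
            kept.append(h)
    return kept


def length_screen_records(records: list[SequenceRecord],
                          subtypes: list[str],
                          refs: list[ConsensusReference],
                          frac: float = 0.60) -> list[bool]:
    """Same screen applied to bare sequence records with known subtypes."""
    by_subtype = {r.subtype: r.full_length for r in refs}
    return [len(rec.seq) >= frac * by_subtype[st]
            for rec, st in zip(records, subtypes)]


def classify_by_consensus(element: SequenceRecord,
                          refs: list[ConsensusReference]
                          ) -> tuple[str, float]:
    """Assign the subtype whose consensus aligns with the highest identity.

    Ties are broken by higher coverage (fraction of the consensus in
    gap-free columns), then by subtype name order.  Screening is a separate
    stage: short elements are still classified.
    """
    if len(refs) < 2:
        raise ValueError("need at least two references to classify")
    best: tuple[float, float, str] | None = None
    best_subtype = None
    for ref in sorted(refs, key=lambda r: r.subtype):
        aln = global_align(element, ref.record)
        identity = gap_stripped_identity(aln)
        gapfree = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                      if x != "-" and y != "-")
        coverage = gapfree / ref.full_length
        key = (identity, coverage)
        if best is None or key > best[:2]:
            best = (identity, coverage, ref.subtype)
            best_subtype = ref.subtype
    assert best is not None
    return best_subtype, best[0]


def screening_report(records: list[SequenceRecord], subtypes: list[str],
                     refs: list[ConsensusReference], frac: float = 0.60):
    """Per-element screening table (element, length, ref length, kept)."""
    import pandas as pd

    by_subtype = {r.subtype: r.full_length for r in refs}
    rows = []
    for rec, st in zip(records, subtypes):
        ref_len = by_subtype[st]
        rows.append({
            "element": rec.id,
            "subtype": st,
            "length": len(rec.seq),
            "reference_length": ref_len,
            "kept": len(rec.seq) >= frac * ref_len,
        })
    return pd.DataFrame(rows)
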