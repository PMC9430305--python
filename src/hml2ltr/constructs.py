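"""In-silico reporter-construct design: section chimeras and site mutants.

Reproduces, on sequence level, the reporter-insert designs used to dissect
LTR promoter activity: the four chimeras in which one section of the LTR5B
backbone is replaced by the homologous LTR5Hs section (5Hs1-5B … 5Hs4-5B),
the site-directed binding-site mutants (TATAA→TGTAA, GGGCTGG→TGGCTGG,
GGGCAGC→TGGCAGC, AGGGAAAAACCG→AGGGGAGAATGG, TGTATGCATAT→30-nt LTR5B
homolog), and reverse-orientation inserts.  Every construct carries an
ordered, replayable edit list and length bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .frame import (
    CoordinateFrame,
    SectionSpec,
    anchor_to_frame,
    canonical_sections,
    validate_sections,
)
from .motifs import MotifDef, scan_motif
from .sequence_io import SequenceRecord, reverse_complement

#: printed wild-type → LTR5B-allele mutation strings
CANONICAL_MUTATIONS = {
    "TATA": ("TATAA", "TGTAA"),
    "NF-kB": ("AGGGAAAAACCG", "AGGGGAGAATGG"),
    "TP53-1": ("GGGCTGG", "TGGCTGG"),
    "TP53-2": ("GGGCAGC", "TGGCAGC"),
    "POU2F1": ("TGTATGCATAT", "TAGAGTCAAACATAAATCTGGCCTATGTGC"),
}


class MutationError(ValueError):
    """Site mutation could not be applied (absent or ambiguous site)."""


@dataclass(frozen=True)
class MutationDef:
    name: str
    from_seq: str
    to_seq: str
    occurrence: int | None = None  # which match to edit; None = must be unique

    def __post_init__(self) -> None:
        if not self.from_seq:
            raise ValueError("empty from_seq")


def canonical_mutation_defs() -> list[MutationDef]:
    return [MutationDef(name, f, t) for name, (f, t) in CANONICAL_MUTATIONS.items()]


@dataclass
class ConstructRecord:
    """A reporter insert with a replayable, ordered edit history."""

    name: str
    backbone: SequenceRecord
    edits: list[dict] = field(default_factory=list)
    final_seq: str = ""

    def __post_init__(self) -> None:
        if not self.final_seq:
            self.final_seq = self.backbone.seq

    @property
    def length_delta(self) -> int:
        return sum(len(e["inserted"]) - len(e["removed"]) for e in self.edits)

    def replay(self) -> str:
        """Re-apply the edit list to the backbone; must equal final_seq."""
        seq = self.backbone.seq
        for e in self.edits:
            s, t = e["span"]
            if seq[s:t] != e["removed"]:
                raise ValueError(
                    f"replay mismatch in construct {self.name!r} at {s}:{t}"
                )
            seq = seq[:s] + e["inserted"] + seq[t:]
        return seq

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(id=self.name, seq=self.final_seq)


def apply_site_mutation(seq: str, m: MutationDef) -> str:
    """Replace the designated occurrence of ``from_seq`` with ``to_seq``.

    Zero occurrences raise; multiple occurrences with no explicit
    ``occurrence`` index also raise, so an ambiguous site is never silently
    edited at its first match.
    """
    positions = scan_motif(seq, m.from_seq)
    if not positions:
        raise MutationError(f"mutation {m.name!r}: site {m.from_seq} not found")
    if len(positions) > 1 and m.occurrence is None:
        raise MutationError(
            f"mutation {m.name!r}: site {m.from_seq} occurs "
            f"{len(positions)} times; set occurrence to disambiguate"
        )
    idx = positions[0 if m.occurrence is None else m.occurrence]
    return seq[:idx] + m.to_seq + seq[idx + len(m.from_seq):]


def partition_sections(frame: CoordinateFrame) -> list[SectionSpec]:
    """The four canonical sections, validated against the frame extent."""
    sections = canonical_sections()
    validate_sections(sections)
    lo = min(s.start_rel for s in sections)
    hi = max(s.end_rel for s in sections)
    if frame.min_coord > lo or frame.max_coord < hi:
        raise ValueError(
            f"frame spans {frame.min_coord}..{frame.max_coord}; "
            f"sections need {lo}..{hi}"
        )
    return sections


def homologous_replace(backbone: SequenceRecord, donor: SequenceRecord,
                       section: SectionSpec, frame: CoordinateFrame,
                       name: str | None = None,
                       min_coverage: float = 0.80) -> ConstructRecord:
    """Replace the backbone's copy of ``section`` with the donor's copy.

    Both sequences are anchored to the frame; the backbone span homologous
    to the section (outermost mapped positions) is excised and the donor's
    homologous span inserted.  Flanks are untouched and the edit recorded.
    """
    bmap = anchor_to_frame(backbone, frame)
    dmap = anchor_to_frame(donor, frame)
    for label, fmap in (("backbone", bmap), ("donor", dmap)):
        if fmap.section_coverage(section) < min_coverage:
            raise ValueError(
                f"{label} {fmap.element.id!r} does not cover section "
                f"{section.name}"
            )
    bspan = bmap.section_span(section)
    dspan = dmap.section_span(section)
    assert bspan and dspan
    removed = backbone.seq[bspan[0] : bspan[1]]
    inserted = donor.seq[dspan[0] : dspan[1]]
    final = backbone.seq[: bspan[0]] + inserted + backbone.seq[bspan[1]:]
    rec = ConstructRecord(
        name=name or f"{section.name}-replacement",
        backbone=backbone,
        edits=[{
            "kind": "section_replacement",
            "section": section.name,
            "span": bspan,
            "removed": removed,
            "inserted": inserted,
        }],
        final_seq=final,
    )
    return rec


def mutate_construct(construct: ConstructRecord,
                     mutations: list[MutationDef],
                     name: str | None = None) -> ConstructRecord:
    """Apply ordered site mutations on top of an existing construct.

    Coordinates are re-derived after each edit, so unequal-length edits
    (e.g. the 11→30 nt POU2F1 replacement) compose correctly.
    """
    seq = construct.final_seq
    edits = list(construct.edits)
    for m in mutations:
        positions = scan_motif(seq, m.from_seq)
        if not positions:
            raise MutationError(f"mutation {m.name!r}: site not found")
        if len(positions) > 1 and m.occurrence is None:
            raise MutationError(
                f"mutation {m.name!r}: {len(positions)} sites; ambiguous")
        idx = positions[0 if m.occurrence is None else m.occurrence]
        edits.append({
            "kind": "site_mutation",
            "mutation": m.name,
            "span": (idx, idx + len(m.from_seq)),
            "removed": m.from_seq,
            "inserted": m.to_seq,
        })
        seq = seq[:idx] + m.to_seq + seq[idx + len(m.from_seq):]
    return ConstructRecord(
        name=name or f"{construct.name}+{'+'.join(m.name for m in mutations)}",
        backbone=construct.backbone,
        edits=edits,
        final_seq=seq,
    )


def reverse_orientation(construct: ConstructRecord) -> SequenceRecord:
    """The reverse-orientation insert of a construct."""
    return SequenceRecord(id=f"{construct.name}_rev",
                          seq=reverse_complement(construct.final_seq))


def validate_construct(construct: ConstructRecord,
                       motifs: list[MotifDef]) -> dict:
    """Presence/absence of each registry motif before/after edits, plus
    length and replay bookkeeping."""
    before = {m.name: bool(scan_motif(construct.backbone.seq, m))
              for m in motifs}
    after = {m.name: bool(scan_motif(construct.final_seq, m))
             for m in motifs}
    return {
        "construct": construct.name,
        "motifs_before": before,
        "motifs_after": after,
        "lost": sorted(n for n in before if before[n] and not after[n]),
        "gained": sorted(n for n in before if not before[n] and after[n]),
        "length_delta": construct.length_delta,
        "length_check": len(construct.final_seq)
        == len(construct.backbone.seq) + construct.length_delta,
        "replay_check": construct.replay() == construct.final_seq,
    }
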