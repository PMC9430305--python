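"""TSS-relative LTR coordinate frame, section definitions and anchoring.

The promoter architecture of an LTR is described in a coordinate frame in
which position +1 is the first base of the R region (the transcription
start site); U3 occupies the non-positive coordinates.  For the LTR5Hs
reference used here the frame spans −792..177, partitioned into the four
canonical sections −792..−553, −552..−264, −263..0 and 1..177 (inclusive
endpoints; 0 belongs to the upstream, U3-side section so that the four
sections tile the frame without gaps).

Arbitrary elements are projected into the frame by global alignment to the
frame reference; the resulting monotone coordinate map is what section
extraction, motif statistics and construct design operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import (
    SequenceRecord,
    gap_stripped_identity,
    global_align,
)

#: canonical section endpoints (name, start, end), inclusive, TSS-relative
CANONICAL_SECTIONS = (
    ("section1", -792, -553),
    ("section2", -552, -264),
    ("section3", -263, 0),
    ("section4", 1, 177),
)


class AnchoringError(ValueError):
    """Element could not be anchored to the frame reference."""


@dataclass(frozen=True)
class SectionSpec:
    """A TSS-relative region with inclusive printed-style endpoints."""

    name: str
    start_rel: int
    end_rel: int

    def __post_init__(self) -> None:
        if self.start_rel >= self.end_rel:
            raise ValueError(f"section {self.name}: start >= end")

    def __len__(self) -> int:
        return self.end_rel - self.start_rel + 1

    def positions(self) -> range:
        return range(self.start_rel, self.end_rel + 1)


@dataclass(frozen=True)
class CoordinateFrame:
    """A frame reference sequence with a declared TSS.

    ``r_start_index`` is the 0-based index of the base at frame coordinate
    +1 (the first base of R).  Frame coordinate of index i is
    ``i - r_start_index + 1``; coordinate 0 therefore exists and is the
    last U3 base.
    """

    record: SequenceRecord
    r_start_index: int

    def __post_init__(self) -> None:
        if not 0 < self.r_start_index <= len(self.record.seq):
            raise ValueError("r_start_index outside the frame reference")

    def coord_of(self, index: int) -> int:
        return index - self.r_start_index + 1

    def index_of(self, coord: int) -> int:
        return coord + self.r_start_index - 1

    @property
    def min_coord(self) -> int:
        return self.coord_of(0)

    @property
    def max_coord(self) -> int:
        return self.coord_of(len(self.record.seq) - 1)

    def subsequence(self, section: SectionSpec) -> str:
        lo, hi = self.index_of(section.start_rel), self.index_of(section.end_rel)
        if lo < 0 or hi >= len(self.record.seq):
            raise ValueError(f"section {section.name} outside frame")
        return self.record.seq[lo : hi + 1]


def canonical_sections() -> list[SectionSpec]:
    return [SectionSpec(n, s, e) for n, s, e in CANONICAL_SECTIONS]


def validate_sections(sections: list[SectionSpec]) -> None:
    """Reject overlapping section sets."""
    spans = sorted((s.start_rel, s.end_rel, s.name) for s in sections)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"sections {n1} and {n2} overlap")


@dataclass
class FrameMap:
    """Monotone map from TSS-relative frame coordinates to element positions."""

    frame: CoordinateFrame
    element: SequenceRecord
    mapping: dict[int, int]  # frame coordinate -> element 0-based index
    identity: float

    def get(self, coord: int) -> int | None:
        return self.mapping.get(coord)

    def section_coverage(self, section: SectionSpec) -> float:
        covered = sum(1 for c in section.positions() if c in self.mapping)
        return covered / len(section)

    def section_span(self, section: SectionSpec) -> tuple[int, int] | None:
        """Outermost mapped element positions of the section, half-open."""
        mapped = [self.mapping[c] for c in section.positions()
                  if c in self.mapping]
        if not mapped:
            return None
        return min(mapped), max(mapped) + 1


def anchor_to_frame(element: SequenceRecord, frame: CoordinateFrame,
                    min_identity: float = 60.0) -> FrameMap:
    """Project an element into the frame by global alignment.

    Gap columns produce no mapping; anchoring fails below the identity
    floor (default 60%), which rejects unrelated sequences.
    """
    aln = global_align(frame.record, element)
    try:
        identity = gap_stripped_identity(aln)
    except ValueError as exc:
        raise AnchoringError(str(exc)) from exc
    if identity < min_identity:
        raise AnchoringError(
            f"element {element.id!r}: identity {identity:.1f}% below "
            f"{min_identity:.0f}% anchoring floor"
        )
    mapping: dict[int, int] = {}
    fi = ei = -1
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-":
            fi += 1
        if y != "-":
            ei += 1
        if x != "-" and y != "-":
            mapping[frame.coord_of(fi)] = ei
    return FrameMap(frame=frame, element=element, mapping=mapping,
                    identity=identity)


class SectionMissing(ValueError):
    """Section not covered well enough by the anchoring map."""


def extract_section(fmap: FrameMap, section: SectionSpec,
                    min_coverage: float = 0.80) -> str:
    """Element subsequence spanning the outermost mapped section positions.

    Raises :class:`SectionMissing` when fewer than ``min_coverage`` of the
    section's frame positions are mapped (the element is then excluded from
    that section's statistics and counted in the exclusion report).
    """
    cov = fmap.section_coverage(section)
    if cov < min_coverage:
        raise SectionMissing(
            f"element {fmap.element.id!r}: section {section.name} coverage "
            f"{cov:.2f} below {min_coverage:.2f}"
        )
    span = fmap.section_span(section)
    assert span is not None
    return fmap.element.seq[span[0] : span[1]]
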