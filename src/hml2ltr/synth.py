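"""Synthetic data with known ground truth for every pipeline stage.

Real use of this package runs against hg38 and curated LTR element panels;
the test bed instead generates all inputs synthetically: three subtype
consensus sequences with a divergence structure mirroring the published
similarity statistics (LTR5B oldest and most diverged, LTR5Hs youngest,
LTR5A intermediate and derived from LTR5B), element sets mutated from
those consensuses, motif alleles planted at configured per-subtype
frequencies, solo-LTR copies planted on both strands of a background
genome, lognormal-noise luciferase plates and normal-noise CT tables.
All randomness flows from a single seed; truth tables are emitted so
recall, precision, frequency and effect recovery can be scored exactly.

The default generator parameters ARE the study conditions: panel sizes
43/62/194, per-subtype substitution rates calibrated to the printed mean
identities (e.g. 0.0175 → 98.25% for LTR5Hs), and the published motif
frequencies.  The consensus sequences themselves are synthetic stand-ins —
the real Dfam consensuses are not redistributed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frame import CoordinateFrame, SectionSpec, canonical_sections
from .motifs import CANONICAL_MOTIFS, scan_motif
from .constructs import CANONICAL_MUTATIONS
from .screening import ConsensusReference
from .sequence_io import GenomicInterval, SequenceRecord, reverse_complement

SUBTYPES = ("LTR5A", "LTR5B", "LTR5Hs")

#: element panel sizes of the curated study sets
DEFAULT_N_ELEMENTS = {"LTR5A": 43, "LTR5B": 62, "LTR5Hs": 194}

#: per-subtype element substitution rates, calibrated so that mean
#: gap-stripped identity to the own consensus matches the published
#: statistics (94.21% / 91.16% / 98.25%)
DEFAULT_SUB_RATES = {"LTR5A": 0.058, "LTR5B": 0.088, "LTR5Hs": 0.0175}

#: per-(subtype, motif) wild-type allele frequencies (published values;
#: the non-TATA motifs are specific to LTR5Hs)
DEFAULT_MOTIF_FREQS = {
    "LTR5A": {"TATA": 0.4651, "NF-kB": 0.0, "TP53-1": 0.0,
              "TP53-2": 0.0, "POU2F1": 0.0},
    "LTR5B": {"TATA": 0.7903, "NF-kB": 0.0, "TP53-1": 0.0,
              "TP53-2": 0.0, "POU2F1": 0.0},
    "LTR5Hs": {"TATA": 0.9845, "NF-kB": 0.7371, "TP53-1": 0.9278,
               "TP53-2": 0.9330, "POU2F1": 0.9485},
}

#: frame coordinates of the canonical motif sites (all inside −263..0)
MOTIF_SITE_COORDS = {
    "NF-kB": -250,
    "TP53-1": -200,
    "TP53-2": -150,
    "POU2F1": -120,
    "TATA": -30,
}

#: wild-type and LTR5B-variant alleles planted at the sites
MOTIF_ALLELES = {
    "TATA": ("TATAAA", "TGTAAA"),
    "NF-kB": ("AGGGAAAAACCG", "AGGGGAGAATGG"),
    "TP53-1": ("GGGCTGG", "TGGCTGG"),
    "TP53-2": ("GGGCAGC", "TGGCAGC"),
    "POU2F1": ("TGTATGCATAT", "TAGAGTCAAACATAAATCTGGCCTATGTGC"),
}

FRAME_LENGTH = 970          # covers −792..177 inclusive
R_START_INDEX = 793         # 0-based index of frame coordinate +1
DEFAULT_GC = 0.41           # human-like background GC

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic pipeline inputs."""

    seed: int = 0
    n_elements: dict = field(default_factory=lambda: dict(DEFAULT_N_ELEMENTS))
    sub_rates: dict = field(default_factory=lambda: dict(DEFAULT_SUB_RATES))
    indel_rate: float = 0.0
    motif_freqs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIF_FREQS.items()})
    background_length: int = 100_000
    gc: float = DEFAULT_GC
    min_spacing: int = 1000


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_background(length: int, gc: float, seed_or_rng) -> str:
    rng = _rng(seed_or_rng)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=probs))


def mutate_from_consensus(
    consensus: SequenceRecord | str,
    sub_rate: float,
    indel_rate: float,
    seed_or_rng,
    protect: list[tuple[int, int]] | None = None,
    new_id: str = "mutant",
    geometric_p: float = 0.5,
) -> tuple[SequenceRecord, np.ndarray]:
    """Per-site mutant of a consensus with a source→output position map.

    Substitutions occur per site with probability ``sub_rate`` and a 2:1
    transition:transversion ratio; indels initiate per site with
    probability ``indel_rate``, lengths geometric (p = ``geometric_p``),
    insertion/deletion equiprobable.  ``protect`` intervals (half-open,
    source coordinates) are exempt from all mutation, which keeps planted
    motif sites intact and mappable.  The returned ``posmap`` gives, for
    each source position, its 0-based output index or −1 if deleted.
    Deterministic for a fixed seed.
    """
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    seq = consensus.seq if isinstance(consensus, SequenceRecord) else consensus
    rng = _rng(seed_or_rng)
    n = len(seq)
    protected = np.zeros(n, dtype=bool)
    for s, e in protect or ():
        protected[s:e] = True
    out: list[str] = []
    posmap = np.full(n, -1, dtype=np.int64)
    skip = 0
    for i, base in enumerate(seq):
        if skip > 0:
            skip -= 1
            continue
        if not protected[i] and indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(geometric_p))
            if rng.random() < 0.5:
                out.extend(rng.choice(_BASES, size=length))
            else:
                # deletion of this and the following length-1 bases,
                # stopping short of any protected position
                end = i + length
                while end > i and protected[i:end].any():
                    end -= 1
                if end > i:
                    skip = end - i - 1
                    continue
        new = base
        if not protected[i] and base in _TRANSITION and rng.random() < sub_rate:
            if rng.random() < 2.0 / 3.0:
                new = _TRANSITION[base]
            else:
                tv = _TRANSVERSIONS[base]
                new = tv[int(rng.random() < 0.5)]
        posmap[i] = len(out)
        out.append(new)
    return SequenceRecord(id=new_id, seq="".join(out)), posmap


@dataclass
class SubtypeReferences:
    """Synthetic consensus trio with the LTR5Hs coordinate frame.

    ``site_indices[subtype][motif]`` is the 0-based start of the motif's
    canonical site in that subtype's consensus sequence.
    """

    frame: CoordinateFrame
    consensus: dict[str, SequenceRecord]
    site_indices: dict[str, dict[str, int]]

    def refs(self) -> list[ConsensusReference]:
        return [ConsensusReference(st, self.consensus[st]) for st in SUBTYPES]


def _scrub_spurious(seq_list: list[str], rng: np.random.Generator,
                    canonical: dict[str, int]) -> None:
    """Remove accidental motif matches outside the canonical sites.

    Mutates ``seq_list`` in place: any match of a wild-type or variant
    allele starting away from its motif's canonical site gets one base
    toggled (never inside a canonical allele span), so planted presence
    truth is exact and chance matches cannot inflate frequencies.
    """
    spans = []
    for name, idx in canonical.items():
        # reserve the longer allele's footprint at the canonical site
        width = max(len(a) for a in MOTIF_ALLELES[name])
        spans.append((idx, idx + width))

    def in_span(i: int) -> bool:
        return any(s <= i < e for s, e in spans)

    for _ in range(20):
        dirty = False
        seq = "".join(seq_list)
        for name, (wt, var) in MOTIF_ALLELES.items():
            for allele in (wt, var):
                for pos in scan_motif(seq, allele):
                    if pos == canonical.get(name):
                        continue
                    free = [i for i in range(pos, pos + len(allele))
                            if not in_span(i)]
                    if not free:
                        continue  # fully inside a planted site: not spurious
                    mid = free[len(free) // 2]
                    current = seq_list[mid]
                    others = [b for b in "ACGT" if b != current]
                    seq_list[mid] = others[int(rng.integers(len(others)))]
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub spurious motif matches")


def simulate_subtype_references(
    seed: int = 0,
    d_b_from_hs: float = 0.10,
    d_a_from_b: float = 0.055,
) -> SubtypeReferences:
    """Generate the synthetic consensus trio and the coordinate frame.

    The LTR5Hs frame (970 nt, coordinates −792..177) carries the wild-type
    motif alleles at fixed sites within −263..0.  LTR5B is derived from it
    at ``d_b_from_hs`` substitutions/site and LTR5A from LTR5B at
    ``d_a_from_b``, with the motif sites protected so they stay mappable;
    this reproduces the published divergence ordering (B most diverged
    from Hs, A intermediate, Hs clade well separated).
    """
    rng = _rng(seed)
    frame_idx = {m: MOTIF_SITE_COORDS[m] + R_START_INDEX - 1
                 for m in MOTIF_ALLELES}
    seq_list = list(random_background(FRAME_LENGTH, DEFAULT_GC, rng))
    for name, idx in frame_idx.items():
        wt = MOTIF_ALLELES[name][0]
        seq_list[idx : idx + len(wt)] = list(wt)
    _scrub_spurious(seq_list, rng, frame_idx)
    hs = SequenceRecord(id="LTR5Hs_consensus_synthetic", seq="".join(seq_list))
    frame = CoordinateFrame(record=hs, r_start_index=R_START_INDEX)

    protect_hs = [(i, i + len(MOTIF_ALLELES[m][0]))
                  for m, i in frame_idx.items()]
    b, posmap_b = mutate_from_consensus(
        hs, d_b_from_hs, 0.0, rng, protect=protect_hs,
        new_id="LTR5B_consensus_synthetic")
    sites_b = {m: int(posmap_b[i]) for m, i in frame_idx.items()}
    b_list = list(b.seq)
    _scrub_spurious(b_list, rng, sites_b)
    b = SequenceRecord(id=b.id, seq="".join(b_list))
    protect_b = [(i, i + len(MOTIF_ALLELES[m][0]))
                 for m, i in sites_b.items()]
    a, posmap_a = mutate_from_consensus(
        b, d_a_from_b, 0.0, rng, protect=protect_b,
        new_id="LTR5A_consensus_synthetic")
    sites_a = {m: int(posmap_a[i]) for m, i in sites_b.items()}
    a_list = list(a.seq)
    _scrub_spurious(a_list, rng, sites_a)
    a = SequenceRecord(id=a.id, seq="".join(a_list))
    return SubtypeReferences(
        frame=frame,
        consensus={"LTR5A": a, "LTR5B": b, "LTR5Hs": hs},
        site_indices={"LTR5A": sites_a, "LTR5B": sites_b, "LTR5Hs": frame_idx},
    )


def plant_motifs(element_seq: str, site_indices: dict[str, int],
                 freqs: dict[str, float], seed_or_rng
                 ) -> tuple[str, dict[str, bool]]:
    """Set each canonical site to the wild-type or variant allele.

    With probability ``freqs[motif]`` the site carries the wild-type
    consensus string, otherwise the published variant allele.  Motifs are
    planted independently; sites are rewritten right-to-left so
    unequal-length variant alleles (POU2F1) do not shift the others.
    Returns the edited sequence and the per-motif presence truth.
    """
    rng = _rng(seed_or_rng)
    presence: dict[str, bool] = {}
    # draw in fixed motif order for determinism, write right-to-left
    draws = {}
    for name in MOTIF_ALLELES:
        if name not in freqs:
            continue
        draws[name] = bool(rng.random() < freqs[name])
    seq = element_seq
    for name in sorted(draws, key=lambda m: site_indices[m], reverse=True):
        if name not in site_indices:
            continue
        idx = site_indices[name]
        wt, var = MOTIF_ALLELES[name]
        allele = wt if draws[name] else var
        seq = seq[:idx] + allele + seq[idx + len(wt):]
        presence[name] = draws[name]
    return seq, presence


def simulate_element(refs: SubtypeReferences, subtype: str,
                     seed_or_rng, sub_rate: float | None = None,
                     indel_rate: float = 0.0,
                     freqs: dict[str, float] | None = None,
                     element_id: str = "element"
                     ) -> tuple[SequenceRecord, dict[str, bool]]:
    """One element: consensus → per-site mutation → motif-allele planting."""
    rng = _rng(seed_or_rng)
    rate = DEFAULT_SUB_RATES[subtype] if sub_rate is None else sub_rate
    fr = DEFAULT_MOTIF_FREQS[subtype] if freqs is None else freqs
    sites = refs.site_indices[subtype]
    protect = [(i, i + len(MOTIF_ALLELES[m][0])) for m, i in sites.items()]
    rec, posmap = mutate_from_consensus(
        refs.consensus[subtype], rate, indel_rate, rng,
        protect=protect, new_id=element_id)
    mapped_sites = {m: int(posmap[i]) for m, i in sites.items()}
    seq, presence = plant_motifs(rec.seq, mapped_sites, fr, rng)
    # final site positions after unequal-length allele writes, then scrub
    # chance matches so presence truth is exact
    def planted_len(m: str) -> int:
        wt, var = MOTIF_ALLELES[m]
        if m not in presence:
            return len(wt)
        return len(wt) if presence[m] else len(var)

    final_sites = {}
    for m, idx in mapped_sites.items():
        shift = sum(planted_len(m2) - len(MOTIF_ALLELES[m2][0])
                    for m2, i2 in mapped_sites.items() if i2 < idx)
        final_sites[m] = idx + shift
    seq_list = list(seq)
    _scrub_spurious(seq_list, rng, final_sites)
    return SequenceRecord(id=element_id, seq="".join(seq_list)), presence


def simulate_element_sets(refs: SubtypeReferences, config: SimConfig
                          ) -> dict[str, tuple[list[SequenceRecord],
                                               list[dict[str, bool]]]]:
    """Full per-subtype element panels with motif-presence truth."""
    rng = _rng(config.seed)
    out = {}
    for subtype in SUBTYPES:
        records, truth = [], []
        for i in range(config.n_elements[subtype]):
            rec, presence = simulate_element(
                refs, subtype, rng,
                sub_rate=config.sub_rates[subtype],
                indel_rate=config.indel_rate,
                freqs=config.motif_freqs[subtype],
                element_id=f"{subtype}_{i:03d}")
            records.append(rec)
            truth.append(presence)
        out[subtype] = (records, truth)
    return out


def simulate_raw_length_panels(
    refs: SubtypeReferences,
    raw_sizes: dict[str, int],
    full_sizes: dict[str, int],
    seed: int,
    sub_rates: dict[str, float] | None = None,
) -> tuple[list[SequenceRecord], list[str]]:
    """Raw, unscreened panels in which only a known subset is full length.

    Mirrors what a genome-wide search returns before length screening: for
    each subtype, ``full_sizes[st]`` elements keep their whole span while
    the remainder are truncated windows shorter than 60% of the consensus
    (fragmentary solo-LTR copies).  Used to exercise the length screen with
    exact expected survivor counts.
    """
    rng = _rng(seed)
    rates = sub_rates or DEFAULT_SUB_RATES
    records: list[SequenceRecord] = []
    subtypes: list[str] = []
    for st in SUBTYPES:
        ref = refs.consensus[st]
        L = len(ref.seq)
        for i in range(raw_sizes[st]):
            rec, _ = mutate_from_consensus(ref, rates[st], 0.0, rng,
                                           new_id=f"{st}_raw{i:03d}")
            if i >= full_sizes[st]:
                frac = float(rng.uniform(0.10, 0.58))
                tlen = max(1, int(frac * L))
                start = int(rng.integers(0, L - tlen + 1))
                rec = SequenceRecord(id=rec.id,
                                     seq=rec.seq[start : start + tlen])
            records.append(rec)
            subtypes.append(st)
    return records, subtypes


@dataclass(frozen=True)
class PlantingTruth:
    element_id: str
    interval: GenomicInterval
    subtype: str
    strand: str
    divergence: float
    motif_presence: dict[str, bool]


def simulate_genome(
    refs: SubtypeReferences,
    n_per_subtype: dict[str, int],
    seed: int,
    background_length: int = 100_000,
    gc: float = DEFAULT_GC,
    sub_rates: dict[str, float] | None = None,
    min_spacing: int = 1000,
    contig_id: str = "synthetic_chr1",
) -> tuple[list[SequenceRecord], list[PlantingTruth]]:
    """Background contig with planted, diverged solo-LTR copies.

    Copies are indel-free (so planted coordinates are exact truth), placed
    non-overlapping with at least ``min_spacing`` between them, and
    reverse-complemented with probability one half.  Raises when the
    requested elements cannot be packed.
    """
    rng = _rng(seed)
    rates = sub_rates or DEFAULT_SUB_RATES
    elements = []
    for subtype in SUBTYPES:
        for i in range(n_per_subtype.get(subtype, 0)):
            rec, presence = simulate_element(
                refs, subtype, rng, sub_rate=rates[subtype], indel_rate=0.0,
                element_id=f"{subtype}_g{i:02d}")
            elements.append((rec, subtype, presence, rates[subtype]))
    total = sum(len(rec.seq) for rec, *_ in elements)
    n = len(elements)
    slack = background_length - total - (n + 1) * min_spacing
    if slack < 0:
        raise ValueError("infeasible packing: background too short")
    # split the slack into n+1 extra gap lengths by sorted uniform cuts
    cuts = np.concatenate([[0.0], np.sort(rng.random(n)) * slack, [float(slack)]])
    extras = np.diff(cuts).astype(int)
    gaps = [min_spacing + int(e) for e in extras]
    bg_needed = sum(gaps)
    background = random_background(bg_needed, gc, rng)
    pieces = []
    truth: list[PlantingTruth] = []
    cursor = 0          # consumed background
    out_len = 0         # length of assembled contig so far
    for k, (rec, subtype, presence, rate) in enumerate(elements):
        chunk = background[cursor : cursor + gaps[k]]
        cursor += gaps[k]
        pieces.append(chunk)
        out_len += len(chunk)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = rec.seq if strand == "+" else reverse_complement(rec.seq)
        start = out_len
        pieces.append(seq)
        out_len += len(seq)
        truth.append(PlantingTruth(
            element_id=rec.id,
            interval=GenomicInterval(contig_id, start, start + len(seq), strand),
            subtype=subtype,
            strand=strand,
            divergence=rate,
            motif_presence=presence,
        ))
    pieces.append(background[cursor:])
    contig = SequenceRecord(id=contig_id, seq="".join(pieces))
    return [contig], truth


def truth_table(truth: list[PlantingTruth]) -> pd.DataFrame:
    rows = []
    for t in truth:
        row = {
            "element_id": t.element_id,
            "contig": t.interval.contig,
            "start": t.interval.start,
            "end": t.interval.end,
            "strand": t.strand,
            "subtype": t.subtype,
            "divergence": t.divergence,
        }
        row.update({f"motif_{m}": v for m, v in t.motif_presence.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_luciferase_plate(
    effects: dict[tuple[str, str], float],
    sigma: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    empty_vector_id: str = "empty",
    baseline_ratio: float = 0.05,
    renilla_level: float = 1000.0,
) -> pd.DataFrame:
    """Replicate firefly/Renilla wells with lognormal multiplicative noise.

    ``effects[(construct, stimulus)]`` is the true normalized fold change;
    the empty vector in medium (fold 1) is always included.  Per well,
    F/R = fold × baseline × lognormal(0, σ) and Renilla is lognormal
    around a constant level, so firefly and Renilla are emitted separately.
    """
    rng = _rng(seed)
    all_effects = dict(effects)
    all_effects.setdefault((empty_vector_id, "medium"), 1.0)
    rows = []
    for (construct, stimulus), fold in sorted(all_effects.items()):
        for rep in range(1, n_reps + 1):
            renilla = renilla_level * np.exp(rng.normal(0.0, sigma))
            ratio = fold * baseline_ratio * np.exp(rng.normal(0.0, sigma))
            rows.append({
                "construct": construct,
                "stimulus": stimulus,
                "replicate": rep,
                "firefly": ratio * renilla,
                "renilla": renilla,
            })
    return pd.DataFrame(rows)


def simulate_qpcr(
    ddct_effects: dict[str, float],
    sigma_ct: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    target_gene: str = "TP53",
    ref_gene: str = "ACTB",
    control_sample: str = "NC",
    base_ct_target: float = 24.0,
    base_ct_ref: float = 16.0,
) -> pd.DataFrame:
    """CT table in which sample s has ΔΔCT(s vs control) = ddct_effects[s].

    The target-gene CT of each treated sample is shifted by its ΔΔCT
    effect; replicate noise is normal with ``sigma_ct`` cycles, so
    ``ddct_fold`` recovers 2^−ΔΔCT exactly at σ = 0.
    """
    rng = _rng(seed)
    samples = [control_sample] + sorted(ddct_effects)
    rows = []
    for sample in samples:
        shift = 0.0 if sample == control_sample else ddct_effects[sample]
        for gene, base in ((target_gene, base_ct_target + shift),
                           (ref_gene, base_ct_ref)):
            for rep in range(1, n_reps + 1):
                rows.append({
                    "sample": sample,
                    "gene": gene,
                    "replicate": rep,
                    "ct": base + rng.normal(0.0, sigma_ct),
                })
    return pd.DataFrame(rows)
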