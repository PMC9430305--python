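"""Frame anchoring, section extraction, IUPAC motif scanning and statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hml2ltr import synth
from hml2ltr.frame import (
    AnchoringError,
    CoordinateFrame,
    SectionMissing,
    SectionSpec,
    anchor_to_frame,
    canonical_sections,
    extract_section,
)
from hml2ltr.motifs import (
    IUPAC,
    MotifDef,
    canonical_motif_defs,
    conservation_matrix,
    cooccurrence_frequency,
    extract_sections,
    motif_frequency_table,
    scan_motif,
    SectionExtraction,
)
from hml2ltr.sequence_io import SequenceRecord


def brute_force_scan(seq, consensus):
    """Independent position-by-position IUPAC matcher."""
    out = []
    for i in range(len(seq) - len(consensus) + 1):
        ok = True
        for j, c in enumerate(consensus):
            if seq[i + j] not in IUPAC[c]:
                ok = False
                break
        if ok:
            out.append(i)
    return out


class TestScanMotif:
    def test_direct_and_wildcard_matches(self):
        assert scan_motif("GGTATAAACC", MotifDef("TATA", "TATAAA")) == [2]
        assert scan_motif("CCATGTT", MotifDef("YY1", "CCATNTT")) == [0]
        assert scan_motif("AAAA", MotifDef("x", "TTT")) == []

    def test_overlapping_matches_all_reported(self):
        assert scan_motif("AAAAA", MotifDef("x", "AA")) == [0, 1, 2, 3]

    def test_matches_bruteforce_oracle_on_random_strings(self):
        rng = np.random.default_rng(17)
        motifs = ["TATAAA", "GGGCTGG", "CCATNTT", "RYSWKM", "ATGCMAA"]
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGTN"), size=rng.integers(5, 60)))
            m = motifs[int(rng.integers(len(motifs)))]
            assert scan_motif(seq, MotifDef("m", m)) == brute_force_scan(seq, m)

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            MotifDef("bad", "TAT!AA")


class TestFrame:
    def test_canonical_sections_partition_without_gaps(self):
        secs = canonical_sections()
        assert [len(s) for s in secs] == [240, 289, 264, 177]
        covered = sorted(p for s in secs for p in s.positions())
        assert covered == list(range(-792, 178))

    def test_coordinate_round_trip(self, frame):
        for coord in (-792, -263, 0, 1, 177):
            assert frame.coord_of(frame.index_of(coord)) == coord

    def test_identity_map_on_frame_reference(self, frame):
        fmap = anchor_to_frame(frame.record, frame)
        assert fmap.identity == 100.0
        for coord in range(frame.min_coord, frame.max_coord + 1):
            assert fmap.get(coord) == frame.index_of(coord)

    def test_deletion_upstream_does_not_shift_section3(self, frame):
        # remove 10 nt well upstream of -263; section3 must map with no offset
        cut = frame.index_of(-500)
        seq = frame.record.seq
        mutant = SequenceRecord(id="del10", seq=seq[:cut] + seq[cut + 10:])
        fmap = anchor_to_frame(mutant, frame)
        sec3 = canonical_sections()[2]
        for coord in sec3.positions():
            assert fmap.get(coord) == frame.index_of(coord) - 10
        assert extract_section(fmap, sec3) == frame.subsequence(sec3)

    def test_unrelated_sequence_fails_anchoring(self, frame, rng):
        junk = SequenceRecord(id="junk", seq="".join(
            rng.choice(list("ACGT"), size=len(frame.record.seq))))
        with pytest.raises(AnchoringError):
            anchor_to_frame(junk, frame)

    def test_identity_map_section4_is_last_177(self, frame):
        fmap = anchor_to_frame(frame.record, frame)
        sec4 = canonical_sections()[3]
        assert extract_section(fmap, sec4) == frame.record.seq[-177:]

    def test_unmapped_section_flagged(self, frame):
        # element missing the whole of section 4
        seq = frame.record.seq[: frame.index_of(0) + 1]
        truncated = SequenceRecord(id="trunc", seq=seq)
        fmap = anchor_to_frame(truncated, frame)
        with pytest.raises(SectionMissing):
            extract_section(fmap, canonical_sections()[3])

    def test_internal_deletion_shortens_extraction(self, frame):
        sec3 = canonical_sections()[2]
        cut = frame.index_of(-100)
        seq = frame.record.seq
        mutant = SequenceRecord(id="del20", seq=seq[:cut] + seq[cut + 20:])
        fmap = anchor_to_frame(mutant, frame)
        extracted = extract_section(fmap, sec3)
        assert len(extracted) == len(sec3) - 20


class TestFrequencies:
    def _ext(self, seqs):
        return SectionExtraction(
            section=SectionSpec("s", -263, 0),
            seqs={f"e{i}": s for i, s in enumerate(seqs)},
            excluded={})

    def test_hand_counted_percentages(self):
        ext = self._ext(["TATAAACC", "GGTATAAA", "TTTTTTTT", "ATATAAAT"])
        table = motif_frequency_table(
            {"LTR5Hs": ext}, [MotifDef("TATA", "TATAAA")])
        row = table.iloc[0]
        assert row["n_total"] == 4
        assert row["n_present"] == 3
        assert row["percent"] == 75.00

    def test_absent_motif_is_zero(self):
        ext = self._ext(["AAAA", "CCCC"])
        table = motif_frequency_table({"x": ext}, [MotifDef("m", "GGGCTGG")])
        assert table.iloc[0]["percent"] == 0.00

    def test_empty_subtype_omitted(self):
        table = motif_frequency_table(
            {"empty": self._ext([])}, [MotifDef("m", "AA")])
        assert table.empty

    def test_order_invariance(self):
        seqs = ["TATAAA", "CCCCCC", "GGTATAAAGG", "TTTT"]
        t1 = motif_frequency_table({"s": self._ext(seqs)},
                                   [MotifDef("TATA", "TATAAA")])
        t2 = motif_frequency_table({"s": self._ext(seqs[::-1])},
                                   [MotifDef("TATA", "TATAAA")])
        assert t1["percent"].tolist() == t2["percent"].tolist()

    def test_cooccurrence_hand_count(self):
        # A in elements {1,2}, B in {2,3}, n=4 -> (1, 25.00)
        seqs = ["GGGGGG", "AATTAA", "AATTCC", "CCCCCC"]
        # A = AATT matches e1,e2 ; B = CC matches e2,e3
        ext = self._ext(seqs)
        count, pct = cooccurrence_frequency(
            ext, MotifDef("A", "AATT"), MotifDef("B", "CC"))
        assert (count, pct) == (1, 25.00)

    def test_cooccurrence_degenerate_equals_single(self):
        seqs = ["TATAAA", "CCCCCC", "TATAAA"]
        ext = self._ext(seqs)
        m = MotifDef("TATA", "TATAAA")
        count, pct = cooccurrence_frequency(ext, m, m)
        assert (count, pct) == (2, pytest.approx(66.67))

    def test_cooccurrence_bounded_by_singles(self, refs):
        cfg = synth.SimConfig(seed=3, n_elements={"LTR5A": 0, "LTR5B": 0,
                                                  "LTR5Hs": 40})
        sets = synth.simulate_element_sets(refs, cfg)
        records, _ = sets["LTR5Hs"]
        sec3 = canonical_sections()[2]
        ext = extract_sections(records, refs.frame, sec3)
        motifs = {m.name: m for m in canonical_motif_defs()}
        table = motif_frequency_table({"LTR5Hs": ext}, list(motifs.values()))
        singles = dict(zip(table["motif"], table["percent"]))
        _, pct = cooccurrence_frequency(ext, motifs["TP53-1"], motifs["TP53-2"])
        assert pct <= min(singles["TP53-1"], singles["TP53-2"]) + 1e-9


class TestConservation:
    def test_identical_sequences_full_information(self):
        cm = conservation_matrix(["TATAAA"] * 5)
        assert np.allclose(cm.information, 2.0)

    def test_even_two_base_split_one_bit(self):
        cm = conservation_matrix(["AC", "AG", "AC", "AG"])
        assert cm.information[0] == pytest.approx(2.0)
        assert cm.information[1] == pytest.approx(1.0)

    def test_hand_computed_entropy_block(self):
        # column: A,A,C,G -> H = 1.5 bits -> IC = 0.5
        cm = conservation_matrix(["A", "A", "C", "G"])
        h = -(0.5 * math.log2(0.5) + 2 * 0.25 * math.log2(0.25))
        assert cm.information[0] == pytest.approx(2.0 - h)
        assert cm.counts.iloc[0].tolist() == [2, 1, 1, 0]

    def test_information_bounds(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(10)]
        cm = conservation_matrix(seqs)
        assert np.all(cm.information >= 0.0)
        assert np.all(cm.information <= 2.0)
        assert (cm.counts.sum(axis=1) == 10).all()


class TestPlantedFrequencies:
    @pytest.mark.parametrize("subtype,n", [("LTR5A", 43), ("LTR5B", 62),
                                           ("LTR5Hs", 194)])
    def test_recovered_frequency_within_binomial_99ci(self, refs, subtype, n):
        """Planted wild-type-allele frequencies are recovered within the
        exact binomial 99% interval at the study panel sizes."""
        from scipy import stats

        cfg = synth.SimConfig(seed=11)
        sets = synth.simulate_element_sets(refs, cfg)
        records, truth = sets[subtype]
        assert len(records) == n
        sec3 = canonical_sections()[2]
        ext = extract_sections(records, refs.frame, sec3)
        assert not ext.excluded
        table = motif_frequency_table(
            {subtype: ext}, canonical_motif_defs())
        for _, row in table.iterrows():
            p = cfg.motif_freqs[subtype][row["motif"]]
            lo, hi = stats.binom.interval(0.99, n, p) if 0 < p < 1 else (
                (0, 0) if p == 0 else (n, n))
            assert lo <= row["n_present"] <= hi, (
                f"{subtype}/{row['motif']}: {row['n_present']} outside "
                f"[{lo}, {hi}] for p={p}")

    def test_presence_matches_planting_truth(self, refs):
        """Scanning the extracted section reproduces the per-element truth."""
        cfg = synth.SimConfig(seed=23, n_elements={"LTR5A": 0, "LTR5B": 0,
                                                   "LTR5Hs": 50})
        sets = synth.simulate_element_sets(refs, cfg)
        records, truth = sets["LTR5Hs"]
        sec3 = canonical_sections()[2]
        ext = extract_sections(records, refs.frame, sec3)
        mismatches = 0
        for rec, t in zip(records, truth):
            seq = ext.seqs[rec.id]
            for m in canonical_motif_defs():
                observed = bool(scan_motif(seq, m))
                if observed != t[m.name]:
                    mismatches += 1
        # random substitutions can occasionally create a spurious match,
        # but truth and scan must agree essentially everywhere
        assert mismatches <= 2
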