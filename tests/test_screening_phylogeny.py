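"""Length screen, subtype classification, K2P distances, NJ and bootstrap."""

import math

import numpy as np
import pytest

from hml2ltr import synth
from hml2ltr.discovery import ElementHit
from hml2ltr.phylogeny import (
    DistanceMatrix,
    SATURATION_CEILING,
    SaturationError,
    bipartitions,
    bootstrap_support,
    clade_support,
    distance_matrix,
    k2p_distance,
    nj_tree,
)
from hml2ltr.screening import ConsensusReference, classify_by_consensus, length_screen
from hml2ltr.sequence_io import GenomicInterval, SequenceRecord


def _hit(length, subtype):
    return ElementHit(
        interval=GenomicInterval("c", 1000, 1000 + length),
        subtype=subtype, identity=95.0, coverage=1.0, n_seeds=10)


def _ref(subtype, length):
    return ConsensusReference(subtype, SequenceRecord(id=subtype, seq="A" * length))


class TestLengthScreen:
    def test_threshold_arithmetic(self):
        refs = [_ref("LTR5Hs", 1000)]
        kept = length_screen([_hit(650, "LTR5Hs"), _hit(599, "LTR5Hs"),
                              _hit(600, "LTR5Hs")], refs)
        assert [len(h.interval) for h in kept] == [650, 600]

    def test_frac_zero_keeps_all(self):
        refs = [_ref("LTR5Hs", 1000)]
        hits = [_hit(10, "LTR5Hs"), _hit(999, "LTR5Hs")]
        assert length_screen(hits, refs, frac=0.0) == hits

    def test_idempotent_and_order_preserving(self):
        refs = [_ref("LTR5A", 900), _ref("LTR5B", 1000)]
        hits = [_hit(899, "LTR5B"), _hit(540, "LTR5A"), _hit(539, "LTR5A")]
        once = length_screen(hits, refs)
        assert length_screen(once, refs) == once
        assert [len(h.interval) for h in once] == [899, 540]

    def test_missing_reference_is_an_error(self):
        with pytest.raises(KeyError):
            length_screen([_hit(650, "LTR5Hs")], [_ref("LTR5A", 900)])


class TestClassification:
    def test_consensus_classifies_as_itself(self, refs, consensus_refs):
        st, ident = classify_by_consensus(refs.consensus["LTR5Hs"], consensus_refs)
        assert st == "LTR5Hs"
        assert ident == 100.0

    def test_short_elements_still_classified(self, refs, consensus_refs):
        frag = SequenceRecord(id="frag", seq=refs.consensus["LTR5B"].seq[:300])
        st, _ = classify_by_consensus(frag, consensus_refs)
        assert st == "LTR5B"

    def test_accuracy_on_diverged_synthetic_elements(self, refs, consensus_refs):
        """>=99% correct over 100 seeded elements at 8% divergence."""
        rng = np.random.default_rng(21)
        correct = total = 0
        for i in range(100):
            subtype = synth.SUBTYPES[i % 3]
            rec, _ = synth.simulate_element(
                refs, subtype, rng, sub_rate=0.08, element_id=f"e{i}")
            st, _ = classify_by_consensus(rec, consensus_refs)
            total += 1
            correct += st == subtype
        assert correct / total >= 0.99

    def test_needs_two_references(self, refs, consensus_refs):
        with pytest.raises(ValueError):
            classify_by_consensus(refs.consensus["LTR5A"], consensus_refs[:1])


class TestK2P:
    def test_identical_is_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_pure_transition_hand_value(self):
        # P=0.25, Q=0: -1/2 ln(0.5)
        assert k2p_distance("AAAA", "AAGA") == pytest.approx(0.34657, abs=1e-5)

    def test_pure_transversion_hand_value(self):
        # P=0, Q=0.25: -1/2 ln(0.75) - 1/4 ln(0.5) = 0.3171278
        assert k2p_distance("AAAA", "AACA") == pytest.approx(
            -0.5 * math.log(0.75) - 0.25 * math.log(0.5), abs=1e-12)
        assert k2p_distance("AAAA", "AACA") == pytest.approx(0.31713, abs=1e-5)

    def test_saturation_flagged_or_ceiled(self):
        a, b = "AAAA", "GGGG"  # P=1 -> saturated
        assert k2p_distance(a, b) == SATURATION_CEILING
        with pytest.raises(SaturationError):
            k2p_distance(a, b, ceiling=None)

    def test_approaches_p_distance_for_small_divergence(self):
        """d -> p as p -> 0 (relative error < 5% at p <= 0.02)."""
        n = 1000
        for n_diff in (5, 10, 20):
            a = "A" * n
            b = "G" * n_diff + "A" * (n - n_diff)
            p = n_diff / n
            d = k2p_distance(a, b)
            assert abs(d - p) / p < 0.05

    def test_gap_columns_excluded(self):
        assert k2p_distance("A-CG", "AAC-") == 0.0

    def test_vectorized_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(6)]
        recs = [SequenceRecord(id=f"s{i}", seq=s) for i, s in enumerate(seqs)]
        dm = distance_matrix(recs, aligned=True)
        for i in range(6):
            for j in range(i + 1, 6):
                expected = k2p_distance(seqs[i], seqs[j])
                assert dm.d[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], d=d))
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # hand-drawn tree: (A:2,B:3)-x, x-y internal 4, (C:1,D:5)-y
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 5, 7, 11],
            [5, 0, 8, 12],
            [7, 8, 0, 6],
            [11, 12, 6, 0],
        ], float)
        tree = nj_tree(DistanceMatrix(labels=labels, d=d))
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 1, "D": 5})

    def test_nj_matches_independent_implementation(self):
        """Topology agrees with scikit-bio's NJ on random distance matrices."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        for trial in range(5):
            n = 7
            pts = rng.random((n, 4)) * 10
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            labels = [f"t{i}" for i in range(n)]
            ours = nj_tree(DistanceMatrix(labels=labels, d=d))
            theirs = skbio_nj(SkbioDM(d, ids=labels))
            their_bps = set()
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                other = frozenset(labels) - side
                if 1 < len(side) < n - 1:
                    canon = side if len(side) < len(other) else (
                        other if len(other) < len(side)
                        else min(side, other, key=sorted))
                    their_bps.add(canon)
            assert bipartitions(ours) == their_bps

    def test_rejects_asymmetric_matrix(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            DistanceMatrix(labels=list("ABC"), d=d)

    def test_negative_branches_clamped(self):
        d = np.array([
            [0, 1, 9, 9],
            [1, 0, 9, 9],
            [9, 9, 0, 0.1],
            [9, 9, 0.1, 0],
        ], float)
        tree = nj_tree(DistanceMatrix(labels=list("ABCD"), d=d))
        assert all(l.length >= 0 for l in tree.leaves())


class TestBootstrap:
    def _two_clade_records(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=500))
        other = list(base)
        for i in rng.choice(500, size=50, replace=False):  # 10% divergence
            other[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[i]]
        other = "".join(other)
        recs = [SequenceRecord(id=f"x{i}", seq=base) for i in range(3)]
        recs += [SequenceRecord(id=f"y{i}", seq=other) for i in range(3)]
        return recs

    def test_clean_split_gets_full_support(self):
        recs = self._two_clade_records()
        tree = bootstrap_support(recs, n_reps=50, seed=1)
        support = clade_support(tree, {"x0", "x1", "x2"})
        assert support == 1.0

    def test_reproducible_for_fixed_seed(self):
        recs = self._two_clade_records()
        t1 = bootstrap_support(recs, n_reps=30, seed=7)
        t2 = bootstrap_support(recs, n_reps=30, seed=7)
        assert t1.newick() == t2.newick()

    def test_invalid_inputs_rejected(self):
        recs = self._two_clade_records()
        with pytest.raises(ValueError):
            bootstrap_support(recs, n_reps=0, seed=1)
        ragged = recs[:5] + [SequenceRecord(id="short", seq="ACGT")]
        with pytest.raises(ValueError):
            bootstrap_support(ragged, n_reps=10, seed=1)

    def test_three_subtype_structure(self, refs):
        """LTR5Hs monophyletic (support >= 0.9); LTR5A nested in LTR5B."""
        rng = np.random.default_rng(7)
        recs = []
        for st in synth.SUBTYPES:
            for i in range(10):
                rec, _ = synth.simulate_element(
                    refs, st, rng, freqs={}, element_id=f"{st}_{i}")
                recs.append(rec)
        tree = bootstrap_support(recs, n_reps=100, seed=3)
        hs = {n for n in tree.leaf_names() if n.startswith("LTR5Hs")}
        a = {n for n in tree.leaf_names() if n.startswith("LTR5A")}
        assert clade_support(tree, hs) is not None
        assert clade_support(tree, hs) >= 0.9
        # LTR5A forms a clade strictly inside the non-Hs side of the tree
        assert clade_support(tree, a) is not None
        assert not a & hs


def test_newick_output_parses_with_dendropy():
    import dendropy

    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], d=d))
    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"A", "B", "C"}
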