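import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from ppikernel.io_formats import EvidencedInteraction, ProteinRecord
from ppikernel.similarity import (
    SamplingConfig,
    align_identity,
    hssp_threshold,
    hval,
    reduce_redundancy,
    sample_negatives,
)
from helpers import random_sequence


def _biopython_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


class TestAlignIdentity:
    def test_identical_sequences(self, rng):
        seq = random_sequence(rng, 100)
        summary = align_identity(seq, seq)
        assert summary.pide == 100.0
        assert summary.length == 100

    def test_single_substitution_of_hundred(self, rng):
        seq = random_sequence(rng, 100)
        other = "A" + seq[1:] if seq[0] != "A" else "C" + seq[1:]
        summary = align_identity(seq, other)
        assert summary.pide == pytest.approx(99.0)
        assert summary.length == 100

    def test_symmetry(self, rng):
        for _ in range(5):
            a = random_sequence(rng, int(rng.integers(30, 80)))
            b = random_sequence(rng, int(rng.integers(30, 80)))
            assert align_identity(a, b) == align_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_identity("", "ACDE")

    def test_scores_match_independent_aligner(self, rng):
        """Optimal global alignment scores agree with Bio.Align.PairwiseAligner
        configured with the same matrix and gap penalties."""
        aligner = _biopython_aligner()
        for _ in range(15):
            a = random_sequence(rng, int(rng.integers(20, 90)))
            b = random_sequence(rng, int(rng.integers(20, 90)))
            assert align_identity(a, b).score == pytest.approx(aligner.score(a, b))


class TestHsspThreshold:
    def test_anchor_values(self):
        assert hssp_threshold(250) == pytest.approx(20.7, abs=0.05)
        assert hssp_threshold(10_000) == 19.5
        assert hssp_threshold(5) == 100.0

    def test_continuity_at_curve_plateau(self):
        assert abs(hssp_threshold(450) - 19.5) < 0.1

    def test_monotone_non_increasing_within_tolerance(self):
        """The curve decays with length; the closed form has a sub-0.05-point
        local rise just before the 450-residue plateau, so monotonicity is
        asserted to that tolerance."""
        values = [hssp_threshold(L) for L in range(12, 600, 7)]
        assert all(b <= a + 0.05 for a, b in zip(values, values[1:]))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            hssp_threshold(0)


class TestHval:
    def test_identical_length_250_pair(self, rng):
        seq = random_sequence(rng, 250)
        assert hval(seq, seq) == pytest.approx(100 - 20.715, abs=0.05)

    def test_unrelated_pair_far_below_homology_cut(self, rng):
        a = random_sequence(rng, 250)
        b = random_sequence(rng, 250)
        assert hval(a, b) < 0

    def test_equals_pide_minus_threshold(self, rng):
        a = random_sequence(rng, 120)
        b = random_sequence(rng, 120)
        summary = align_identity(a, b)
        assert hval(a, b) == pytest.approx(summary.pide - hssp_threshold(summary.length))


class TestReduceRedundancy:
    def _interactions(self, pairs, score=10.0):
        return [EvidencedInteraction(a, b, [("x-ray crystallography", score)]) for a, b in pairs]

    def test_duplicate_interaction_removed(self, small_proteome):
        seqs = {r.id: r.sequence for r in small_proteome}
        inters = self._interactions([("q000", "q001"), ("q000", "q001")])
        assert len(reduce_redundancy(inters, seqs)) == 1

    def test_shared_protein_triggers_removal(self, small_proteome):
        seqs = {r.id: r.sequence for r in small_proteome}
        inters = self._interactions([("q000", "q001"), ("q001", "q002")])
        kept = reduce_redundancy(inters, seqs)
        assert [it.pair for it in kept] == [("q000", "q001")]

    def test_mutually_unrelated_interactions_all_retained(self, small_proteome):
        seqs = {r.id: r.sequence for r in small_proteome}
        pairs = [(f"q{2*i:03d}", f"q{2*i+1:03d}") for i in range(8)]
        kept = reduce_redundancy(self._interactions(pairs), seqs)
        assert len(kept) == 8

    def test_best_evidenced_representative_survives(self, small_proteome):
        seqs = {r.id: r.sequence for r in small_proteome}
        weak = EvidencedInteraction("q000", "q001", [("pull down", 2.5)])
        strong = EvidencedInteraction("q001", "q002", [("x-ray crystallography", 10.0)])
        kept = reduce_redundancy([weak, strong], seqs)
        assert [it.pair for it in kept] == [("q001", "q002")]

    def test_postconditions_each_protein_once_and_cross_hvals_low(self, small_proteome, rng):
        seqs = {r.id: r.sequence for r in small_proteome}
        ids = [r.id for r in small_proteome]
        pairs = set()
        while len(pairs) < 15:
            i, j = rng.integers(0, len(ids), 2)
            if i != j:
                pairs.add(tuple(sorted((ids[i], ids[j]))))
        kept = reduce_redundancy(self._interactions(sorted(pairs)), seqs)
        proteins = [p for it in kept for p in it.pair]
        assert len(proteins) == len(set(proteins))
        for it_a in kept:
            for it_b in kept:
                if it_a.pair >= it_b.pair:
                    continue
                for p in it_a.pair:
                    for q in it_b.pair:
                        assert hval(seqs[p], seqs[q]) <= 20.0

    def test_missing_sequence_is_an_error(self):
        with pytest.raises(KeyError, match="ghost"):
            reduce_redundancy(self._interactions([("ghost", "q001")]), {"q001": "ACDE"})


class TestSampleNegatives:
    def _positives(self, n):
        return [
            EvidencedInteraction(f"q{2*i:03d}", f"q{2*i+1:03d}", [("pull down", 2.5)])
            for i in range(n)
        ]

    def test_exact_ratio_and_constraints(self, small_proteome):
        positives = self._positives(5)
        config = SamplingConfig(negative_ratio=3, seed=42)
        negatives = sample_negatives(positives, small_proteome, config)
        assert len(negatives) == 15
        assert len(set(negatives)) == 15
        pos_pairs = {p.pair for p in positives}
        pos_ids = {pid for p in pos_pairs for pid in p}
        seqs = {r.id: r.sequence for r in small_proteome}
        for a, b in negatives:
            assert (a, b) not in pos_pairs
            assert a < b
            for endpoint in (a, b):
                assert endpoint not in pos_ids
                for pid in pos_ids:
                    assert hval(seqs[endpoint], seqs[pid]) < 20.0

    def test_same_seed_reproduces_same_set(self, small_proteome):
        positives = self._positives(4)
        config = SamplingConfig(negative_ratio=2, seed=7)
        assert sample_negatives(positives, small_proteome, config) == sample_negatives(
            positives, small_proteome, config
        )

    def test_exhausted_pool_is_an_error(self, small_proteome):
        # near-copies of positive proteins everywhere: the HVAL constraint
        # empties the eligible pool
        positives = self._positives(2)
        clones = [
            ProteinRecord(f"c{i}", rec.sequence)
            for i, rec in enumerate(small_proteome[:4])
        ]
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negatives(positives, small_proteome[:4] + clones, SamplingConfig(seed=1))
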