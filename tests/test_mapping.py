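import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

import homospec as hs
from homospec.mapping import (
    BLOSUM62,
    _encode,
    mutation_positions,
    query_to_subject_map,
)
from homospec._kernels import sw_score
from homospec.model import AlignmentResult, ProteomeDB, ProteinRecord

from conftest import naive_global_local

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def random_seq(rng, lo, hi):
    return "".join(rng.choice(AAS, int(rng.integers(lo, hi))))


def aln(q, s, start=None, end=None, **kw):
    degapped = s.replace("-", "")
    return AlignmentResult(
        "q", "s", q, s,
        subject_start=start or 1,
        subject_end=end or len(degapped),
        score=0.0, **kw,
    )


class TestLocalSearch:
    def test_exact_match_is_highly_significant(self, small_proteome):
        query = small_proteome.records[0].sequence
        hit = hs.local_search(query, small_proteome)
        assert hit is not None
        assert hit[0] == small_proteome.records[0].protein_id
        assert hit[1] < 1e-10
        # direct Karlin-Altschul formula on the exact self-match score
        self_score = sum(BLOSUM62[i, i] for i in _encode(query))
        assert hit[1] == pytest.approx(
            hs.evalue(self_score, len(query), small_proteome.total_residues)
        )

    def test_short_query_against_unrelated_db_is_rejected(self):
        rng = np.random.default_rng(17)
        db = ProteomeDB(
            [ProteinRecord(f"R{i}", random_seq(rng, 100, 150)) for i in range(10)]
        )
        assert hs.local_search("".join(rng.choice(AAS, 8)), db, 0.01) is None

    def test_tie_break_lexicographic(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        db = ProteomeDB([ProteinRecord("B", seq), ProteinRecord("A", seq)])
        assert hs.local_search(seq, db)[0] == "A"

    def test_empty_inputs_rejected(self, small_proteome):
        with pytest.raises(ValueError):
            hs.local_search("", small_proteome)
        with pytest.raises(ValueError):
            hs.local_search("ACDEF", ProteomeDB([]))

    def test_evalue_monotone_in_score(self):
        es = [hs.evalue(s, 100, 10_000) for s in range(10, 100, 5)]
        assert es == sorted(es, reverse=True)

    def test_sw_kernel_matches_biopython_local(self):
        """Cross-check the Smith-Waterman kernel against Biopython's local
        aligner with equivalent affine costs (open+L*extend here equals
        first-gap open+extend there)."""
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = random_seq(rng, 15, 50)
            b = random_seq(rng, 20, 80)
            ours = sw_score(_encode(a), _encode(b), BLOSUM62, 11.0, 1.0)
            assert ours == pytest.approx(aligner.score(a, b))


class TestGlobalLocalAlign:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFS"
        a = hs.global_local_align(seq, seq)
        assert a.identity_pct == 100.0
        assert a.mutation_count == 0
        assert (a.subject_start, a.subject_end) == (1, len(seq))

    def test_single_substitution(self):
        seq = "MKTAYIAKQRQISFVKSHFS"
        mutated = seq[:9] + "W" + seq[10:]
        a = hs.global_local_align(mutated, seq)
        assert a.mutation_count == 1
        assert a.identity_pct == pytest.approx(95.0)
        assert a.mutation_positions == [10]

    def test_single_deletion(self):
        seq = "MKTAYIAKQRQISFVKSHFS"
        a = hs.global_local_align(seq[:9] + seq[10:], seq)
        assert a.mutation_count == 1

    def test_subject_overhangs_are_free(self):
        subject = "AAAAAMKTAYIAKQRQISFVKAAAAA"
        a = hs.global_local_align("MKTAYIAKQRQISFVK", subject)
        assert a.subject_segment == "MKTAYIAKQRQISFVK"
        assert (a.subject_start, a.subject_end) == (6, 21)

    def test_degapped_subject_slice_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            q = random_seq(rng, 8, 30)
            s = random_seq(rng, 10, 50)
            a = hs.global_local_align(q, s)
            assert a.subject_segment == s[a.subject_start - 1 : a.subject_end]
            assert a.query_segment == q

    def test_score_matches_biopython_semiglobal(self):
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -14.0
        aligner.extend_gap_score = -4.0
        # free end gaps in the target row = unpenalized subject overhangs
        aligner.end_insertion_score = 0.0
        rng = np.random.default_rng(9)
        for _ in range(30):
            q = random_seq(rng, 8, 30)
            s = random_seq(rng, 10, 60)
            ours = hs.global_local_align(q, s).score
            assert ours == pytest.approx(aligner.score(q, s))

    def test_agrees_with_substring_enumeration_oracle(self):
        """Brute force: globally align the query against every subject
        substring with a memoized affine recursion; best score must match."""
        rng = np.random.default_rng(13)
        for _ in range(150):
            q = random_seq(rng, 2, 9)
            s = random_seq(rng, 2, 9)
            assert hs.global_local_align(q, s).score == pytest.approx(
                naive_global_local(q, s)
            )

    def test_mapping_onto_own_protein_is_perfect(self, small_proteome):
        for rec in small_proteome:
            seg = rec.sequence[5:40]
            a = hs.global_local_align(seg, rec.sequence)
            assert a.identity_pct == 100.0
            assert a.mutation_count == 0


class TestAlignmentMetrics:
    def test_count_mutations_examples(self):
        assert hs.count_mutations(aln("ACFD", "ACFD")) == 0
        assert hs.count_mutations(aln("AC-D", "ACED")) == 1
        assert hs.count_mutations(aln("ACFD", "ACED", end=4)) == 1

    def test_sequence_identity_examples(self):
        assert hs.sequence_identity(aln("ACDEFGHIKL", "ACDEFGHIKL")) == 100.0
        assert hs.sequence_identity(aln("ACDEFGHIKW", "ACDEFGHIKL", end=10)) == 90.0
        assert hs.sequence_identity(aln("AC", "CA", end=2)) == 0.0

    def test_gap_positions_map_to_left_flank(self):
        # subject gap (query insertion) reports the flanking subject position
        a = aln("ACXDE", "AC-DE", start=4, end=7)
        assert mutation_positions(a) == [5]
        m = query_to_subject_map(a)
        assert m[2] == 5 and m[3] == 5 and m[4] == 6

    def test_planted_mutation_count_recovery(self):
        """count_mutations recovers the planted count for k <= 4 in a
        large majority of random proteins."""
        ok = 0
        rng = np.random.default_rng(41)
        for i in range(200):
            k = int(rng.integers(0, 5))
            ref = hs.generate_reference_proteome(1, (80, 160), seed=50_000 + i)
            hom, _ = hs.mutate_proteome(ref, k, 0.2, seed=60_000 + i)
            a = hs.global_local_align(ref.records[0].sequence, hom.records[0].sequence)
            ok += a.mutation_count == k
        assert ok >= 190
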