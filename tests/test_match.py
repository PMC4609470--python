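import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estpoly.match import (
    KarlinAltschul,
    MatchFilter,
    Scoring,
    bit_score,
    evalue,
    hsp_from_rows,
    local_align,
    match_sets,
    min_raw_score,
)
from estpoly.seqio import SequenceRecord, revcomp
from tests.conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=1, max_size=15)


def sw_affine_oracle(a: str, b: str, match=1, mismatch=-2, gap_open=5, gap_extend=2):
    """Exhaustive affine-gap local DP; a gap of length L costs open + extend*L."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def plus_strand_best(query: str, subject: str) -> float:
    hsps = local_align(
        SequenceRecord("q", query),
        SequenceRecord("s", subject),
        min_raw=1,
        min_segment=1,
    )
    plus = [h.raw_score for h in hsps if h.strand == "+"]
    return max(plus) if plus else 0.0


class TestLocalAlign:
    def test_self_alignment_full_identity(self, rng):
        seq = random_seq(rng, 100)
        hsps = local_align(SequenceRecord("q", seq), SequenceRecord("s", seq))
        top = hsps[0]
        assert top.identity == 1.0
        assert top.strand == "+"
        assert (top.q_start, top.q_end) == (0, 100)
        assert (top.s_start, top.s_end) == (0, 100)

    def test_reverse_complement_hit_on_minus_strand(self, rng):
        seq = random_seq(rng, 60)
        hsps = local_align(SequenceRecord("q", seq), SequenceRecord("s", revcomp(seq)))
        top = hsps[0]
        assert top.strand == "-" and top.identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align(SequenceRecord("q", ""), SequenceRecord("s", "ACGT"))

    def test_large_gap_splits_into_two_hsps(self, rng):
        anc = random_seq(rng, 600)
        query = anc[:300] + random_seq(rng, 100) + anc[300:]
        hsps = [
            h
            for h in local_align(SequenceRecord("q", query), SequenceRecord("s", anc))
            if h.strand == "+" and h.n_columns >= 33
        ]
        assert len(hsps) == 2

    @given(dna, dna)
    @settings(max_examples=200, deadline=None)
    def test_score_matches_exhaustive_dp(self, a, b):
        assert plus_strand_best(a, b) == sw_affine_oracle(a, b)


class TestEvalue:
    def test_unit_evalue_identity(self):
        m, n = 500, 2000
        bit = math.log2(m * n)
        assert evalue(bit, m, n) == pytest.approx(1.0)

    def test_linear_in_database_length(self):
        assert evalue(30.0, 100, 2000) == pytest.approx(2 * evalue(30.0, 100, 1000))

    def test_bit_score_hand_computation(self):
        ka = KarlinAltschul(lam=1.33, k=0.621)
        raw = 50
        expected = (1.33 * 50 - math.log(0.621)) / math.log(2)
        assert bit_score(raw, ka) == pytest.approx(expected)

    def test_min_raw_score_inverts_evalue(self):
        ka = KarlinAltschul()
        m, n = 850, 400_000
        s = min_raw_score(1e-10, m, n, ka)
        assert evalue(bit_score(s, ka), m, n) == pytest.approx(1e-10, rel=1e-6)


class TestMatchSets:
    def test_self_match_full_coverage(self, rng):
        A = [SequenceRecord(f"u{i}", random_seq(rng, 200)) for i in range(4)]
        pairs, summary = match_sets(A, A)
        assert summary["matched_unigene_count"] == 4
        assert summary["coverage_pct"] == pytest.approx(100.0)
        for p in pairs:
            assert p.query_id == p.subject_id
            assert all(h.identity == 1.0 for h in p.hsps)

    def test_tied_subjects_resolved_lexicographically(self, rng):
        seq = random_seq(rng, 150)
        query = [SequenceRecord("q", seq)]
        subjects = [SequenceRecord("s_b", seq), SequenceRecord("s_a", seq)]
        pairs, _ = match_sets(query, subjects)
        assert pairs[0].subject_id == "s_a"

    def test_lower_identity_cutoff_is_monotone(self, rng):
        anc = [random_seq(rng, 300) for _ in range(5)]
        # diverge each subject by increasing numbers of substitutions
        def mutate(seq, k):
            s = list(seq)
            for pos in range(0, 3 * k, 3):
                s[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[pos]]
            return "".join(s)

        A = [SequenceRecord(f"q{i}", a) for i, a in enumerate(anc)]
        B = [SequenceRecord(f"s{i}", mutate(a, 2 * i)) for i, a in enumerate(anc)]
        counts = []
        for ident in (0.999, 0.99, 0.97, 0.9):
            _, summary = match_sets(A, B, MatchFilter(min_identity=ident))
            counts.append(summary["matched_unigene_count"])
        assert counts == sorted(counts)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            match_sets([], [SequenceRecord("s", "ACGT")])


class TestHSPFromRows:
    def test_row_invariants(self):
        hsp = hsp_from_rows("q", "s", "ACG-TA", "ACGCTG")
        assert hsp.n_columns == 6
        assert hsp.n_matches == 4
        assert hsp.identity == pytest.approx(4 / 6)
        assert hsp.q_end - hsp.q_start == 5  # non-gap query columns
        assert hsp.s_end - hsp.s_start == 6

    def test_raw_score_affine_gap_cost(self):
        # 4 matches, one mismatch (-2), one 1-nt gap (5 + 2)
        hsp = hsp_from_rows("q", "s", "ACG-TA", "ACGCTG")
        assert hsp.raw_score == 4 * 1 - 2 - 7
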