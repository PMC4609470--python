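import numpy as np
import pytest

from estpoly.match import hsp_from_rows, match_sets, MatchedPair
from estpoly.seqio import SequenceRecord
from estpoly.synth import SynthParams, simulate_pair
from estpoly.variants import (
    call_small_indels,
    call_snps,
    call_variants,
    detect_large_indels,
    variant_table,
)
from tests.conftest import pair_from_rows, random_seq


class TestCallSnps:
    def test_direction_is_subject_to_query(self):
        # subject G aligned to query A: the substitution reads G -> A
        pair = pair_from_rows("ACGTA", "ACGTG")
        (snp,) = call_snps(pair)
        assert snp.subject_base == "G" and snp.query_base == "A"
        assert snp.pattern == "G->A"
        assert snp.cls == "transition"
        assert snp.s_pos == 4

    def test_identical_sequences_yield_nothing(self, rng):
        seq = random_seq(rng, 80)
        pair = pair_from_rows(seq, seq)
        assert call_snps(pair) == []

    def test_planted_mismatch_classes(self, rng):
        base = list(random_seq(rng, 100))
        query = base.copy()
        query[10], base[10] = "T", "C"  # C->T transition
        query[50], base[50] = "T", "A"  # A->T transversion
        query[90], base[90] = "C", "G"  # G->C transversion
        pair = pair_from_rows("".join(query), "".join(base))
        snps = call_snps(pair)
        assert len(snps) == 3
        assert sorted(s.cls for s in snps) == [
            "transition", "transversion", "transversion",
        ]

    def test_n_columns_skipped(self):
        pair = pair_from_rows("ANGTA", "ACGTA")
        assert call_snps(pair) == []


class TestCallSmallIndels:
    def test_gap_run_is_one_insertion(self):
        pair = pair_from_rows("ACTTAGT", "AC---GT")
        (indel,) = call_small_indels(pair)
        assert indel.kind == "insertion"
        assert indel.length == 3 and indel.seq == "TTA"
        assert indel.s_pos == 2

    def test_separate_runs_are_separate_events(self):
        pair = pair_from_rows("ACTAGTT", "AC-AG-T")
        indels = call_small_indels(pair)
        assert [(i.kind, i.length) for i in indels] == [
            ("insertion", 1), ("insertion", 1),
        ]

    def test_deletion_reads_subject_segment(self):
        pair = pair_from_rows("AC--GTA", "ACTTGTA")
        (indel,) = call_small_indels(pair)
        assert indel.kind == "deletion" and indel.seq == "TT"

    def test_flanks_come_from_continuous_sequence(self, rng):
        left, right = random_seq(rng, 20), random_seq(rng, 20)
        q_row = left + "TTA" + right
        s_row = left + "---" + right
        pair = pair_from_rows(q_row, s_row)
        (indel,) = call_small_indels(pair)
        assert indel.flank5 == left[-10:]
        assert indel.flank3 == right[:10]

    def test_simulator_size_spectrum_recovered(self):
        p = SynthParams(
            n_unigenes=40, seed=3, sub_rate=0.0, large_indel_rate=0.0,
            repeat_fraction=0.0,
        )
        sim = simulate_pair(p)
        pairs, _ = match_sets(sim.library_a, sim.library_b)
        _, small, _ = call_variants(pairs)
        planted = sim.truth.variants
        planted_hist = planted.groupby("length").size().to_dict()
        called_hist = {}
        for v in small:
            called_hist[v.length] = called_hist.get(v.length, 0) + 1
        assert called_hist == planted_hist


class TestDetectLargeIndels:
    def _two_hsp_pair(self, gq, gs, rng):
        """Pair with a junction of query gap gq and subject gap gs."""
        qlen, slen = 300 + gq + 300, 300 + gs + 300
        q = random_seq(rng, qlen)
        s = q[:300] + random_seq(rng, gs) + q[300 + gq :]
        h1 = hsp_from_rows("q", "s", q[:300], q[:300], q_start=0, s_start=0, s_len=slen)
        h2 = hsp_from_rows(
            "q", "s", q[300 + gq :], q[300 + gq :],
            q_start=300 + gq, s_start=300 + gs, s_len=slen,
        )
        return MatchedPair("q", "s", [h1, h2], h1.n_columns + h2.n_columns,
                           "+", q, s)

    def test_query_jump_is_insertion(self, rng):
        pair = self._two_hsp_pair(100, 0, rng)
        (indel,) = detect_large_indels(pair)
        assert indel.kind == "insertion"
        assert indel.length == 100 and indel.size_class == "large"

    def test_subject_jump_is_deletion(self, rng):
        pair = self._two_hsp_pair(0, 80, rng)
        (indel,) = detect_large_indels(pair)
        assert indel.kind == "deletion" and indel.length == 80

    def test_below_threshold_not_emitted(self, rng):
        pair = self._two_hsp_pair(15, 12, rng)
        assert detect_large_indels(pair) == []

    def test_planted_474nt_insertion_recovered(self, rng):
        anc = random_seq(rng, 850)
        query = anc[:400] + random_seq(rng, 474) + anc[400:]
        pairs, _ = match_sets(
            [SequenceRecord("q", query)], [SequenceRecord("s", anc)]
        )
        _, _, large = call_variants(pairs)
        assert [(v.kind, v.length) for v in large] == [("insertion", 474)]


class TestInvariants:
    def test_direction_antisymmetry_on_simulated_pairs(self):
        p = SynthParams(n_unigenes=15, seed=8, large_indel_rate=0.0)
        sim = simulate_pair(p)
        fwd_pairs, _ = match_sets(sim.library_a, sim.library_b)
        rev_pairs, _ = match_sets(sim.library_b, sim.library_a)
        f_snps, f_small, _ = call_variants(fwd_pairs)
        r_snps, r_small, _ = call_variants(rev_pairs)
        fwd_patterns = sorted(s.pattern for s in f_snps)
        rev_flipped = sorted(f"{s.query_base}->{s.subject_base}" for s in r_snps)
        assert fwd_patterns == rev_flipped
        assert sum(v.kind == "insertion" for v in f_small) == sum(
            v.kind == "deletion" for v in r_small
        )

    def test_no_variants_from_identical_pair(self, rng):
        seq = random_seq(rng, 300)
        pairs, _ = match_sets([SequenceRecord("q", seq)], [SequenceRecord("s", seq)])
        snps, small, large = call_variants(pairs)
        assert snps == [] and small == [] and large == []

    def test_column_conservation_per_hsp(self):
        p = SynthParams(n_unigenes=10, seed=5)
        sim = simulate_pair(p)
        pairs, _ = match_sets(sim.library_a, sim.library_b)
        for pair in pairs:
            for h in pair.hsps:
                q_cols = sum(1 for c in h.q_row if c != "-")
                s_cols = sum(1 for c in h.s_row if c != "-")
                assert q_cols == h.q_end - h.q_start
                assert s_cols == h.s_end - h.s_start
                assert h.n_columns >= max(q_cols, s_cols)

    def test_variant_table_coordinates_one_based(self):
        pair = pair_from_rows("ACGTA", "ACGTG")
        snps = call_snps(pair)
        table = variant_table(snps, [])
        assert table.iloc[0].s_pos == 5
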