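import numpy as np
import pandas as pd
import pytest

from estpoly.match import MatchedPair
from estpoly.stats import (
    flank_profile,
    functional_bins,
    ratio_spectrum,
    summarize,
    summary_tables,
)
from estpoly.variants import IndelRecord, SNPRecord


def fake_pair(query_id="q", matched_columns=1000):
    return MatchedPair(query_id, "s", [], matched_columns, "+", "", "")


def snp(pattern="G->A", query_id="q"):
    s, q = pattern.split("->")
    cls = "transition" if {s, q} in ({"A", "G"}, {"C", "T"}) else "transversion"
    return SNPRecord(query_id, "s", 0, s, q, pattern, cls)


def indel(kind="insertion", length=1, size_class="small", query_id="q",
          flank5="", flank3=""):
    return IndelRecord(query_id, "s", kind, size_class, length, 0,
                       "A" * length, flank5, flank3)


class TestSummarize:
    def test_forced_arithmetic(self):
        pairs = [fake_pair(matched_columns=2000)]
        variants = (
            [snp("C->T")] * 6 + [snp("A->T")] * 4
            + [indel("insertion")] * 3 + [indel("deletion")]
        )
        s = summarize(pairs, variants)
        assert s.freq_per_kb["snp"] == pytest.approx(5.0)
        assert s.freq_per_kb["transition"] == pytest.approx(3.0)
        assert s.indel_freq_per_kb["indel"] == pytest.approx(2.0)

    def test_zero_variants_all_zero(self):
        s = summarize([fake_pair()], [])
        assert s.snp_total == 0
        assert all(v == 0 for v in s.freq_per_kb.values())
        assert all(v == 0 for v in s.indel_freq_per_kb.values())

    def test_zero_matched_length_is_error(self):
        with pytest.raises(ValueError):
            summarize([], [])

    def test_frequency_conservation(self):
        variants = [snp("C->T"), snp("G->A"), snp("A->T"), snp("C->G")]
        s = summarize([fake_pair()], variants)
        assert s.freq_per_kb["transition"] + s.freq_per_kb["transversion"] == (
            pytest.approx(s.freq_per_kb["snp"])
        )
        assert sum(s.per_pattern.values()) == s.snp_total

    def test_order_invariance(self, rng):
        variants = [snp("C->T"), snp("A->T"), indel("insertion", 2),
                    indel("deletion", 1)]
        pairs = [fake_pair("q1", 500), fake_pair("q2", 700)]
        s1 = summarize(pairs, variants)
        order = rng.permutation(len(variants))
        s2 = summarize(pairs[::-1], [variants[i] for i in order])
        assert s1.freq_per_kb == s2.freq_per_kb
        assert s1.per_length_indels == s2.per_length_indels

    def test_large_indels_excluded_from_per_kb(self):
        variants = [indel("insertion", 100, size_class="large")]
        s = summarize([fake_pair()], variants)
        assert s.indel_freq_per_kb["indel"] == 0


class TestRatioSpectrum:
    def test_perfect_negative_linearity(self):
        variants = []
        for L, n_ins in ((1, 4), (2, 3), (3, 2), (4, 1)):
            variants += [indel("insertion", L)] * n_ins + [indel("deletion", L)]
        small, _ = ratio_spectrum(variants)
        assert small.pearson_r2 == pytest.approx(1.0)
        assert small.direction == -1

    def test_constant_ratio_flagged_degenerate(self):
        variants = []
        for L in (1, 2, 3, 4):
            variants += [indel("insertion", L)] * 2 + [indel("deletion", L)] * 2
        small, _ = ratio_spectrum(variants)
        assert small.degenerate is True
        assert small.pearson_r2 == 0.0

    def test_too_few_defined_bins_undefined(self):
        variants = [indel("insertion", 1), indel("deletion", 1)]
        small, _ = ratio_spectrum(variants)
        assert small.pearson_r2 is None

    def test_zero_deletion_bins_excluded(self):
        variants = [indel("insertion", 1)] * 5  # no deletions: ratio undefined
        small, _ = ratio_spectrum(variants)
        assert all(r is None for (_, _, _, _, r) in small.bins)

    def test_large_bins_use_observed_lengths(self):
        variants = [
            indel("insertion", 30, "large"), indel("deletion", 40, "large"),
            indel("insertion", 100, "large"), indel("deletion", 150, "large"),
            indel("insertion", 300, "large"), indel("deletion", 500, "large"),
        ]
        _, large = ratio_spectrum(variants)
        reps = [rep for (_, rep, ni, nd, _) in large.bins]
        assert reps == [35.0, 125.0, 400.0]


class TestFlankProfile:
    def test_all_gc_flanks(self):
        variants = [indel(flank5="G" * 10, flank3="C" * 10) for _ in range(3)]
        prof = flank_profile(variants)
        assert all(v["all"] == 1.0 for v in prof.positions.values())

    def test_positional_read_off(self):
        v = indel(flank5="", flank3="GATTACAGAT")
        prof = flank_profile([v])
        assert prof.positions[1]["insertion"] == 1.0  # G
        assert prof.positions[2]["insertion"] == 0.0  # A
        assert np.isnan(prof.positions[-1]["insertion"])  # truncated 5' flank

    def test_weighted_combination(self):
        vs = [
            indel("insertion", flank5="G" * 10, flank3="G" * 10),
            indel("deletion", flank5="A" * 10, flank3="A" * 10),
        ]
        prof = flank_profile(vs)
        assert prof.positions[1]["all"] == pytest.approx(0.5)
        assert prof.means["insertion"] == 1.0
        assert prof.means["deletion"] == 0.0


class TestFunctionalBins:
    def _data(self):
        pairs = [fake_pair("q1", 1000), fake_pair("q2", 1000)]
        variants = [snp(query_id="q1")] * 4 + [snp(query_id="q2")] * 2 + [
            indel(query_id="q2")
        ]
        return pairs, variants

    def test_single_category_equals_global(self):
        pairs, variants = self._data()
        cmap = {"q1": ["all"], "q2": ["all"]}
        table = functional_bins(variants, pairs, cmap)
        s = summarize(pairs, variants)
        row = table.iloc[0]
        assert row.snp_per_kb == pytest.approx(s.freq_per_kb["snp"])
        assert row.n_unigenes == 2

    def test_empty_category_flagged_not_error(self):
        pairs, variants = self._data()
        table = functional_bins(variants, pairs, {"zzz": ["ghost"]})
        row = table.iloc[0]
        assert bool(row.zero_matched) is True and row.n_snps == 0

    def test_disjoint_categories_conserve_counts(self):
        pairs, variants = self._data()
        cmap = {"q1": ["one"], "q2": ["two"]}
        table = functional_bins(variants, pairs, cmap).set_index("category")
        s = summarize(pairs, variants)
        assert table.n_snps.sum() == s.snp_total
        # count-weighted frequency combination reproduces the global rate
        weights = np.array([1000, 1000])
        combined = (table.snp_per_kb.values * weights).sum() / weights.sum()
        assert combined == pytest.approx(s.freq_per_kb["snp"])

    def test_dataframe_category_map_accepted(self):
        pairs, variants = self._data()
        df = pd.DataFrame({"unigene_id": ["q1", "q2"], "category": ["x", "x"]})
        table = functional_bins(variants, pairs, df)
        assert list(table.category) == ["x"]


def test_summary_tables_layout():
    s = summarize([fake_pair()], [snp("C->T"), indel("insertion", 1)])
    tables = summary_tables(s)
    assert len(tables["snp_patterns"]) == 12
    assert list(tables["small_indel_lengths"].length) == list(range(1, 11))
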