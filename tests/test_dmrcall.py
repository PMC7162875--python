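import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from rrbskit import bscore, dmrcall, reference, synthio
from rrbskit.dmrcall import DMRParams, fisher_exact_two_sided

from conftest import cpg_run, make_table

counts_st = st.integers(min_value=0, max_value=40)


class TestFisherExact:
    def test_extreme_table(self):
        # margins 10/10: only the two extreme tables are as improbable,
        # each with probability 1/C(20,10) = 1/184756
        assert fisher_exact_two_sided(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)

    def test_most_probable_table(self):
        assert fisher_exact_two_sided(1, 1, 1, 1) == 1.0

    def test_all_zero_table_convention(self):
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 0, 0, 0)

    @given(counts_st, counts_st, counts_st, counts_st)
    @settings(max_examples=300, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        p = fisher_exact_two_sided(a, b, c, d)
        assert p == pytest.approx(reference.fisher_two_sided_enumeration(a, b, c, d), abs=1e-10)
        assert 0 < p <= 1

    @given(counts_st, counts_st, counts_st, counts_st)
    @settings(max_examples=100, derandomize=True)
    def test_matches_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        expected = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(expected, rel=1e-6)

    def test_large_counts_stable(self):
        p = fisher_exact_two_sided(4000, 1000, 1000, 4000)
        assert 0 < p < 1e-100  # log-space computation does not underflow to 0


class TestScanWindows:
    def test_sliding_window_count(self):
        m1 = cpg_run("a", [(8, 2)] * 7)
        m2 = cpg_run("b", [(2, 8)] * 7)
        ws = dmrcall.scan_windows(m1, m2, min_sites=5, min_cov=5)
        assert len(ws) == 3  # n - w + 1
        assert [(w.first, w.last) for w in ws] == [(0, 4), (1, 5), (2, 6)]
        assert ws[0].start == 100 and ws[0].end == 181
        assert (ws[0].mc1, ws[0].uc1, ws[0].mc2, ws[0].uc2) == (40, 10, 10, 40)

    def test_below_minimum_sites(self):
        m1 = cpg_run("a", [(8, 2)] * 4)
        m2 = cpg_run("b", [(2, 8)] * 4)
        assert dmrcall.scan_windows(m1, m2) == []

    def test_site_covered_in_one_sample_excluded(self):
        m1 = cpg_run("a", [(8, 2)] * 6)
        counts2 = [(2, 8)] * 6
        counts2[2] = (2, 2)  # below min_cov=5 in sample 2
        m2 = cpg_run("b", counts2)
        ws = dmrcall.scan_windows(m1, m2, min_sites=5, min_cov=5)
        assert len(ws) == 1  # only 5 qualifying sites remain
        assert (ws[0].start, ws[0].end) == (100, 201)
        assert (ws[0].mc2, ws[0].uc2) == (10, 40)  # site at 140 not pooled

    def test_context_filter(self):
        m1 = make_table("a", [("chr1", i * 10, "+", "CHH", 8, 2) for i in range(6)])
        m2 = make_table("b", [("chr1", i * 10, "+", "CHH", 2, 8) for i in range(6)])
        assert dmrcall.scan_windows(m1, m2, context="CpG") == []
        assert len(dmrcall.scan_windows(m1, m2, context="CHH")) == 2


class TestTestWindow:
    def _window(self, mc1, uc1, mc2, uc2):
        return dmrcall.CandidateWindow("chr1", 0, 100, "CpG", 0, 4, mc1, uc1, mc2, uc2)

    def test_fold_change_ratio(self):
        t = dmrcall.test_window(self._window(60, 40, 25, 75))
        assert t.fold == pytest.approx(0.60 / 0.25)
        assert t.l1 == 0.6 and t.l2 == 0.25

    def test_hypomethylation_rule(self):
        t = dmrcall.test_window(self._window(15, 85, 5, 95), hypo_threshold=0.2)
        assert t.fold == pytest.approx(3.0)
        assert not t.passed  # max level 0.15 < 0.2: both hypomethylated

    def test_neither_rule_stricter(self):
        w = self._window(80, 20, 25, 75)
        assert dmrcall.test_window(w, hypo_rule="not_both").passed
        assert not dmrcall.test_window(w, hypo_rule="neither", hypo_threshold=0.3).passed

    def test_passing_window(self):
        t = dmrcall.test_window(self._window(30, 10, 10, 30))
        assert t.passed
        assert t.fold == pytest.approx(3.0)
        assert t.p == pytest.approx(
            reference.fisher_two_sided_enumeration(30, 10, 10, 30), abs=1e-12
        )
        assert t.p < 0.05

    def test_zero_level_gives_infinite_fold(self):
        t = dmrcall.test_window(self._window(0, 50, 30, 20))
        assert t.fold == math.inf
        assert t.passed


def _dmr_keys(result):
    return sorted((d.chrom, d.start, d.end, d.n_sites) for d in result.dmrs)


class TestMergeAndCall:
    def test_identical_samples_give_no_dmrs(self):
        m = cpg_run("a", [(8, 2)] * 20)
        res = dmrcall.call_dmrs(m, m)
        assert res.dmrs == [] and res.n_windows == 16

    def test_single_strong_region(self):
        m1 = cpg_run("a", [(8, 2)] * 5)
        m2 = cpg_run("b", [(2, 8)] * 5)
        res = dmrcall.call_dmrs(m1, m2)
        assert len(res.dmrs) == 1
        d = res.dmrs[0]
        assert (d.start, d.end, d.n_sites) == (100, 181, 5)
        assert d.fold >= 2 and d.p < 0.05

    # Merge-test geometry: a moderate block A (7,3 vs 3,7; fold 7/3 per
    # site), two neutral sites N (5,5 in both samples) and a strong block
    # B (8,2 vs 2,8).  Windows bridging A into N fail the 2-fold rule, so
    # A and the N+B stretch collapse into two separate putative regions;
    # whether they merge is then decided by the spanning-region test.

    A = [(7, 3)] * 5
    N = [(5, 5)] * 2
    B = [(8, 2)] * 5

    @staticmethod
    def _two_sample_rows(blocks, positions):
        rows1, rows2 = [], []
        sites = [cnt for block, _ in blocks for cnt in block]
        pos = [p for _, ps in blocks for p in ps]
        for (mc, uc), p in zip(sites, pos):
            rows1.append(("chr1", p, "+", "CpG", mc, uc))
            rows2.append(("chr1", p, "+", "CpG", uc, mc))
        return rows1, rows2

    def test_nearby_regions_merge_when_span_passes(self):
        blocks = [
            (self.A, [100 + 20 * i for i in range(5)]),
            (self.N, [250, 270]),
            (self.B, [400 + 20 * i for i in range(5)]),
        ]
        rows1, rows2 = self._two_sample_rows(blocks, None)
        res = dmrcall.call_dmrs(make_table("a", rows1), make_table("b", rows2))
        assert len(res.dmrs) == 1
        d = res.dmrs[0]
        assert (d.start, d.end, d.n_sites) == (100, 481, 12)
        assert d.fold >= 2 and d.p < 0.05
        assert len(d.merged_from) >= 2  # provenance spans both regions

    def test_opposite_direction_regions_stay_independent(self):
        # both blocks pass individually but in opposite directions; every
        # bridging window and the pooled span fail the 2-fold rule
        rows1 = [("chr1", 100 + i * 20, "+", "CpG", 16, 4) for i in range(5)]
        rows1 += [("chr1", 300 + i * 20, "+", "CpG", 7, 13) for i in range(5)]
        rows2 = [("chr1", 100 + i * 20, "+", "CpG", 7, 13) for i in range(5)]
        rows2 += [("chr1", 300 + i * 20, "+", "CpG", 16, 4) for i in range(5)]
        res = dmrcall.call_dmrs(make_table("a", rows1), make_table("b", rows2))
        assert _dmr_keys(res) == [("chr1", 100, 181, 5), ("chr1", 300, 381, 5)]

    def test_gap_beyond_max_gap_prevents_merge(self):
        blocks = [
            (self.A, [100 + 20 * i for i in range(5)]),
            (self.N, [1000, 1010]),
            (self.B, [2100 + 20 * i for i in range(5)]),
        ]
        rows1, rows2 = self._two_sample_rows(blocks, None)
        m1, m2 = make_table("a", rows1), make_table("b", rows2)
        far = dmrcall.call_dmrs(m1, m2, max_gap=500)
        assert len(far.dmrs) == 2  # putative regions 819 bp apart
        near = dmrcall.call_dmrs(m1, m2, max_gap=1000)
        assert len(near.dmrs) == 1  # same data, merge allowed across the gap

    def test_final_dmrs_satisfy_criteria_and_independence(self, genome, dmr_spec):
        p1 = synthio.assign_profile(genome, "medium", dmr_spec=dmr_spec, seed=51)
        p2 = synthio.assign_profile(genome, "pVC", dmr_spec=dmr_spec, seed=52)
        m1 = bscore.methylome_from_profile(p1, genome, 25, seed=61)
        m2 = bscore.methylome_from_profile(p2, genome, 25, seed=62)
        res = dmrcall.call_dmrs(m1, m2)
        assert res.dmrs
        params = res.params
        for d in res.dmrs:
            assert d.fold >= params.fold_min
            assert d.p < params.p_max
            assert max(d.l1, d.l2) >= params.hypo_threshold
            assert d.merged_from
        sas = {sa.chrom: sa for sa in dmrcall._qualifying_sites(
            m1, m2, params.context, params.min_cov)}
        # adjacent pairs within max_gap must fail when pooled (independence)
        for a, b in zip(res.dmrs, res.dmrs[1:]):
            if a.chrom != b.chrom or b.start - a.end > params.max_gap:
                continue
            sa = sas[a.chrom]
            first = int(np.searchsorted(sa.pos, a.start))
            last = int(np.searchsorted(sa.pos, b.end - 1))
            span = dmrcall._window_from_span(sa, params.context, first, last)
            assert not dmrcall.test_window(
                span, params.fold_min, params.p_max, params.hypo_threshold
            ).passed

    def test_recovers_implanted_regions(self, genome, dmr_spec):
        p1 = synthio.assign_profile(genome, "medium", dmr_spec=dmr_spec, seed=71)
        p2 = synthio.assign_profile(genome, "pVC", dmr_spec=dmr_spec, seed=72)
        m1 = bscore.methylome_from_profile(p1, genome, 25, seed=81)
        m2 = bscore.methylome_from_profile(p2, genome, 25, seed=82)
        res = dmrcall.call_dmrs(m1, m2)
        truth = [(f.start, f.end) for f in genome.features_of("truth_dmr")]
        for s, e in truth:
            assert any(d.start < e and s < d.end for d in res.dmrs)
        for d in res.dmrs:
            assert any(s - 500 <= d.start and d.end <= e + 500 for s, e in truth)

    @pytest.mark.parametrize("seed", [101, 202])
    def test_matches_bruteforce_oracle(self, seed):
        g = synthio.generate_genome(
            1, 30_000, 0.5, 3, 8, seed=seed, n_truth_dmrs=4
        )
        spec = [(f.id, {"medium": 0.9, "pVC": 0.1}) for f in g.features_of("truth_dmr")]
        p1 = synthio.assign_profile(g, "medium", dmr_spec=spec, seed=seed + 1)
        p2 = synthio.assign_profile(g, "pVC", dmr_spec=spec, seed=seed + 2)
        m1 = bscore.methylome_from_profile(p1, g, 25, seed=seed + 3)
        m2 = bscore.methylome_from_profile(p2, g, 25, seed=seed + 4)
        res = dmrcall.call_dmrs(m1, m2)
        oracle = reference.dmrs_bruteforce(m1, m2)
        assert _dmr_keys(res) == sorted(oracle)

    def test_empty_overlap_returns_empty_with_warning(self, caplog):
        m1 = cpg_run("a", [(8, 2)] * 6, chrom="chr1")
        m2 = cpg_run("b", [(2, 8)] * 6, chrom="chr2")
        with caplog.at_level("WARNING"):
            res = dmrcall.call_dmrs(m1, m2)
        assert res.dmrs == [] and res.n_qualifying_sites == 0

    def test_bed_and_tsv_export(self, tmp_path):
        m1 = cpg_run("a", [(8, 2)] * 5)
        m2 = cpg_run("b", [(2, 8)] * 5)
        res = dmrcall.call_dmrs(m1, m2)
        res.to_bed(tmp_path / "d.bed")
        res.to_tsv(tmp_path / "d.tsv")
        bed = (tmp_path / "d.bed").read_text().splitlines()
        assert len(bed) == 1
        chrom, start, end, name, score, strand = bed[0].split("\t")
        assert 0 < float(score) <= 100
        df = res.to_frame()
        assert list(df.n_sites) == [5]
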