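import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrbskit import synthio
from rrbskit.synthio import Fragment, ReferenceGenome


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        g1 = synthio.generate_genome(1, 10_000, 0.5, 3, 5, seed=1)
        g2 = synthio.generate_genome(1, 10_000, 0.5, 3, 5, seed=1)
        assert g1.chromosomes == g2.chromosomes
        assert g1.features == g2.features

    def test_seed_changes_sequence(self):
        g1 = synthio.generate_genome(1, 10_000, 0.5, 3, 5, seed=1)
        g2 = synthio.generate_genome(1, 10_000, 0.5, 3, 5, seed=2)
        assert g1.chromosomes != g2.chromosomes

    def test_ccgg_boost_adds_motifs(self):
        n = {
            boost: sum(
                len(re.findall("(?=CCGG)", s))
                for s in synthio.generate_genome(
                    1, 50_000, 0.5, boost, 5, seed=3
                ).chromosomes.values()
            )
            for boost in (1.0, 3.0)
        }
        assert n[3.0] > n[1.0]

    def test_motif_density_at_least_one_per_kb(self, genome):
        for seq in genome.chromosomes.values():
            assert len(re.findall("(?=CCGG)", seq)) >= len(seq) / 1000

    def test_annotation_structure(self, genome):
        genome.validate()
        genes = genome.features_of("gene")
        promoters = {f.id for f in genome.features_of("promoter")}
        assert all(f"prom_{g.id}" in promoters for g in genes)
        tsdr = genome.feature_by_id("tsdr")
        middle = genome.chromosomes[tsdr.chrom][tsdr.start : tsdr.end]
        assert len(re.findall("(?=CG)", middle)) >= 7

    def test_bad_arguments_raise(self):
        with pytest.raises(ValueError):
            synthio.generate_genome(0, 10_000, 0.5, 3, 5, seed=1)
        with pytest.raises(ValueError):
            synthio.generate_genome(1, 5_000, 0.5, 3, 5, seed=1)
        with pytest.raises(ValueError):
            synthio.generate_genome(1, 10_000, 1.5, 3, 5, seed=1)


class TestDigestion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AACCGGTTCCGGAA", [(0, 3), (3, 9), (9, 14)]),
            ("CCGGCCGG", [(0, 1), (1, 5), (5, 8)]),
            ("ATATATATAT", [(0, 10)]),  # no CCGG: single fragment
        ],
    )
    def test_cut_after_first_c(self, seq, expected):
        frags = synthio.digest_mspi(ReferenceGenome({"t": seq}))
        assert [(f.start, f.end) for f in frags] == expected

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    @settings(max_examples=200, derandomize=True)
    def test_fragments_partition_chromosome(self, seq):
        frags = synthio.digest_mspi(ReferenceGenome({"t": seq}))
        assert frags[0].start == 0 and frags[-1].end == len(seq)
        for a, b in zip(frags, frags[1:]):
            assert a.end == b.start
        assert sum(f.length for f in frags) == len(seq)

    def test_size_select_bounds_inclusive(self):
        frags = [Fragment("c", 0, n) for n in (39, 40, 220, 221)]
        kept = synthio.size_select(frags)
        assert [f.length for f in kept] == [40, 220]
        assert synthio.size_select([]) == []
        mid = [Fragment("c", 0, n) for n in (99, 100, 101)]
        assert [f.length for f in synthio.size_select(mid, 100, 100)] == [100]

    def test_size_select_idempotent(self, fragments):
        assert synthio.size_select(fragments) == fragments

    def test_size_select_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            synthio.size_select([], 100, 50)


class TestAssignProfile:
    def test_dmr_spec_levels_exact(self, genome):
        p = synthio.assign_profile(
            genome, "TGFb_pVC", base_cg_level=0.8,
            dmr_spec=[("tsdr", {"TGFb_pVC": 0.1})], seed=1,
        )
        tsdr = genome.feature_by_id("tsdr")
        sub = p.sites[
            (p.sites.chrom == tsdr.chrom)
            & (p.sites.pos >= tsdr.start) & (p.sites.pos < tsdr.end)
            & (p.sites.context == "CpG")
        ]
        assert len(sub) >= 7
        assert (sub.true_level == 0.1).all()

    def test_background_noncg_level(self, genome):
        p = synthio.assign_profile(genome, "medium", base_noncg_level=0.01, seed=2)
        chh = p.sites[p.sites.context == "CHH"]
        assert abs(chh.true_level.mean() - 0.01) < 0.03  # clipping inflates slightly

    def test_every_cytosine_has_one_record(self, genome, profile_medium):
        n_c = sum(s.count("C") + s.count("G") for s in genome.chromosomes.values())
        assert len(profile_medium.sites) == n_c
        keys = profile_medium.sites[["chrom", "pos", "strand"]]
        assert not keys.duplicated().any()
        lv = profile_medium.sites.true_level
        assert ((lv >= 0) & (lv <= 1)).all()

    def test_shared_spec_same_seed_identical_inside(self, genome):
        spec = [("tsdr", {"medium": 0.3, "pVC": 0.3})]
        p1 = synthio.assign_profile(genome, "medium", dmr_spec=spec, seed=9)
        p2 = synthio.assign_profile(genome, "pVC", dmr_spec=spec, seed=9)
        tsdr = genome.feature_by_id("tsdr")
        for p in (p1, p2):
            sub = p.sites[
                (p.sites.pos >= tsdr.start) & (p.sites.pos < tsdr.end)
                & (p.sites.context == "CpG")
            ]
            assert (sub.true_level == 0.3).all()

    def test_unknown_condition_and_feature_raise(self, genome):
        with pytest.raises(ValueError):
            synthio.assign_profile(genome, "mock", seed=1)
        with pytest.raises(KeyError):
            synthio.assign_profile(genome, "medium", dmr_spec=[("nope", {})], seed=1)


class TestSimulateReads:
    def test_fully_methylated_reads_match_reference(self, genome, fragments):
        prof = synthio.assign_profile(
            genome, "medium", base_cg_level=1.0, base_noncg_level=1.0,
            jitter_sd=0.0, seed=1,
        )
        rs = synthio.simulate_reads(
            fragments[:5], genome, prof, 50, 3, conversion_rate=1.0, error_rate=0.0, seed=2
        )
        for r in rs.reads:
            ref = genome.chromosomes[r.chrom][r.start : r.start + len(r.sequence)]
            expected = ref if r.library == "OT" else synthio.revcomp(ref)
            assert r.sequence == expected

    def test_unmethylated_cytosines_read_as_t(self, genome, fragments):
        prof = synthio.assign_profile(
            genome, "medium", base_cg_level=0.0, base_noncg_level=0.0,
            jitter_sd=0.0, seed=1,
        )
        rs = synthio.simulate_reads(
            fragments[:5], genome, prof, 50, 3, conversion_rate=1.0, error_rate=0.0, seed=2
        )
        for r in rs.reads:
            assert "C" not in r.sequence

    def test_incomplete_conversion_rate(self, genome):
        # all true levels 0; conversion 0.99 leaves ~1% of Cs unconverted
        prof = synthio.assign_profile(
            genome, "medium", base_cg_level=0.0, base_noncg_level=0.0,
            jitter_sd=0.0, seed=1,
        )
        frags = synthio.size_select(synthio.digest_mspi(genome))
        rs = synthio.simulate_reads(
            frags, genome, prof, 50, 6, conversion_rate=0.99, error_rate=0.0, seed=3
        )
        n_c = n_ct = 0
        for r in rs.reads:
            ref = genome.chromosomes[r.chrom][r.start : r.start + len(r.sequence)]
            oriented = ref if r.library == "OT" else synthio.revcomp(ref)
            for b_read, b_ref in zip(r.sequence, oriented):
                if b_ref == "C":
                    n_ct += 1
                    n_c += b_read == "C"
        assert n_ct > 10_000
        se = np.sqrt(0.01 * 0.99 / n_ct)
        assert abs(n_c / n_ct - 0.01) < 3 * se

    def test_fastq_byte_identical_per_seed(self, genome, fragments, profile_medium, tmp_path):
        args = (fragments[:10], genome, profile_medium, 50, 5, 0.995, 0.001)
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        synthio.simulate_reads(*args, seed=5).to_fastq(f1)
        synthio.simulate_reads(*args, seed=5).to_fastq(f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_invalid_rates_raise(self, genome, fragments, profile_medium):
        with pytest.raises(ValueError):
            synthio.simulate_reads(fragments, genome, profile_medium, 50, 5, 1.2, 0, seed=1)
        with pytest.raises(ValueError):
            synthio.simulate_reads(fragments, genome, profile_medium, 50, 5, 1.0, -0.1, seed=1)

    def test_fastq_round_trip(self, genome, fragments, profile_medium, tmp_path):
        rs = synthio.simulate_reads(
            fragments[:5], genome, profile_medium, 50, 3, 0.995, 0.001, seed=6
        )
        path = tmp_path / "r.fastq"
        rs.to_fastq(path)
        back = synthio.ReadSet.from_fastq(path)
        assert [(r.id, r.sequence, r.chrom, r.start, r.library) for r in back.reads] == [
            (r.id, r.sequence, r.chrom, r.start, r.library) for r in rs.reads
        ]


class TestSimulateAmplicon:
    def test_degenerate_levels(self):
        t0 = synthio.simulate_amplicon([0.0] * 7, 100, seed=1)
        assert (t0.percent == 0).all()
        t1 = synthio.simulate_amplicon([1.0] * 7, 100, seed=1)
        assert (t1.percent == 100).all()

    def test_binomial_sampling_accuracy(self):
        t = synthio.simulate_amplicon([0.5] * 7, 10_000, seed=2)
        assert (abs(t.percent - 50.0) < 1.5).all()  # 3 binomial SE = 1.5 points

    def test_length_check(self):
        with pytest.raises(ValueError):
            synthio.simulate_amplicon([0.5] * 6, 100, seed=1, tsdr_cpg_count=7)


class TestSuppressionAssay:
    def test_roles_and_standard_count(self):
        ev = synthio.simulate_suppression_assay(
            {"cd4": 0, "gd": 10}, n_standard_added=25, seed=1
        )
        assert (ev.role == "cd4").sum() == 0
        assert (ev.role == "gd").sum() == 10
        assert (ev.role == "standard").sum() == 25

    def test_generation_zero_gives_single_mode(self):
        ev = synthio.simulate_suppression_assay(
            {"cd4": 500}, 10, cfse_generations=[1.0], seed=2
        )
        cd4 = ev[ev.role == "cd4"]
        assert (cd4.generation == 0).all()
        spread = np.log2(cd4.cfse).std()
        assert spread < 0.5  # well under one division of separation

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            synthio.simulate_suppression_assay({"cd4": -1}, 10, seed=1)
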