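"""k-mer screen: indexing, counting, testing, run calling, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import bh_oracle, naive_count_kmers, random_dna

from editqc._sequence import revcomp
from editqc.io import ConstructAnnotation, SequenceRecord
from editqc.kmer import (
    PositionCountTrack,
    bh_adjust,
    build_kmer_index,
    call_runs,
    classify_transgene,
    control_elevated_mask,
    count_read_kmers,
    entropy_mask,
    estimate_background,
    marker_presence,
    position_test,
    region_averages,
    screen_sample,
)
from editqc.simulate import DECOY_SEQ, build_scenario, scenario_reads


def make_track(counts, total=10_000, sample_id="s", construct_id="c", k=20):
    return PositionCountTrack(sample_id, construct_id, k, np.asarray(counts), total)


class TestIndex:
    def test_number_of_positions_is_length_minus_k_plus_one(self, rng):
        construct = SequenceRecord("c", random_dna(rng, 19_074))
        ix = build_kmer_index(construct, 20)
        assert ix.n_positions == 19_055

    def test_repeated_kmer_maps_to_all_positions(self):
        ix = build_kmer_index(SequenceRecord("c", "ACGTACGTACGT"), 8)
        assert ix.positions["ACGTACGT"] == (1, 5)

    def test_single_kmer_construct(self):
        ix = build_kmer_index(SequenceRecord("c", "AAAAAAAA"), 8)
        assert ix.positions == {"AAAAAAAA": (1,)}

    def test_k_larger_than_construct_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index(SequenceRecord("c", "ACGTACGT"), 9)
        with pytest.raises(ValueError):
            build_kmer_index(SequenceRecord("c", "ACGTACGTACGT"), 4)


class TestCounting:
    def test_exact_substring_read_increments_consecutive_run(self, rng):
        seq = random_dna(rng, 1_000)
        ix = build_kmer_index(SequenceRecord("c", seq), 20)
        track = count_read_kmers([SequenceRecord("r", seq[200:350])], ix)
        assert track.total_read_kmers == 131
        assert (track.counts[200:331] == 1).all()
        assert track.counts.sum() == 131

    def test_unrelated_read_leaves_counts_untouched(self, rng):
        ix = build_kmer_index(SequenceRecord("c", random_dna(rng, 500)), 20)
        # a read over a disjoint alphabet region of randomness; verify against
        # the naive oracle rather than assuming zero by luck
        read = SequenceRecord("r", random_dna(rng, 100))
        track = count_read_kmers([read], ix)
        oracle, _ = naive_count_kmers([read], ix.construct_seq, 20)
        assert (track.counts == oracle).all()

    def test_reverse_complement_read_counts_identically(self, rng):
        seq = random_dna(rng, 800)
        ix = build_kmer_index(SequenceRecord("c", seq), 20)
        fwd = count_read_kmers([SequenceRecord("f", seq[100:260])], ix)
        rev = count_read_kmers([SequenceRecord("r", revcomp(seq[100:260]))], ix)
        assert (fwd.counts == rev.counts).all()

    def test_matches_naive_oracle_on_random_reads(self, rng):
        seq = random_dna(rng, 600)
        ix = build_kmer_index(SequenceRecord("c", seq), 12)
        reads = [SequenceRecord(f"r{i}", random_dna(rng, 60)) for i in range(30)]
        reads += [SequenceRecord("hit", seq[50:140]), SequenceRecord("rc", revcomp(seq[300:390]))]
        track = count_read_kmers(reads, ix)
        oracle, total = naive_count_kmers(reads, seq, 12)
        assert (track.counts == oracle).all()
        assert track.total_read_kmers == total

    def test_palindromic_kmer_counted_once(self):
        # ACGTACGTACGTACGT (16 bp) is its own reverse complement at k=16
        pal = "ACGT" * 4
        assert revcomp(pal) == pal
        construct = SequenceRecord("c", "TT" + pal + "GG")
        ix = build_kmer_index(construct, 16)
        track = count_read_kmers([SequenceRecord("r", pal)], ix)
        oracle, _ = naive_count_kmers([SequenceRecord("r", pal)], construct.sequence, 16)
        assert (track.counts == oracle).all()

    def test_short_and_ambiguous_reads_tallied(self, rng):
        seq = random_dna(rng, 300)
        ix = build_kmer_index(SequenceRecord("c", seq), 20)
        reads = [
            SequenceRecord("short", "ACGT"),
            SequenceRecord("amb", seq[10:40] + "N" + seq[41:70]),
        ]
        track = count_read_kmers(reads, ix)
        assert track.short_reads == 1
        assert track.skipped_ambiguous == 20  # windows overlapping the single N
        oracle, total = naive_count_kmers(reads, seq, 20)
        assert (track.counts == oracle).all()
        assert track.total_read_kmers == total

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_strand_symmetry_property(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        seq = random_dna(rng, 200)
        ix = build_kmer_index(SequenceRecord("c", seq), 10)
        reads = [SequenceRecord(f"r{i}", random_dna(rng, 40)) for i in range(5)]
        flipped = [SequenceRecord(r.id, revcomp(r.sequence)) for r in reads]
        a = count_read_kmers(reads, ix).counts
        b = count_read_kmers(flipped, ix).counts
        assert (a == b).all()


class TestRegionAverages:
    def test_all_zero_track(self):
        ann = ConstructAnnotation("c", 100, (1, 60))
        avg = region_averages(make_track(np.zeros(81)), ann)
        assert (avg.tdna_avg, avg.non_tdna_avg, avg.total_avg) == (0, 0, 0)

    def test_weighted_total_between_region_means(self, rng):
        counts = rng.integers(0, 50, 181)
        ann = ConstructAnnotation("c", 200, (1, 120))
        avg = region_averages(make_track(counts), ann)
        lo, hi = sorted([avg.tdna_avg, avg.non_tdna_avg])
        assert lo <= avg.total_avg <= hi
        w = 120 / 181
        assert avg.total_avg == pytest.approx(w * avg.tdna_avg + (1 - w) * avg.non_tdna_avg)

    def test_empty_region_rejected(self):
        ann = ConstructAnnotation("c", 100, (1, 100))
        with pytest.raises(ValueError):
            region_averages(make_track(np.zeros(81)), ann)


class TestPositionTest:
    def test_zero_sample_count_gives_p_one(self):
        s = make_track([0, 0])
        c = make_track([5, 0])
        assert (position_test(s, c, method="conditional") == 1.0).all()

    def test_conditional_closed_form_equal_totals(self):
        s = make_track([30], total=1000)
        c = make_track([0], total=1000)
        p = position_test(s, c, method="conditional")
        assert p[0] == pytest.approx(2.0**-30, rel=1e-12)

    def test_hybrid_uses_background_when_control_uncovered(self):
        # control evidence at one end; a far-away position (beyond +-k) is
        # uncovered and tested against the background, a nearby one is not
        cs = np.zeros(60, dtype=int)
        cc = np.zeros(60, dtype=int)
        cs[0] = 6          # far from any control coverage
        cs[45] = 6
        cc[50] = 4         # covers 30..60 after +-k dilation (k=20)
        p = position_test(make_track(cs), make_track(cc), background=0.05)
        from scipy import stats
        assert p[0] == pytest.approx(stats.poisson.sf(5, 0.05), rel=1e-9)
        assert p[45] == pytest.approx(stats.binom.sf(5, 6, 0.5), rel=1e-9)

    def test_depth_normalization_shifts_null(self):
        # sample sequenced twice as deep: equal counts are not enrichment
        s = make_track([10], total=2000)
        c = make_track([10], total=1000)
        p_deep = position_test(s, c, method="conditional")
        s2 = make_track([10], total=1000)
        p_flat = position_test(s2, c, method="conditional")
        assert p_deep[0] > p_flat[0]

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            position_test(make_track([1], total=0), make_track([1]))

    def test_randomized_conditional_pvalues_uniform_under_null(self, rng):
        # the PIT form of the exact conditional test is uniform by theorem;
        # KS at 1% checks the implementation
        from scipy import stats
        lam = 2.0
        n = 10_000
        s = make_track(rng.poisson(lam, n), total=500_000)
        c = make_track(rng.poisson(lam, n), total=500_000)
        p = position_test(s, c, method="conditional", randomize=True, rng=rng)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_hybrid_pvalues_conservative_under_null(self, rng):
        # branch selection on c_c == 0 removes extreme outcomes from the
        # binomial stratum, so the hybrid PIT is sub-uniform (never
        # anti-conservative): P(p <= t) <= t up to sampling noise
        lam = 2.0
        n = 10_000
        s = make_track(rng.poisson(lam, n), total=500_000)
        c = make_track(rng.poisson(lam, n), total=500_000)
        p = np.sort(position_test(s, c, background=lam, randomize=True, rng=rng))
        ecdf_excess = (np.arange(1, n + 1) / n) - p
        assert ecdf_excess.max() < 3.0 / np.sqrt(n)


class TestBH:
    def test_single_value_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_hand_oracle(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)

    def test_qvalues_dominate_pvalues(self, rng):
        p = rng.uniform(size=500)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestRunsAndMasking:
    def test_no_significant_positions_yields_empty_lists(self):
        runs, masked, _ = call_runs(np.ones(50), alpha=0.01, k=20)
        assert runs == [] and masked == []

    def test_single_and_double_position_runs_match_fragment_lengths(self):
        q = np.ones(100)
        q[10] = 1e-5          # one position -> 20-bp match
        q[40] = q[41] = 1e-5  # two consecutive -> 21-bp match
        runs, _, _ = call_runs(q, alpha=0.01, k=20)
        assert [(r.start, r.end, r.matched_length) for r in runs] == [
            (11, 11, 20), (41, 42, 21)
        ]

    def test_low_complexity_run_is_masked(self, rng):
        construct = random_dna(rng, 100) + DECOY_SEQ + random_dna(rng, 100)
        q = np.ones(len(construct) - 19)
        q[100] = q[101] = 1e-6  # the two windows fully inside the decoy
        runs, masked, mask = call_runs(q, alpha=0.01, k=20, construct_seq=construct)
        assert runs == []
        assert [(r.start, r.end) for r in masked] == [(101, 102)]
        assert mask[100] and mask[101]

    def test_control_elevated_run_is_masked(self):
        counts = np.zeros(200)
        counts[50:60] = 40  # host-homologous block in the control
        control = make_track(counts)
        q = np.ones(200)
        q[52:55] = 1e-6
        q[120] = 1e-6
        runs, masked, _ = call_runs(q, alpha=0.01, k=20, control=control)
        assert [(r.start, r.end) for r in masked] == [(53, 55)]
        assert [(r.start, r.end) for r in runs] == [(121, 121)]

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            call_runs(np.ones(5), alpha=1.5)


class TestBackgroundEstimate:
    def test_recovers_bulk_rate_under_contamination(self, rng):
        # 15% of positions elevated: a fixed 1% trim would fail here
        counts = rng.poisson(0.7, 20_000)
        counts[:3_000] = rng.poisson(25, 3_000)
        track = make_track(counts)
        assert estimate_background(track) == pytest.approx(0.7, abs=0.05)

    def test_all_zero_control_floors(self):
        assert estimate_background(make_track(np.zeros(1000))) == 0.05

    def test_elevated_mask_flags_block_not_background(self, rng):
        counts = rng.poisson(0.5, 5_000)
        counts[1_000:1_200] = rng.poisson(30, 200)
        mask = control_elevated_mask(make_track(counts))
        assert mask[1_000:1_200].all()
        # away from the (dilated) block boundary the background stays unmasked
        assert mask[:950].mean() < 0.05


class TestEntropyMask:
    def test_decoy_windows_flagged_random_windows_not(self, rng):
        seq = random_dna(rng, 400) + DECOY_SEQ + random_dna(rng, 400)
        mask = entropy_mask(seq, 20)
        assert mask[400] and mask[401]
        assert mask[:350].sum() == 0


class TestClassification:
    def _comparison(self, runs, n=1000, k=20):
        from editqc.kmer import Run, ScreenComparison
        return ScreenComparison(
            "s", "c", k, 0.01, np.ones(n), np.ones(n), np.zeros(n),
            [Run(s, e, e - s + k) for s, e in runs], [], np.zeros(n, bool),
        )

    def test_absent_without_runs(self):
        ann = ConstructAnnotation("c", 1019, (1, 700))
        call = classify_transgene(self._comparison([]), ann)
        assert call.status == "absent"

    def test_present_with_broad_tdna_coverage(self):
        ann = ConstructAnnotation("c", 1019, (1, 700))
        call = classify_transgene(self._comparison([(1, 500)]), ann)
        assert call.status == "present"
        assert call.tdna_covered_fraction > 0.7

    def test_residual_fragments_with_short_runs_only(self):
        ann = ConstructAnnotation("c", 1019, (1, 700))
        call = classify_transgene(self._comparison([(100, 100), (300, 301)]), ann)
        assert call.status == "residual_fragments"

    def test_inconclusive_with_one_long_but_subthreshold_run(self):
        ann = ConstructAnnotation("c", 1019, (1, 700))
        call = classify_transgene(self._comparison([(100, 200)]), ann)
        assert call.status == "inconclusive"


class TestMarkerPresence:
    def test_all_zero_track_negative(self):
        ann = ConstructAnnotation("c", 120, (1, 80), {"HPT": (20, 50)})
        present, mean = marker_presence(make_track(np.zeros(101)), ann, "HPT")
        assert not present and mean == 0

    def test_unknown_feature_rejected(self):
        ann = ConstructAnnotation("c", 120, (1, 80))
        with pytest.raises(KeyError):
            marker_presence(make_track(np.zeros(101)), ann, "HPT")

    def test_feature_signal_over_background(self):
        counts = np.zeros(101)
        counts[19:31] = 12
        ann = ConstructAnnotation("c", 120, (1, 80), {"HPT": (20, 50)})
        present, mean = marker_presence(make_track(counts), ann, "HPT")
        assert present and mean > 1


class TestEndToEndScreen:
    def test_null_screen_has_no_unmasked_runs(self, small_scenario):
        # two same-depth read sets from the transgene-free host
        data = build_scenario(small_scenario)
        ix = build_kmer_index(data.construct, 20)
        ctrl = count_read_kmers(scenario_reads(data, which="control"), ix, sample_id="wt")
        fails = 0
        for rep in range(5):
            from editqc.simulate import simulate_reads
            reads = simulate_reads(
                data.host, small_scenario.depth, 150, small_scenario.error_rate,
                seed=900 + rep, sample_id="null",
            )
            res = screen_sample(ix, data.annotation, ctrl, reads, sample_id=f"null{rep}")
            fails += bool(res.comparison.significant_runs)
            assert res.call.status in ("absent", "residual_fragments")
        assert fails == 0

    def test_homology_block_elevated_in_control_and_masked(self, small_scenario):
        data = build_scenario(small_scenario)
        ix = build_kmer_index(data.construct, 20)
        ctrl = count_read_kmers(scenario_reads(data, which="control"), ix, sample_id="wt")
        hs, he = data.annotation.features["homology_segment"]
        assert ctrl.counts[hs - 1 : he - 20].mean() > 5 * ctrl.counts.mean() * 0.5
        mask = control_elevated_mask(ctrl)
        assert mask[hs + 10 : he - 40].mean() > 0.9

    def test_full_insertion_recovered(self, small_scenario):
        import dataclasses
        sc = dataclasses.replace(small_scenario, event="full_insertion")
        data = build_scenario(sc)
        ix = build_kmer_index(data.construct, 20)
        ctrl = count_read_kmers(scenario_reads(data, which="control"), ix, sample_id="wt")
        res = screen_sample(ix, data.annotation, ctrl, scenario_reads(data, which="sample"))
        assert res.call.status == "present"
        assert res.sample_averages.tdna_avg > 10 * max(res.sample_averages.non_tdna_avg, 0.05)
        present, _ = marker_presence(res.sample_track, data.annotation, "HPT")
        assert present
        present_cas9, _ = marker_presence(res.sample_track, data.annotation, "Cas9")
        assert present_cas9

    def test_no_insertion_markers_negative(self, small_scenario):
        data = build_scenario(small_scenario)
        ix = build_kmer_index(data.construct, 20)
        track = count_read_kmers(scenario_reads(data, which="sample"), ix, sample_id="s")
        assert not marker_presence(track, data.annotation, "HPT")[0]

    def test_depth_matches_expected_tdna_average(self, small_scenario):
        # full insertion at depth d: expected count per T-DNA position is
        # d * (R - k + 1) / R * P(kmer error-free)
        import dataclasses
        sc = dataclasses.replace(small_scenario, event="full_insertion")
        data = build_scenario(sc)
        ix = build_kmer_index(data.construct, 20)
        track = count_read_kmers(scenario_reads(data, which="sample"), ix, sample_id="s")
        ann = data.annotation
        hs, he = ann.features["homology_segment"]
        tdna = np.ones(track.counts.size, bool)
        tdna[ann.tdna_interval[1]:] = False
        tdna[hs - 21 : he] = False  # exclude the two-copy homology block
        expect = sc.depth * 131 / 150 * (1 - sc.error_rate) ** 20
        assert track.counts[tdna].mean() == pytest.approx(expect, rel=0.15)
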