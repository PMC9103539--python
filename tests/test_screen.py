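"""Coverage, dense sub-region detection, repeat filtering and the funnel."""

import numpy as np
import pytest

import ernascan as es
from ernascan.screen import FILTERED_CLASSES

LOCUS = es.LocusSpec("c", 0, 1000)


def aln(read_id, pos):
    return es.AlignmentRecord(read_id, pos, "+", 0)


def region(start, end, rid="r", stage=es.Stage.MERGED):
    return es.CandidateRegion(es.GenomicInterval("c", start, end), stage, rid)


def repeat(start, end, cls=es.RepeatClass.SINE):
    return es.RepeatRecord(es.GenomicInterval("c", start, end), cls)


class TestComputeCoverage:
    def test_single_alignment_span(self):
        track = es.compute_coverage([aln("r", 0)], 10, LOCUS)
        assert track.depth[:10].tolist() == [1] * 10
        assert track.depth[10:].sum() == 0

    def test_two_identical_alignments_stack(self):
        track = es.compute_coverage([aln("a", 5), aln("b", 5)], 10, LOCUS)
        assert track.depth[5:15].tolist() == [2] * 10

    def test_conservation_on_random_alignments(self):
        rng = np.random.default_rng(21)
        alignments = [aln(f"r{i}", int(rng.integers(0, 950))) for i in range(500)]
        track = es.compute_coverage(alignments, 50, LOCUS)
        assert track.depth.sum() == 500 * 50

    def test_matches_per_base_oracle(self, oracles):
        rng = np.random.default_rng(22)
        alignments = [aln(f"r{i}", int(rng.integers(0, 950))) for i in range(100)]
        track = es.compute_coverage(alignments, 50, LOCUS)
        expected = oracles.coverage_by_base([(a.position, 50) for a in alignments], 1000)
        assert np.array_equal(track.depth, expected)

    def test_out_of_locus_alignment_errors(self):
        with pytest.raises(ValueError, match="outside the locus"):
            es.compute_coverage([aln("r", 995)], 10, LOCUS)


class TestDropZeroReadRegions:
    def test_uncovered_region_removed(self):
        kept = es.drop_zero_read_regions(
            [region(100, 200, stage=es.Stage.CONSTRUCTED)], [aln("r", 500)], 50, LOCUS
        )
        assert kept == []

    def test_single_base_overlap_retained(self):
        [kept] = es.drop_zero_read_regions(
            [region(100, 200, stage=es.Stage.CONSTRUCTED)], [aln("r", 51)], 50, LOCUS
        )
        assert kept.read_count == 1 and kept.stage == es.Stage.COVERED

    def test_survivors_match_quadratic_oracle(self):
        rng = np.random.default_rng(23)
        regions = [
            region(int(s), int(s) + 60, f"g{i}", stage=es.Stage.CONSTRUCTED)
            for i, s in enumerate(rng.integers(0, 900, size=30))
        ]
        alignments = [aln(f"r{i}", int(rng.integers(0, 950))) for i in range(40)]
        kept = es.drop_zero_read_regions(regions, alignments, 50, LOCUS)
        expected = set()
        for reg in regions:
            count = sum(
                1 for a in alignments
                if a.position < reg.interval.end and a.position + 50 > reg.interval.start
            )
            if count:
                expected.add((reg.region_id, count))
        assert {(r.region_id, r.read_count) for r in kept} == expected


class TestDetectDenseSubregions:
    def _track(self, depth):
        locus = es.LocusSpec("c", 0, len(depth))
        return es.CoverageTrack(locus, np.asarray(depth)), region(0, len(depth))

    def test_constant_depth_yields_whole_region(self):
        track, reg = self._track([5] * 200)
        [sub] = es.detect_dense_subregions(track, reg, es.DenseParams(5, 100, 0))
        assert (sub.interval.start, sub.interval.end) == (0, 200)
        assert sub.stage == es.Stage.DENSE_SUBREGION

    def test_gap_bridged_or_split_by_max_gap(self):
        depth = [5] * 120 + [0] * 10 + [5] * 120
        track, reg = self._track(depth)
        [bridged] = es.detect_dense_subregions(track, reg, es.DenseParams(5, 100, 50))
        assert (bridged.interval.start, bridged.interval.end) == (0, 250)
        split = es.detect_dense_subregions(track, reg, es.DenseParams(5, 100, 5))
        assert [(s.interval.start, s.interval.end) for s in split] == [(0, 120), (130, 250)]

    def test_all_zero_depth(self):
        track, reg = self._track([0] * 300)
        assert es.detect_dense_subregions(track, reg, es.DenseParams()) == []

    def test_endpoints_sit_on_dense_bases(self):
        depth = [0] * 30 + [7] * 150 + [1] * 20 + [9] * 150 + [0] * 30
        track, reg = self._track(depth)
        [sub] = es.detect_dense_subregions(track, reg, es.DenseParams(5, 100, 50))
        assert (sub.interval.start, sub.interval.end) == (30, 350)

    def test_random_tracks_match_scan_oracle(self, oracles):
        rng = np.random.default_rng(24)
        for _ in range(50):
            depth = rng.integers(0, 10, size=400)
            c, L, g = int(rng.integers(1, 8)), int(rng.integers(1, 120)), int(rng.integers(0, 40))
            track, reg = self._track(depth)
            got = [
                (s.interval.start, s.interval.end)
                for s in es.detect_dense_subregions(track, reg, es.DenseParams(c, L, g))
            ]
            assert got == oracles.dense_runs_by_scan(depth, c, L, g)


class TestFilterRepeats:
    def test_subregion_inside_sine_removed(self):
        subs = [region(100, 200, stage=es.Stage.DENSE_SUBREGION)]
        assert es.filter_repeats(subs, [repeat(50, 300)], es.RepeatFilterParams()) == []

    def test_other_class_never_filters(self):
        subs = [region(100, 200, stage=es.Stage.DENSE_SUBREGION)]
        kept = es.filter_repeats(
            subs, [repeat(50, 300, es.RepeatClass.OTHER)], es.RepeatFilterParams()
        )
        assert len(kept) == 1 and kept[0].stage == es.Stage.REPEAT_FREE

    def test_matches_per_base_oracle_and_monotone_in_tolerance(self, oracles):
        rng = np.random.default_rng(25)
        subs = [
            region(int(s), int(s) + 80, f"s{i}", stage=es.Stage.DENSE_SUBREGION)
            for i, s in enumerate(rng.integers(0, 900, size=20))
        ]
        reps = [
            repeat(int(s), int(s) + int(rng.integers(10, 120)))
            for s in rng.integers(0, 950, size=15)
        ]
        rep_spans = [(r.interval.start, r.interval.end) for r in reps]
        prev_count = -1
        for frac in (0.0, 0.1, 0.3, 0.6, 1.0):
            kept = es.filter_repeats(subs, reps, es.RepeatFilterParams(max_overlap_frac=frac))
            expected = {
                s.region_id
                for s in subs
                if oracles.repeat_overlap_frac_by_base(
                    (s.interval.start, s.interval.end), rep_spans
                ) <= frac
            }
            assert {s.region_id for s in kept} == expected
            assert len(kept) >= prev_count
            prev_count = len(kept)


class TestUniquenessAndAnnotation:
    def test_region_without_surviving_subregion_removed(self):
        regions = [region(0, 500, "m0"), region(600, 900, "m1")]
        surviving = [
            es.CandidateRegion(
                es.GenomicInterval("c", 650, 800), es.Stage.REPEAT_FREE, "m1.sub_0", ("m1",)
            )
        ]
        kept = es.region_uniqueness_verdict(regions, surviving)
        assert [r.region_id for r in kept] == ["m1"]

    def test_verdict_matches_set_join_recount(self, screen_result):
        alive = {p for s in screen_result.surviving_subregions for p in s.parent_ids}
        expected = [
            r.region_id
            for r in screen_result.stage_regions["dense_subregion"]
            if r.region_id in alive
        ]
        assert [r.region_id for r in screen_result.stage_regions["repeat_free"]] == expected

    def test_exon_overlap_matches_intron_does_not(self):
        tx = es.TranscriptRecord(
            "tx", "g",
            (es.GenomicInterval("c", 100, 200, "+"), es.GenomicInterval("c", 400, 500, "+")),
        )
        exonic = region(150, 250, stage=es.Stage.REPEAT_FREE)
        intronic = region(250, 380, stage=es.Stage.REPEAT_FREE)
        results = es.annotate_candidates([exonic, intronic], [tx])
        assert results[0][1] == [tx] and results[0][0].stage == es.Stage.ANNOTATED
        assert results[1][1] == [] and results[1][0].stage == es.Stage.REPEAT_FREE

    def test_annotation_matches_all_pairs_scan(self, screen_result, default_fixture):
        sim, _ = default_fixture
        for sub, matches in screen_result.annotation:
            expected = [
                tx
                for tx in sim.transcripts
                if any(
                    sub.interval.start < e.end and e.start < sub.interval.end
                    for e in tx.exons
                )
            ]
            assert matches == expected


class TestRunScreen:
    def test_no_reads_collapses_after_zero_read_stage(self, default_fixture):
        sim, _ = default_fixture
        result = es.run_screen(
            peaks=sim.peaks, locus=sim.locus, repeats=sim.repeats,
            transcripts=sim.transcripts, locus_sequence=sim.sequence, reads=[],
        )
        assert result.funnel.counts == [12, 0, 0, 0, 0, 0]

    def test_repeats_everywhere_leave_no_repeat_free_region(self, default_fixture):
        sim, reads = default_fixture
        wall_to_wall = [es.RepeatRecord(es.GenomicInterval(sim.locus.chrom, 0, sim.locus.end),
                                        es.RepeatClass.LINE)]
        result = es.run_screen(
            peaks=sim.peaks, locus=sim.locus, repeats=wall_to_wall,
            transcripts=sim.transcripts, locus_sequence=sim.sequence, reads=reads,
        )
        assert dict(zip(result.funnel.stage_names, result.funnel.counts))["repeat_free"] == 0

    def test_funnel_counts_never_increase(self, screen_result):
        counts = screen_result.funnel.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_read_order_permutation_leaves_funnel_unchanged(self, default_fixture, screen_result):
        sim, reads = default_fixture
        shuffled = list(reads)
        np.random.default_rng(99).shuffle(shuffled)
        result = es.run_screen(
            peaks=sim.peaks, locus=sim.locus, repeats=sim.repeats,
            transcripts=sim.transcripts, locus_sequence=sim.sequence, reads=shuffled,
        )
        assert result.funnel.counts == screen_result.funnel.counts
        assert [c.interval for c in result.candidates] == [
            c.interval for c in screen_result.candidates
        ]

    def test_coverage_conservation_holds_on_run(self, default_fixture, screen_result):
        sim, reads = default_fixture
        lengths = {r.read_id: len(r.sequence) for r in reads}
        alignments = es.align_all(reads, sim.sequence)
        expected = sum(lengths[a.read_id] for a in alignments)
        assert screen_result.coverage.depth.sum() == expected

    def test_stage_error_names_stage(self, default_fixture):
        sim, _ = default_fixture
        overhanging = [es.AlignmentRecord("r", sim.locus.length - 10, "+", 0)]
        with pytest.raises(RuntimeError, match="coverage"):
            es.run_screen(
                peaks=sim.peaks, locus=sim.locus, repeats=sim.repeats,
                transcripts=sim.transcripts,
                alignments=overhanging, read_lengths=50,
            )

    def test_default_classes_are_the_four_interspersed_families(self):
        assert FILTERED_CLASSES == {
            es.RepeatClass.SINE, es.RepeatClass.LINE, es.RepeatClass.LTR, es.RepeatClass.DNA
        }
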