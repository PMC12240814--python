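"""Copy-number: binning, counting, normalization, smoothing, Anscombe,
circular binary segmentation (with exhaustive oracle) and segment merging."""

import math

import numpy as np
import pysam
import pytest

from svarcall import copy_number as cn
from svarcall.io_formats import GenomicInterval


class TestBuildBins:
    def test_contig_tiles_into_fixed_bins(self):
        bins = cn.build_bins({"chr1": 100_000}, bin_size=10_000)
        assert len(bins) == 10
        assert bins[0].interval == GenomicInterval("chr1", 0, 10_000)

    def test_breakend_splits_its_bin(self):
        bins = cn.build_bins({"chr1": 100_000}, bin_size=10_000, breakpoints=[("chr1", 25_000)])
        ivs = [(b.interval.start, b.interval.end) for b in bins]
        assert (20_000, 25_000) in ivs and (25_000, 30_000) in ivs
        assert len(bins) == 11

    def test_short_contig_single_truncated_bin(self):
        bins = cn.build_bins({"chrM": 7_000}, bin_size=10_000)
        assert len(bins) == 1 and bins[0].interval.end == 7_000


class TestFilterBins:
    def test_blacklist_overlap_above_threshold_excludes(self):
        bins = cn.build_bins({"chr1": 10_000}, bin_size=10_000)
        blk = [GenomicInterval("chr1", 0, 600)]  # 6% overlap
        cn.filter_bins(bins, blacklist=blk)
        assert bins[0].excluded and bins[0].exclusion_reason == "blacklist"

    def test_blacklist_overlap_at_threshold_kept(self):
        bins = cn.build_bins({"chr1": 10_000}, bin_size=10_000)
        blk = [GenomicInterval("chr1", 0, 500)]  # exactly 5%
        cn.filter_bins(bins, blacklist=blk)
        assert not bins[0].excluded

    def test_n_fraction_excludes(self):
        bins = cn.build_bins({"chr1": 10_000}, bin_size=10_000)
        key = ("chr1", 0, 10_000)
        cn.filter_bins(bins, n_fraction_per_bin={key: 0.80})
        assert bins[0].exclusion_reason == "n_fraction"


def _count_bam(tmp_path, records):
    path = str(tmp_path / "c.bam")
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100_000}]}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for name, pos, mapq, flag in records:
            rec = pysam.AlignedSegment(header=bam.header)
            rec.query_name = name
            rec.reference_id = 0
            rec.reference_start = pos
            rec.mapping_quality = mapq
            rec.cigarstring = "100M"
            rec.flag = flag
            bam.write(rec)
    pysam.sort("-o", path, path)
    pysam.index(path)
    return path


class TestCountReads:
    def test_supplementary_and_low_mapq_not_counted(self, tmp_path):
        path = _count_bam(
            tmp_path,
            [("a", 500, 60, 0), ("b", 600, 60, 2048), ("c", 700, 4, 0), ("d", 800, 5, 0)],
        )
        bins = cn.build_bins({"chr1": 100_000}, bin_size=10_000)
        cn.count_reads(path, bins)
        assert bins[0].tumor_count == 2  # a and d only

    def test_boundary_read_counts_in_right_hand_bin(self, tmp_path):
        path = _count_bam(tmp_path, [("a", 10_000, 60, 0)])
        bins = cn.build_bins({"chr1": 100_000}, bin_size=10_000)
        cn.count_reads(path, bins)
        assert bins[0].tumor_count == 0 and bins[1].tumor_count == 1


def _bin(contig, start, t, n=None):
    return cn.CopyNumberBin(GenomicInterval(contig, start, start + 10_000), tumor_count=t, normal_count=n)


class TestNormalize:
    def test_paired_equal_depth_gives_zero(self):
        bins = [_bin("chr1", i * 10_000, 100, 100) for i in range(4)]
        cn.normalize_log2(bins, mode="paired")
        assert all(b.log2r == pytest.approx(0.0) for b in bins)

    def test_paired_twofold_gain(self):
        # one doubled bin among many neutral ones; depth scaling uses totals
        bins = [_bin("chr1", i * 10_000, 100, 100) for i in range(100)] + [_bin("chr1", 1_000_000, 200, 100)]
        cn.normalize_log2(bins, mode="paired")
        scale = (100 * 100 + 100) / (100 * 100 + 200)
        assert bins[-1].log2r == pytest.approx(math.log2(2 * scale))

    def test_zero_normal_bin_excluded_not_infinite(self):
        bins = [_bin("chr1", 0, 100, 0), _bin("chr1", 10_000, 100, 100)]
        cn.normalize_log2(bins, mode="paired")
        assert bins[0].excluded and bins[0].log2r is None

    def test_tumor_only_median_is_zero(self):
        bins = [_bin("chr1", i * 10_000, c) for i, c in enumerate([50, 100, 100, 100, 400])]
        cn.normalize_log2(bins, mode="tumor_only")
        assert bins[1].log2r == pytest.approx(0.0)
        assert bins[4].log2r == pytest.approx(2.0)

    def test_zero_count_bins_removed(self):
        bins = [_bin("chr1", 0, 0, 0), _bin("chr1", 10_000, 100, 100)]
        cn.normalize_log2(bins, mode="paired")
        assert bins[0].exclusion_reason == "zero_count"


class TestSmoothing:
    def test_single_spike_replaced_by_local_median(self):
        x = np.zeros(20)
        x[2:18] += np.linspace(-0.01, 0.01, 16)  # non-degenerate MAD
        x[10] = 10.0
        out = cn.smooth_outliers(x)
        assert abs(out[10]) < 0.1
        assert np.array_equal(out[:10], x[:10])

    def test_flat_series_unchanged(self):
        x = np.ones(15)
        assert np.array_equal(cn.smooth_outliers(x), x)

    def test_two_consecutive_spikes_untouched(self):
        x = np.zeros(20)
        x[2:18] += np.linspace(-0.01, 0.01, 16)
        x[10] = 10.0
        x[11] = 10.0
        out = cn.smooth_outliers(x)
        assert out[10] == 10.0 and out[11] == 10.0


class TestVarianceStabilize:
    def test_closed_forms(self):
        assert cn.variance_stabilize(np.array([0.0]))[0] == pytest.approx(2 * math.sqrt(1.375), abs=1e-12)
        # log2r -> -inf corresponds to ratio 0; approximate with a huge loss
        assert cn.variance_stabilize(np.array([-50.0]))[0] == pytest.approx(2 * math.sqrt(0.375), rel=1e-6)

    def test_monotone(self):
        l = np.linspace(-3, 3, 50)
        a = cn.variance_stabilize(l)
        assert np.all(np.diff(a) > 0)


def brute_force_max_arc(x):
    """Independent O(n^2) double-loop scan of the same arc statistic.

    Ties (an arc and its circular complement score identically) resolve to
    the lexicographically smallest (i, j), matching the documented contract.
    """
    x = np.asarray(x, float)
    n = len(x)
    sd = x.std()
    mean = x.mean()

    def stat(i, j):
        k = j - i
        return abs(x[i:j].sum() - k * mean) / (sd * math.sqrt(k * (1 - k / n)))

    arcs = [(i, j) for i in range(n) for j in range(i + 1, n + 1) if j - i < n]
    best = max(stat(i, j) for i, j in arcs)
    for i, j in arcs:  # already in lexicographic order
        if stat(i, j) >= best - 1e-12:
            return best, i, j


class TestCbs:
    def test_constant_series_no_changepoints(self):
        assert cn.cbs_segment(np.zeros(100), seed=0) == []

    def test_strong_step_recovered_exactly_once(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(5, 1, 100)])
        cps = cn.cbs_segment(x, seed=3)
        assert len(cps) == 1 and abs(cps[0] - 100) <= 2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(2, 1, 60)])
        assert cn.cbs_segment(x, seed=9) == cn.cbs_segment(x, seed=9)

    @pytest.mark.parametrize("trial", range(25))
    def test_split_statistic_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 31))
        x = rng.normal(0, 1, n)
        got_stat, gi, gj = cn.max_arc_statistic(x)
        exp_stat, ei, ej = brute_force_max_arc(x)
        assert got_stat == pytest.approx(exp_stat, abs=1e-9)
        assert (gi, gj) == (ei, ej)

    def test_short_series_no_changepoints(self):
        assert cn.cbs_segment(np.array([1.0, 5.0, 1.0]), seed=0) == []


class TestMergeSegments:
    def _segs(self, means, contig="chr1"):
        segs = []
        for i, m in enumerate(means):
            segs.append(
                cn.CopyNumberSegment(
                    interval=GenomicInterval(contig, i * 100_000, (i + 1) * 100_000),
                    mean_log2r=m,
                    n_bins=10,
                    bin_indices=(i * 10, (i + 1) * 10),
                )
            )
        return segs

    def test_equal_means_all_merge(self):
        merged = cn.merge_segments(self._segs([0.5, 0.5, 0.5]))
        assert len(merged) == 1

    def test_two_segments_never_merge_on_their_own_difference(self):
        merged = cn.merge_segments(self._segs([0.0, 3.0]))
        assert len(merged) == 2  # threshold is their own delta; strict <

    def test_three_segment_oracle(self):
        # means {0, 0.02, 1.0}: pairwise diffs {0.02, 0.98, 1.0}; 20th
        # percentile (linear interpolation) = 0.404; only |0-0.02| merges
        diffs = np.array([0.02, 0.98, 1.0])
        threshold = float(np.percentile(diffs, 20))
        assert threshold == pytest.approx(0.404)
        merged = cn.merge_segments(self._segs([0.0, 0.02, 1.0]))
        assert len(merged) == 2
        assert merged[0].n_bins == 20

    def test_different_contigs_never_merge(self):
        a = self._segs([0.1])
        b = self._segs([0.1], contig="chr2")
        merged = cn.merge_segments(a + b)
        assert len(merged) == 2

    def test_segments_tile_retained_bins(self):
        rng = np.random.default_rng(5)
        bins = [_bin("chr1", i * 10_000, int(c), 100) for i, c in enumerate(rng.poisson(100, 200))]
        result = cn.run_copy_number(bins, mode="paired", seed=5)
        retained = [b for b in bins if not b.excluded]
        assert sum(s.n_bins for s in result.segments) == len(retained)
        for a, b in zip(result.segments, result.segments[1:]):
            if a.interval.contig == b.interval.contig:
                assert a.interval.end == b.interval.start
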