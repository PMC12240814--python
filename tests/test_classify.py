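"""Feature encoding, training labels, the forest, conformal regions,
filter precedence, rescue and panel filtering."""

import numpy as np
import pytest

from svarcall import classify as cls
from svarcall.clustering import cluster_breakpoints
from svarcall.discovery import CIGAR_DELETION, CoverageTrack, PutativeBreakpoint
from svarcall.io_formats import Breakend

CONTIGS = {"chr1": 100_000}


def make_cluster(pos=10_000, mate=10_500, n_reads=5, sample="tumor", mapq=60, length=None):
    members = [
        PutativeBreakpoint(
            locus_a=("chr1", pos, "+"),
            locus_b=("chr1", mate, "-"),
            kind=CIGAR_DELETION,
            sv_length=length if length is not None else mate - pos,
            read_name=f"{sample}_read{i}",
            sample=sample,
            mapq=mapq,
        )
        for i in range(n_reads)
    ]
    (cluster,) = cluster_breakpoints(members)
    return cluster


def coverage_with_depth(depth, contigs=CONTIGS):
    track = CoverageTrack(contigs, bin_size=5)
    for contig in contigs:
        for key in ((contig, 0),):
            track.counts[key][:] = depth
    return track


class TestFeatureEncoding:
    def test_vector_has_exactly_seventy_features(self):
        feats = cls.encode_features(make_cluster(), coverage_with_depth(10))
        assert feats.values.shape == (70,)
        assert len(cls.FEATURE_MANIFEST) == 70

    def test_degenerate_identical_members(self):
        # 5 identical 500 bp deletions over depth 10: AF 0.5, zero scatter
        feats = cls.encode_features(make_cluster(n_reads=5), coverage_with_depth(10))
        assert feats["tumor_af_a"] == pytest.approx(0.5)
        assert feats["sv_length_std"] == 0.0
        assert feats["start_std"] == 0.0

    def test_unpaired_mode_zeroes_normal_features(self):
        feats = cls.encode_features(make_cluster(), coverage_with_depth(10), None)
        assert feats["paired_mode"] == 0.0
        assert feats["normal_depth_at_a"] == 0.0
        assert feats["normal_support"] == 0.0

    def test_feature_names_unique(self):
        assert len(set(cls.FEATURE_MANIFEST)) == 70


class TestTrainingLabels:
    def _truth(self):
        return [Breakend("chr1", 10_040, "+")]

    def test_matched_within_buffer_is_somatic(self):
        cluster = make_cluster(pos=10_000)
        feats = cls.encode_features(cluster, coverage_with_depth(20))
        _, _, labels = cls.build_training_labels([cluster], [feats], self._truth())
        assert labels == [cls.SOMATIC]

    def test_strong_unmatched_cluster_excluded(self):
        cluster = make_cluster(pos=50_000, mate=50_500, n_reads=7, mapq=55)
        feats = cls.encode_features(cluster, coverage_with_depth(20), coverage_with_depth(20))
        kept, _, labels = cls.build_training_labels([cluster], [feats], self._truth())
        assert kept == [] and labels == []

    def test_weak_unmatched_cluster_is_noise(self):
        cluster = make_cluster(pos=50_000, mate=50_500, n_reads=2, mapq=20)
        feats = cls.encode_features(cluster, coverage_with_depth(40))
        _, _, labels = cls.build_training_labels([cluster], [feats], self._truth())
        assert labels == [cls.NOISE]


def _separable_data(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, 70))
    y = np.where(X[:, 0] > 0, cls.SOMATIC, cls.NOISE)
    X[:, 0] += np.where(y == cls.SOMATIC, 2.0, -2.0)
    return X, y


class TestForest:
    def test_separable_data_high_auroc(self):
        X, y = _separable_data()
        model = cls.train_classifier(X, y, seed=1)
        assert model.holdout_auroc_ >= 0.95

    def test_no_signal_gives_chance_auroc(self):
        # labels independent of the features: ranking cannot beat chance
        rng = np.random.default_rng(2)
        X = rng.normal(size=(800, 70))
        y = rng.permutation(np.array([cls.SOMATIC] * 400 + [cls.NOISE] * 400))
        model = cls.train_classifier(X, y, seed=2)
        assert abs(model.holdout_auroc_ - 0.5) < 0.15

    def test_same_seed_identical_predictions(self):
        X, y = _separable_data(500)
        m1 = cls.train_classifier(X, y, seed=5)
        m2 = cls.train_classifier(X, y, seed=5)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_raises(self):
        X = np.zeros((10, 70))
        with pytest.raises(ValueError, match="single class"):
            cls.train_classifier(X, np.array([cls.SOMATIC] * 10), seed=0)

    def test_wrong_feature_count_raises(self):
        X, y = _separable_data(200)
        model = cls.train_classifier(X, y, seed=0)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 69)))


class TestFilterPrecedence:
    @pytest.fixture
    def model(self):
        X, y = _separable_data(400, seed=3)
        return cls.train_classifier(X, y, seed=3)

    def _classify_one(self, model, cluster, depth=20, **kw):
        feats = cls.encode_features(cluster, coverage_with_depth(depth))
        # force the prediction by surgery on feature 0 (the separable axis)
        feats.values[0] = kw.pop("axis", 3.0)
        (out,) = cls.classify_and_filter(model, [cluster], [feats], **kw)
        return out

    def test_predicted_noise_is_likely_noise(self, model):
        out = self._classify_one(model, make_cluster(), axis=-3.0)
        assert out.filter_status == cls.LIKELY_NOISE

    def test_somatic_with_low_support(self, model):
        out = self._classify_one(model, make_cluster(n_reads=2))
        assert out.class_label == cls.SOMATIC
        assert out.filter_status == cls.LOW_SUPPORT

    def test_somatic_with_low_af(self, model):
        cluster = make_cluster(n_reads=4)
        feats = cls.encode_features(cluster, coverage_with_depth(1000))
        feats.values[0] = 3.0
        (out,) = cls.classify_and_filter(model, [cluster], [feats])
        assert out.filter_status == cls.LOW_AF

    def test_pass(self, model):
        out = self._classify_one(model, make_cluster(n_reads=5))
        assert out.filter_status == cls.PASS


class TestConformal:
    def test_p_values_match_hand_computation(self):
        # calibration scores fixed by construction: all somatic trees vote
        # perfectly on one side, so nonconformity ~ 0/1 split
        X, y = _separable_data(1000, seed=4)
        mcp = cls.mcp_calibrate(X, y, seed=4)
        q = np.zeros((1, 70))
        q[0, 0] = 3.0
        pvals = mcp.p_values(q)
        assert pvals[cls.SOMATIC][0] > 0.5
        assert pvals[cls.NOISE][0] < 0.2
        assert mcp.predict_region(q, epsilon=0.2) == [cls.SOMATIC]

    def test_outlier_gets_null_region(self):
        X, y = _separable_data(1000, seed=5)
        mcp = cls.mcp_calibrate(X, y, seed=5)
        q = np.zeros((1, 70))  # on the decision boundary: unlike both classes
        regions = mcp.predict_region(q, epsilon=0.49)
        assert regions == ["null"]

    def test_regions_nest_as_epsilon_shrinks(self):
        X, y = _separable_data(800, seed=6)
        mcp = cls.mcp_calibrate(X, y, seed=6)
        rng = np.random.default_rng(6)
        Q = rng.normal(0, 2, size=(50, 70))
        order = {"null": 0, cls.SOMATIC: 1, cls.NOISE: 1, "both": 2}
        for eps_hi, eps_lo in [(0.3, 0.1), (0.1, 0.01)]:
            hi = mcp.predict_region(Q, eps_hi)
            lo = mcp.predict_region(Q, eps_lo)
            for a, b in zip(hi, lo):
                assert order[b] >= order[a]  # smaller epsilon -> larger region

    def test_invalid_epsilon_raises(self):
        X, y = _separable_data(300, seed=7)
        mcp = cls.mcp_calibrate(X, y, seed=7)
        with pytest.raises(ValueError):
            mcp.predict_region(X[:1], epsilon=1.5)


class TestRescue:
    def _classified(self, cluster, status=cls.LIKELY_NOISE):
        cb = cls.ClassifiedBreakpoint(cluster=cluster, class_label=cls.NOISE,
                                      class_probability=0.4, filter_status=status)
        cluster.filter_status = status
        return cb

    def test_qualifying_cluster_rescued(self):
        cluster = make_cluster(n_reads=4)
        cluster.normal_any_support = 0
        (out,) = cls.rescue_by_changepoints([self._classified(cluster)], [("chr1", 10_040)])
        assert out.filter_status == cls.PASS and out.rescued

    def test_distance_rule(self):
        cluster = make_cluster(n_reads=4)
        cluster.normal_any_support = 0
        (out,) = cls.rescue_by_changepoints([self._classified(cluster)], [("chr1", 10_560 + 1)])
        assert not out.rescued  # 61 bp from the nearer breakend

    def test_normal_any_support_blocks_rescue(self):
        cluster = make_cluster(n_reads=4)
        cluster.normal_any_support = 3
        (out,) = cls.rescue_by_changepoints([self._classified(cluster)], [("chr1", 10_040)])
        assert not out.rescued

    def test_normal_supporting_reads_block_rescue(self):
        members = make_cluster(n_reads=4).members + make_cluster(n_reads=1, sample="normal").members
        (cluster,) = cluster_breakpoints(members)
        cluster.normal_any_support = 1
        (out,) = cls.rescue_by_changepoints([self._classified(cluster)], [("chr1", 10_040)])
        assert not out.rescued


class TestGermlinePanels:
    def test_hit_with_high_population_af_removed(self):
        cluster = make_cluster(pos=10_000)
        kept, germ = cls.filter_germline_panels([cluster], [(Breakend("chr1", 10_080, "+"), 0.2)])
        assert kept == [] and germ == [cluster]
        assert cluster.filter_status == "GERMLINE"

    def test_low_af_panel_entry_ignored(self):
        cluster = make_cluster(pos=10_000)
        kept, germ = cls.filter_germline_panels([cluster], [(Breakend("chr1", 10_080, "+"), 0.05)])
        assert kept == [cluster] and germ == []

    def test_no_panels_no_change(self):
        cluster = make_cluster()
        kept, germ = cls.filter_germline_panels([cluster])
        assert kept == [cluster]

    def test_pon_entry_removes_without_af(self):
        cluster = make_cluster(pos=10_000)
        kept, germ = cls.filter_germline_panels([cluster], pon_svs=[Breakend("chr1", 10_050, "+")])
        assert germ == [cluster]
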