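"""Somatic/noise classification of breakpoint clusters.

Each cluster is encoded as a fixed 70-covariate vector (support, allele
fraction, mapping quality, positional scatter, per-haplotype depth around both
breakends, notation).  A random-forest classifier separates somatic junctions
from alignment noise; a Mondrian (class-conditional) conformal predictor wraps
the forest to attach calibrated prediction regions with a guaranteed maximum
per-class error rate under exchangeability.  Downstream filters vet the
predictions with allele-fraction and support thresholds, rescue borderline
calls at copy-number changepoints, and remove germline hits against panels in
tumor-only mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.utils.validation import check_is_fitted

from svarcall.clustering import NOTATIONS, BreakpointCluster
from svarcall.discovery import CoverageTrack
from svarcall.io_formats import NORMAL, TUMOR, UNPHASED, Breakend

SOMATIC = "somatic"
NOISE = "noise"

PASS = "PASS"
LIKELY_NOISE = "LIKELY_NOISE"
LOW_SUPPORT = "LOW_SUPPORT"
LOW_AF = "LOW_AF"

DEFAULT_AF_MIN = 0.01
DEFAULT_SUPPORT_MIN = 3
DEFAULT_EPSILON = 0.05

_DEPTH_FLANK = 100  # bp offset used for the before/after depth covariates


def _depth_features(track: Optional[CoverageTrack], contig: str, pos: int) -> dict[str, float]:
    """Total depth before/at/after a breakend plus per-haplotype depth at it."""
    out = {"before": 0.0, "at": 0.0, "after": 0.0, "hp1": 0.0, "hp2": 0.0, "hp0": 0.0}
    if track is None or contig not in track.contig_lengths:
        return out
    length = track.contig_lengths[contig]
    clamp = lambda p: min(max(p, 0), length - 1)
    at = track.at(contig, clamp(pos))
    out["at"] = float(at["total"])
    out["hp1"], out["hp2"], out["hp0"] = float(at[1]), float(at[2]), float(at[UNPHASED])
    out["before"] = float(track.at(contig, clamp(pos - _DEPTH_FLANK))["total"])
    out["after"] = float(track.at(contig, clamp(pos + _DEPTH_FLANK))["total"])
    return out


def _build_manifest() -> list[str]:
    names = [
        "mapq_mean", "mapq_std", "mapq_min", "mapq_max",
        "sv_length_mean", "sv_length_std", "sv_length_median",
        "sv_length_min", "sv_length_max",
        "start_std", "end_std", "start_mad", "end_mad",
        "span_a", "span_b", "locus_gap",
        "n_members", "tumor_support", "normal_support",
        "tumor_af_a", "tumor_af_b", "normal_af_a", "normal_af_b",
        "insert_size", "insert_size_std",
        "tumor_hp1_support", "tumor_hp2_support", "tumor_unphased_support",
        "normal_hp1_support", "normal_hp2_support", "normal_unphased_support",
        "unphased_fraction", "hp_imbalance",
        "normal_any_support", "normal_any_af",
        "frac_split", "frac_cigar", "frac_softclip",
        "paired_mode", "interchromosomal",
    ]
    for sample in ("tumor", "normal"):
        for locus in ("a", "b"):
            for what in ("before", "at", "after"):
                names.append(f"{sample}_depth_{what}_{locus}")
    for sample in ("tumor", "normal"):
        for hap in ("hp1", "hp2", "hp0"):
            names.append(f"{sample}_depth_{hap}_a")
    # depth discontinuity across each breakend (after minus before) and the
    # depth ratio between the two breakends
    for sample in ("tumor", "normal"):
        for locus in ("a", "b"):
            names.append(f"{sample}_depth_change_{locus}")
        names.append(f"{sample}_depth_ratio_ab")
    for notation in NOTATIONS:
        names.append(f"notation_{notation}")
    return names


#: frozen, ordered manifest of the 70 covariates (contract: exactly 70)
FEATURE_MANIFEST: tuple[str, ...] = tuple(_build_manifest())
assert len(FEATURE_MANIFEST) == 70

FEATURE_MANIFEST_VERSION = "1"


@dataclass
class BreakpointFeatures:
    """The 70-covariate encoding consumed by the classifier."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_MANIFEST

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (70,):
            raise ValueError(f"expected 70 features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature value")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def encode_features(
    cluster: BreakpointCluster,
    coverage_tumor: Optional[CoverageTrack],
    coverage_normal: Optional[CoverageTrack] = None,
) -> BreakpointFeatures:
    """Deterministic 70-feature encoding of one cluster.

    When no normal sample is given, normal-derived covariates are 0 and the
    ``paired_mode`` flag feature is 0.
    """
    m = cluster.members
    mapqs = np.array([x.mapq for x in m], dtype=float)
    lengths = np.array([x.sv_length for x in m], dtype=float)
    starts = np.array([x.locus_a[1] for x in m], dtype=float)
    ends = np.array([x.locus_b[1] for x in m if x.locus_b is not None], dtype=float)
    if ends.size == 0:
        ends = starts

    ca, pa, _ = cluster.locus_a
    if cluster.locus_b is not None:
        cb, pb, _ = cluster.locus_b
    else:
        cb, pb = ca, pa

    dt_a = _depth_features(coverage_tumor, ca, pa)
    dt_b = _depth_features(coverage_tumor, cb, pb)
    dn_a = _depth_features(coverage_normal, ca, pa)
    dn_b = _depth_features(coverage_normal, cb, pb)

    ts, ns = cluster.tumor_support, cluster.normal_support
    hap_t = cluster.haplotype_support.get(TUMOR, {})
    hap_n = cluster.haplotype_support.get(NORMAL, {})
    hp1, hp2 = hap_t.get(1, 0), hap_t.get(2, 0)
    unphased = hap_t.get(UNPHASED, 0)
    kinds = [x.kind for x in m]
    normal_any = getattr(cluster, "normal_any_support", ns)

    def safe_af(support: float, d: dict) -> float:
        # reads supporting the junction end exactly at the breakend, so the
        # bin at the breakend itself can be depleted; the local maximum of
        # the flanking depths is the honest denominator
        depth = max(d["before"], d["at"], d["after"])
        return min(support / depth, 1.0) if depth > 0 else 0.0

    values = {
        "mapq_mean": mapqs.mean(),
        "mapq_std": mapqs.std(),
        "mapq_min": mapqs.min(),
        "mapq_max": mapqs.max(),
        "sv_length_mean": lengths.mean(),
        "sv_length_std": lengths.std(),
        "sv_length_median": float(np.median(lengths)),
        "sv_length_min": lengths.min(),
        "sv_length_max": lengths.max(),
        "start_std": starts.std(),
        "end_std": ends.std(),
        "start_mad": float(np.median(np.abs(starts - np.median(starts)))),
        "end_mad": float(np.median(np.abs(ends - np.median(ends)))),
        "span_a": starts.max() - starts.min(),
        "span_b": ends.max() - ends.min(),
        "locus_gap": abs(pb - pa) if ca == cb else 0.0,
        "n_members": len(m),
        "tumor_support": ts,
        "normal_support": ns,
        "tumor_af_a": safe_af(ts, dt_a),
        "tumor_af_b": safe_af(ts, dt_b),
        "normal_af_a": safe_af(ns, dn_a),
        "normal_af_b": safe_af(ns, dn_b),
        "insert_size": cluster.insert_size or 0,
        "insert_size_std": lengths.std() if cluster.notation == "INS" else 0.0,
        "tumor_hp1_support": hp1,
        "tumor_hp2_support": hp2,
        "tumor_unphased_support": unphased,
        "normal_hp1_support": hap_n.get(1, 0),
        "normal_hp2_support": hap_n.get(2, 0),
        "normal_unphased_support": hap_n.get(UNPHASED, 0),
        "unphased_fraction": unphased / ts if ts else 0.0,
        "hp_imbalance": abs(hp1 - hp2) / (hp1 + hp2 + 1),
        "normal_any_support": normal_any,
        "normal_any_af": safe_af(normal_any, dn_a),
        "frac_split": kinds.count("split") / len(m),
        "frac_cigar": (kinds.count("cigar_deletion") + kinds.count("cigar_insertion")) / len(m),
        "frac_softclip": kinds.count("softclip_sbnd") / len(m),
        "paired_mode": 1.0 if coverage_normal is not None else 0.0,
        "interchromosomal": 1.0 if cluster.interchromosomal else 0.0,
    }
    for sample, da, db in (("tumor", dt_a, dt_b), ("normal", dn_a, dn_b)):
        for locus, d in (("a", da), ("b", db)):
            for what in ("before", "at", "after"):
                values[f"{sample}_depth_{what}_{locus}"] = d[what]
            values[f"{sample}_depth_change_{locus}"] = d["after"] - d["before"]
        for hap in ("hp1", "hp2", "hp0"):
            values[f"{sample}_depth_{hap}_a"] = da[hap]
        values[f"{sample}_depth_ratio_ab"] = da["at"] / db["at"] if db["at"] > 0 else 0.0
    for notation in NOTATIONS:
        values[f"notation_{notation}"] = 1.0 if cluster.notation == notation else 0.0

    vec = np.array([values[name] for name in FEATURE_MANIFEST], dtype=float)
    feats = BreakpointFeatures(vec)
    cluster.allele_fraction = values["tumor_af_a"]
    return feats


def features_matrix(features: Sequence[BreakpointFeatures]) -> np.ndarray:
    return np.vstack([f.values for f in features])


# ---------------------------------------------------------------------------
# Training labels from matched short-read calls

def build_training_labels(
    clusters: Sequence[BreakpointCluster],
    features: Sequence[BreakpointFeatures],
    shortread_breakends: Iterable[Breakend],
    match_buffer: int = 100,
    paired_mode: bool = True,
) -> tuple[list[BreakpointCluster], list[BreakpointFeatures], list[str]]:
    """Label clusters somatic/noise against an orthogonal call set.

    A cluster matched within ``match_buffer`` of a short-read breakend is
    somatic.  Unmatched clusters are noise unless they look like genuine
    somatic events the short-read data missed (strong support, high AF, high
    MAPQ, tight coordinates, clean normal) — those are excluded from training
    altogether rather than mislabeled.
    """
    truth = list(shortread_breakends)
    kept_c: list[BreakpointCluster] = []
    kept_f: list[BreakpointFeatures] = []
    labels: list[str] = []
    for cluster, feats in zip(clusters, features):
        loci = [cluster.locus_a] + ([cluster.locus_b] if cluster.locus_b else [])
        matched = any(
            be.contig == c and abs(be.position - p) <= match_buffer
            for (c, p, _o) in loci
            for be in truth
        )
        if matched:
            kept_c.append(cluster)
            kept_f.append(feats)
            labels.append(SOMATIC)
            continue
        if _high_confidence_unmatched(cluster, feats, paired_mode):
            continue  # excluded from training
        kept_c.append(cluster)
        kept_f.append(feats)
        labels.append(NOISE)
    return kept_c, kept_f, labels


def _high_confidence_unmatched(cluster: BreakpointCluster, feats: BreakpointFeatures, paired_mode: bool) -> bool:
    s = cluster.stats
    if cluster.tumor_support < 6:
        return False
    if (cluster.allele_fraction or feats["tumor_af_a"]) <= 0.10:
        return False
    if s["mapq_mean"] < 50:
        return False
    length = s["sv_length_median"]
    coord_std = max(s["start_std"], s["end_std"])
    if length > 100:
        if coord_std >= 15:
            return False
    else:
        if coord_std >= 1.5 or s["sv_length_std"] >= 10:
            return False
    if paired_mode:
        normal_any = getattr(cluster, "normal_any_support", cluster.normal_support)
        if normal_any >= 2:
            return False
        if feats["normal_depth_at_a"] < 5:
            return False
    return True


# ---------------------------------------------------------------------------
# Random-forest classifier (sklearn estimator)

class SomaticBreakpointClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest somatic/noise classifier over the 70-feature encoding.

    Thin sklearn-style estimator around ``RandomForestClassifier`` with the
    defaults used by the caller (``max_depth=20``); the probability of the
    somatic class is the fraction of trees voting somatic, with ties broken
    toward noise (conservative calling).

    Parameters
    ----------
    max_depth : int
        Maximum tree depth.
    n_estimators : int
        Number of trees.
    test_fraction : float
        Held-out fraction for the internal train/test split (1/5 ~ the 4:1
        split) used to report ``holdout_auroc_``.
    random_state : int
        Seed; predictions are reproducible given the seed.
    """

    def __init__(self, max_depth: int = 20, n_estimators: int = 100, test_fraction: float = 0.2, random_state: int = 0):
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.test_fraction = test_fraction
        self.random_state = random_state

    def fit(self, X, y, groups: Optional[Sequence] = None) -> "SomaticBreakpointClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        if groups is not None:
            splitter = GroupShuffleSplit(n_splits=1, test_size=self.test_fraction, random_state=self.random_state)
            train_idx, test_idx = next(splitter.split(X, y, groups))
        else:
            train_idx, test_idx = train_test_split(
                np.arange(len(y)),
                test_size=self.test_fraction,
                random_state=self.random_state,
                stratify=y,
            )
        self.model_ = RandomForestClassifier(
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            random_state=self.random_state,
        )
        self.model_.fit(X[train_idx], y[train_idx])
        self.classes_ = self.model_.classes_
        proba = self.predict_proba(X[test_idx])[:, self._somatic_col()]
        y_test = (y[test_idx] == SOMATIC).astype(int)
        if y_test.min() != y_test.max():
            self.holdout_auroc_ = float(roc_auc_score(y_test, proba))
        else:
            self.holdout_auroc_ = float("nan")
        self.feature_manifest_ = FEATURE_MANIFEST
        self.manifest_version_ = FEATURE_MANIFEST_VERSION
        return self

    def _somatic_col(self) -> int:
        return int(np.where(self.classes_ == SOMATIC)[0][0])

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_MANIFEST):
            raise ValueError(f"expected {len(FEATURE_MANIFEST)} features, got shape {X.shape}")
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, self._somatic_col()]
        # tie (exactly half the trees) goes to noise
        return np.where(proba > 0.5, SOMATIC, NOISE)


def train_classifier(
    features: Sequence[BreakpointFeatures] | np.ndarray,
    labels: Sequence[str],
    max_depth: int = 20,
    seed: int = 0,
    groups: Optional[Sequence] = None,
) -> SomaticBreakpointClassifier:
    """Train the somatic/noise forest with a 4:1 train/test split (or
    leave-one-group-out when tumor-of-origin groups are given)."""
    X = features if isinstance(features, np.ndarray) else features_matrix(features)
    clf = SomaticBreakpointClassifier(max_depth=max_depth, random_state=seed)
    return clf.fit(X, np.asarray(labels), groups=groups)


# ---------------------------------------------------------------------------
# Mondrian conformal prediction

class MondrianConformalClassifier(BaseEstimator, ClassifierMixin):
    """Mondrian (class-conditional) inductive conformal predictor.

    The labeled data are split 70/30 into a proper training set (fits a random
    forest) and a calibration set.  The nonconformity score of an instance for
    class ``c`` is one minus the fraction of trees voting ``c``.  For a query,
    the p-value for each class is computed against that class's calibration
    scores; the prediction region at significance ``epsilon`` is the set of
    classes with p > epsilon ("both" when two, "null" when empty — the query
    is then an outlier relative to the calibration data).
    """

    def __init__(self, proper_train_fraction: float = 0.70, max_depth: int = 20, n_estimators: int = 100, random_state: int = 0):
        self.proper_train_fraction = proper_train_fraction
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y) -> "MondrianConformalClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("calibration requires both classes")
        idx_train, idx_cal = train_test_split(
            np.arange(len(y)),
            train_size=self.proper_train_fraction,
            random_state=self.random_state,
            stratify=y,
        )
        self.model_ = RandomForestClassifier(
            max_depth=self.max_depth, n_estimators=self.n_estimators, random_state=self.random_state
        )
        self.model_.fit(X[idx_train], y[idx_train])
        self.classes_ = self.model_.classes_
        proba_cal = self.model_.predict_proba(X[idx_cal])
        self.calibration_scores_ = {}
        for k, cls in enumerate(self.classes_):
            mask = y[idx_cal] == cls
            self.calibration_scores_[cls] = np.sort(1.0 - proba_cal[mask, k])
        return self

    def p_values(self, X) -> dict[str, np.ndarray]:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        proba = self.model_.predict_proba(X)
        out = {}
        for k, cls in enumerate(self.classes_):
            scores = 1.0 - proba[:, k]
            cal = self.calibration_scores_[cls]
            n_cal = len(cal)
            # count of calibration scores >= query score, via sorted search
            ge = n_cal - np.searchsorted(cal, scores, side="left")
            out[cls] = (ge + 1) / (n_cal + 1)
        return out

    def predict_region(self, X, epsilon: float = DEFAULT_EPSILON) -> list[str]:
        if not (0 < epsilon < 1):
            raise ValueError("epsilon must be in (0, 1)")
        pvals = self.p_values(X)
        n = len(next(iter(pvals.values())))
        regions = []
        for i in range(n):
            inside = [cls for cls in self.classes_ if pvals[cls][i] > epsilon]
            if len(inside) == 2:
                regions.append("both")
            elif len(inside) == 0:
                regions.append("null")
            else:
                regions.append(str(inside[0]))
        return regions

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))


def mcp_calibrate(features, labels, proper_train_fraction: float = 0.70, seed: int = 0) -> MondrianConformalClassifier:
    X = features if isinstance(features, np.ndarray) else features_matrix(features)
    mcp = MondrianConformalClassifier(proper_train_fraction=proper_train_fraction, random_state=seed)
    return mcp.fit(X, np.asarray(labels))


def mcp_predict(mcp: MondrianConformalClassifier, features, epsilon: float = DEFAULT_EPSILON):
    X = features if isinstance(features, np.ndarray) else features_matrix(features)
    pvals = mcp.p_values(X)
    regions = mcp.predict_region(X, epsilon)
    return regions, pvals


# ---------------------------------------------------------------------------
# Filtering, rescue, panels

@dataclass
class ClassifiedBreakpoint:
    cluster: BreakpointCluster
    class_label: str
    class_probability: float
    filter_status: str
    conformal_region: Optional[str] = None
    conformal_p_somatic: Optional[float] = None
    conformal_p_noise: Optional[float] = None
    rescued: bool = False


def classify_and_filter(
    model: SomaticBreakpointClassifier,
    clusters: Sequence[BreakpointCluster],
    features: Sequence[BreakpointFeatures],
    af_min: float = DEFAULT_AF_MIN,
    support_min: int = DEFAULT_SUPPORT_MIN,
    mcp: Optional[MondrianConformalClassifier] = None,
    epsilon: float = DEFAULT_EPSILON,
) -> list[ClassifiedBreakpoint]:
    """Predict each cluster and set FILTER with total, deterministic
    precedence: LIKELY_NOISE, then LOW_SUPPORT, then LOW_AF, then PASS."""
    if not clusters:
        return []
    X = features_matrix(features)
    proba = model.predict_proba(X)[:, model._somatic_col()]
    labels = model.predict(X)
    regions = pvals = None
    if mcp is not None:
        regions, pvals = mcp_predict(mcp, X, epsilon)
    out: list[ClassifiedBreakpoint] = []
    for i, (cluster, feats) in enumerate(zip(clusters, features)):
        label = str(labels[i])
        af = cluster.allele_fraction if cluster.allele_fraction is not None else feats["tumor_af_a"]
        if label == NOISE:
            status = LIKELY_NOISE
        elif cluster.tumor_support < support_min:
            status = LOW_SUPPORT
        elif af < af_min:
            status = LOW_AF
        else:
            status = PASS
        cb = ClassifiedBreakpoint(
            cluster=cluster,
            class_label=label,
            class_probability=float(proba[i]),
            filter_status=status,
        )
        if regions is not None:
            cb.conformal_region = regions[i]
            cb.conformal_p_somatic = float(pvals[SOMATIC][i])
            cb.conformal_p_noise = float(pvals[NOISE][i])
        cluster.class_label = label
        cluster.class_probability = float(proba[i])
        cluster.filter_status = status
        cluster.conformal_region = cb.conformal_region
        out.append(cb)
    return out


def rescue_by_changepoints(
    classified: Sequence[ClassifiedBreakpoint],
    changepoints: Iterable[tuple[str, int]],
    distance: int = 50,
    tumor_support_min: int = 3,
    normal_any_max: int = 3,
) -> list[ClassifiedBreakpoint]:
    """Rescue non-PASS clusters sitting at somatic copy-number changepoints.

    A changepoint in read depth independently corroborates a breakpoint, so a
    cluster within ``distance`` bp of one is set to PASS provided it has at
    least three tumor reads, no supporting normal reads and fewer than three
    normal reads clustering to the locus with any breakpoint type.
    """
    cps = list(changepoints)
    for cb in classified:
        if cb.filter_status == PASS:
            continue
        cluster = cb.cluster
        loci = [cluster.locus_a] + ([cluster.locus_b] if cluster.locus_b else [])
        near = any(c == contig and abs(p - pos) <= distance for (c, p, _o) in loci for contig, pos in cps)
        if not near:
            continue
        if cluster.tumor_support < tumor_support_min:
            continue
        if cluster.normal_support > 0:
            continue
        normal_any = getattr(cluster, "normal_any_support", cluster.normal_support)
        if normal_any >= normal_any_max:
            continue
        cb.filter_status = PASS
        cb.rescued = True
        cluster.filter_status = PASS
        cluster.rescued = True
        cluster.class_label = SOMATIC
    return list(classified)


def filter_germline_panels(
    clusters: Sequence[BreakpointCluster],
    population_svs: Iterable[tuple[Breakend, Optional[float]]] = (),
    pon_svs: Iterable[Breakend] = (),
    buffer: int = 100,
    af_threshold: float = 0.10,
) -> tuple[list[BreakpointCluster], list[BreakpointCluster]]:
    """Tumor-only germline removal against a population SV catalog (entries
    with population AF above ``af_threshold`` only) and a panel of normals.
    Returns (kept, removed-as-germline)."""
    panel: list[Breakend] = [be for be, af in population_svs if af is None or af > af_threshold]
    panel.extend(pon_svs)
    kept: list[BreakpointCluster] = []
    germline: list[BreakpointCluster] = []
    for cluster in clusters:
        loci = [cluster.locus_a] + ([cluster.locus_b] if cluster.locus_b else [])
        hit = any(
            be.contig == c and abs(be.position - p) <= buffer for (c, p, _o) in loci for be in panel
        )
        if hit:
            cluster.filter_status = "GERMLINE"
            germline.append(cluster)
        else:
            kept.append(cluster)
    return kept, germline


def annotate_normal_any_support(clusters: Sequence[BreakpointCluster], window: int = 50) -> None:
    """Count, per cluster, normal reads clustering to the locus supporting any
    breakpoint orientation or type (drives training-label and rescue gates)."""
    loci = []
    for cluster in clusters:
        for c, p, _o in [cluster.locus_a] + ([cluster.locus_b] if cluster.locus_b else []):
            for name in cluster.normal_read_names:
                loci.append((c, p, name))
    for cluster in clusters:
        names = set()
        for c, p, _o in [cluster.locus_a] + ([cluster.locus_b] if cluster.locus_b else []):
            for lc, lp, name in loci:
                if lc == c and abs(lp - p) <= window:
                    names.add(name)
        cluster.normal_any_support = len(names)
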