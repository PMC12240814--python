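"""Read-depth copy-number analysis: binning, normalization, segmentation.

The genome is tiled in non-overlapping 10-kbp bins (split further at PASS SV
breakends when available); primary alignments with MAPQ >= 5 are counted per
bin by alignment start.  Tumor counts are normalized against the matched
normal (or self-normalized by the median in tumor-only mode) and log2
transformed.  Single-point outliers are smoothed, the ratio scale is Anscombe
transformed to stabilize variance, and changepoints are found by circular
binary segmentation with a permutation test (1,000 permutations, find at
alpha 0.05, validate at 0.01).  Adjacent segments closer than the 20th
percentile of all pairwise segment-mean differences are merged to counter
oversegmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from svarcall.io_formats import GenomicInterval

DEFAULT_BIN_SIZE = 10_000
DEFAULT_BLACKLIST_MAX = 0.05
DEFAULT_N_MAX = 0.75
DEFAULT_ALPHA_FIND = 0.05
DEFAULT_ALPHA_VALIDATE = 0.01
DEFAULT_N_PERM = 1000
MERGE_PERCENTILE = 20.0


@dataclass
class CopyNumberBin:
    interval: GenomicInterval
    tumor_count: int = 0
    normal_count: Optional[int] = None
    log2r: Optional[float] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None  # blacklist | n_fraction | zero_count


@dataclass
class CopyNumberSegment:
    interval: GenomicInterval
    mean_log2r: float
    n_bins: int
    bin_indices: tuple[int, int] = (0, 0)  # half-open range into the retained-bin list
    absolute_cn: Optional[float] = None
    minor_cn: Optional[int] = None

    @property
    def size(self) -> int:
        return self.interval.end - self.interval.start


# ---------------------------------------------------------------------------
# Binning and counting

def build_bins(
    contig_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    breakpoints: Iterable[tuple[str, int]] = (),
) -> list[CopyNumberBin]:
    """Tile each contig with fixed bins; split any bin containing a somatic
    breakend at the breakend position so segments can land exactly on SVs."""
    splits: dict[str, list[int]] = {}
    for contig, pos in breakpoints:
        splits.setdefault(contig, []).append(pos)
    bins: list[CopyNumberBin] = []
    for contig, length in contig_lengths.items():
        edges = set(range(0, length, bin_size))
        edges.add(length)
        for pos in splits.get(contig, []):
            if 0 < pos < length:
                edges.add(pos)
        sorted_edges = sorted(edges)
        for start, end in zip(sorted_edges, sorted_edges[1:]):
            bins.append(CopyNumberBin(GenomicInterval(contig, start, end)))
    return bins


def filter_bins(
    bins: list[CopyNumberBin],
    blacklist: Sequence[GenomicInterval] = (),
    n_fraction_per_bin: Optional[dict[tuple[str, int, int], float]] = None,
    blacklist_max: float = DEFAULT_BLACKLIST_MAX,
    n_max: float = DEFAULT_N_MAX,
) -> list[CopyNumberBin]:
    """Mark bins overlapping blacklisted regions by more than ``blacklist_max``
    or composed of more than ``n_max`` N bases as excluded."""
    for b in bins:
        iv = b.interval
        size = iv.end - iv.start
        if size == 0:
            b.excluded, b.exclusion_reason = True, "zero_count"
            continue
        overlap = sum(iv.overlap(bl) for bl in blacklist)
        if overlap / size > blacklist_max:
            b.excluded, b.exclusion_reason = True, "blacklist"
            continue
        if n_fraction_per_bin is not None:
            nf = n_fraction_per_bin.get((iv.contig, iv.start, iv.end), 0.0)
            if nf > n_max:
                b.excluded, b.exclusion_reason = True, "n_fraction"
    return bins


def count_reads(
    bam_path: str,
    bins: list[CopyNumberBin],
    min_mapq: int = 5,
    which: str = "tumor",
) -> list[CopyNumberBin]:
    """Count primary alignments (MAPQ >= ``min_mapq``) per bin by alignment
    start; secondary and supplementary records are skipped."""
    edges: dict[str, np.ndarray] = {}
    index: dict[str, list[int]] = {}
    for i, b in enumerate(bins):
        index.setdefault(b.interval.contig, []).append(i)
    for contig, idxs in index.items():
        edges[contig] = np.array([bins[i].interval.start for i in idxs])
    counts = np.zeros(len(bins), dtype=np.int64)
    with pysam.AlignmentFile(bam_path) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            contig = rec.reference_name
            if contig not in edges:
                continue
            j = int(np.searchsorted(edges[contig], rec.reference_start, side="right")) - 1
            if j < 0:
                continue
            i = index[contig][j]
            if rec.reference_start < bins[i].interval.end:
                counts[i] += 1
    for i, b in enumerate(bins):
        if which == "tumor":
            b.tumor_count = int(counts[i])
        else:
            b.normal_count = int(counts[i])
    return bins


def normalize_log2(bins: list[CopyNumberBin], mode: str = "paired") -> list[CopyNumberBin]:
    """Compute per-bin log2 tumor/reference depth ratios.

    Paired mode scales by total depths so a diploid-neutral bin sits at 0;
    tumor-only mode self-normalizes by the median count over retained bins.
    Bins with no reads in any sample are excluded (reason ``zero_count``), as
    are paired bins with a zero normal count (the ratio would be infinite).
    """
    retained = [b for b in bins if not b.excluded]
    if mode == "paired":
        for b in retained:
            if (b.tumor_count or 0) == 0 and (b.normal_count or 0) == 0:
                b.excluded, b.exclusion_reason = True, "zero_count"
            elif (b.normal_count or 0) == 0:
                b.excluded, b.exclusion_reason = True, "zero_count"
        live = [b for b in retained if not b.excluded]
        total_t = sum(b.tumor_count for b in live)
        total_n = sum(b.normal_count for b in live)
        if total_t == 0:
            raise ValueError("no tumor reads in any retained bin")
        scale = total_n / total_t
        for b in live:
            ratio = (b.tumor_count / b.normal_count) * scale
            b.log2r = math.log2(ratio) if ratio > 0 else None
            if b.log2r is None:
                b.excluded, b.exclusion_reason = True, "zero_count"
    elif mode == "tumor_only":
        for b in retained:
            if (b.tumor_count or 0) == 0:
                b.excluded, b.exclusion_reason = True, "zero_count"
        live = [b for b in retained if not b.excluded]
        med = float(np.median([b.tumor_count for b in live])) if live else 0.0
        if med == 0:
            raise ValueError("median tumor count is zero")
        for b in live:
            b.log2r = math.log2(b.tumor_count / med)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bins


# ---------------------------------------------------------------------------
# Smoothing and variance stabilization

def smooth_outliers(series: np.ndarray, half_window: int = 2, mad_factor: float = 2.0) -> np.ndarray:
    """Replace single-point outliers by their local median.

    A point is smoothed iff it deviates from the median of its +/-2-bin
    neighborhood (the point excluded) by more than ``mad_factor`` times the
    series' median absolute deviation, both immediate neighbors lie strictly
    on the same side of it, and it differs from each immediate neighbor by
    more than the same threshold — a genuinely isolated spike.  Runs of two
    or more deviating points are left untouched, and so are the edge bins of
    real copy-number steps (one neighbor sits on the same level).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        return x.copy()
    mad = float(np.median(np.abs(x - np.median(x))))
    out = x.copy()
    for i in range(1, n - 1):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        neighborhood = np.concatenate([x[lo:i], x[i + 1 : hi]])
        med = float(np.median(neighborhood))
        if abs(x[i] - med) <= mad_factor * mad:
            continue
        if abs(x[i] - x[i - 1]) <= mad_factor * mad or abs(x[i] - x[i + 1]) <= mad_factor * mad:
            continue
        same_side = (x[i - 1] < x[i] and x[i + 1] < x[i]) or (x[i - 1] > x[i] and x[i + 1] > x[i])
        if same_side:
            out[i] = med
    return out


def variance_stabilize(log2r: np.ndarray) -> np.ndarray:
    """Anscombe transform on the ratio scale: A(r) = 2 sqrt(r + 3/8) with
    r = 2^log2R (the log scale can go below -3/8, the ratio scale cannot)."""
    r = np.power(2.0, np.asarray(log2r, dtype=float))
    return 2.0 * np.sqrt(r + 0.375)


# ---------------------------------------------------------------------------
# Circular binary segmentation

def max_arc_statistic(x: np.ndarray) -> tuple[float, int, int]:
    """Maximum standardized arc-sum deviation over all circular arcs.

    For an arc covering indices (i, j] (0 <= i < j <= n), the statistic is
    |S_j - S_i - k*mean| / (sd * sqrt(k (1 - k/n))) with k = j - i.  Returns
    (max statistic, i, j).  The denominator uses the segment-wide SD, which is
    permutation-invariant.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if n < 2 or sd == 0:
        return 0.0, 0, n
    S = np.concatenate([[0.0], np.cumsum(x)])
    mean = S[-1] / n
    best = -1.0
    for k in range(1, n):
        d = S[k:] - S[:-k] - k * mean  # arc sums minus expectation, all i
        denom = sd * math.sqrt(k * (1 - k / n))
        m = float(np.max(np.abs(d)) / denom)
        if m > best:
            best = m
    # ties (an arc and its complement score identically): take the
    # lexicographically smallest (i, j)
    bi, bj = 0, n
    found = False
    for i in range(n):
        if found:
            break
        for k in range(1, n - i if i else n):
            j = i + k
            if j > n or (i == 0 and j == n):
                continue
            denom = sd * math.sqrt(k * (1 - k / n))
            stat = abs(S[j] - S[i] - k * mean) / denom
            if stat >= best - 1e-12:
                bi, bj = i, j
                found = True
                break
    return best, bi, bj


def _perm_max_stats(x: np.ndarray, n_perm: int, rng: np.random.Generator, threshold_count: int, observed: float) -> tuple[int, int]:
    """Count permutations whose max arc statistic >= observed.

    Stops early (in blocks) once the count exceeds ``threshold_count`` — the
    split can no longer be significant, and the decision is unchanged.
    Returns (exceed_count, permutations_run).
    """
    n = len(x)
    sd = x.std()
    mean = x.mean()
    block = 100
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.empty((b, n))
        for r in range(b):
            perms[r] = rng.permutation(x)
        S = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
        maxima = np.zeros(b)
        for k in range(1, n):
            d = np.abs(S[:, k:] - S[:, :-k] - k * mean)
            denom = sd * math.sqrt(k * (1 - k / n))
            np.maximum(maxima, d.max(axis=1) / denom, out=maxima)
        exceed += int(np.sum(maxima >= observed - 1e-12))
        done += b
        if exceed > threshold_count:
            break
    return exceed, done


def _split_p_value(x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator) -> tuple[float, int, int]:
    obs, i, j = max_arc_statistic(x)
    if obs <= 0:
        return 1.0, i, j
    threshold_count = int(alpha * n_perm)
    exceed, done = _perm_max_stats(x, n_perm, rng, threshold_count, obs)
    if done < n_perm:
        # early-stopped: already known to be non-significant
        return max(exceed / done, alpha + 1e-9), i, j
    return exceed / n_perm, i, j


def cbs_segment(
    series: np.ndarray,
    alpha_find: float = DEFAULT_ALPHA_FIND,
    alpha_validate: float = DEFAULT_ALPHA_VALIDATE,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_width: int = 2,
) -> list[int]:
    """Circular binary segmentation changepoints of a 1-D series.

    Recursively splits each segment at the best circular arc whose permutation
    p-value is below ``alpha_find``; retained changepoints are then re-tested
    against their flanking segments at ``alpha_validate``.  Deterministic
    given (series, seed): each sub-segment derives its RNG from the run seed
    and the segment's offset.  Returns sorted interior changepoint indices t
    meaning a boundary between positions t-1 and t.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        return []
    changepoints: set[int] = set()

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        m = len(seg)
        if m < 2 * min_width:
            return
        rng = np.random.default_rng((seed, lo, hi))
        p, i, j = _split_p_value(seg, alpha_find, n_perm, rng)
        if p >= alpha_find:
            return
        # snap arc boundaries within min_width of the segment edge to the edge
        if i < min_width:
            i = 0
        if m - j < min_width:
            j = m
        if j - i < min_width:
            return
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:
            return
        for c in cuts:
            changepoints.add(c)
        bounds = [lo] + cuts + [hi]
        for a, b in zip(bounds, bounds[1:]):
            recurse(a, b)

    recurse(0, n)

    # validation: re-test each changepoint against its flanking segments and
    # prune iteratively — dropping one spurious changepoint widens its
    # neighbors' flanks, so they are re-tested against the updated segments
    cps = sorted(changepoints)
    while cps:
        bounds = [0] + cps + [n]
        worst_p, worst_idx = -1.0, None
        for idx, cp in enumerate(cps):
            lo, hi = bounds[idx], bounds[idx + 2]
            rng = np.random.default_rng((seed, 1_000_003, cp, len(cps)))
            p = _changepoint_p(x[lo:hi], cp - lo, alpha_validate, n_perm, rng)
            if p >= alpha_validate and p > worst_p:
                worst_p, worst_idx = p, idx
        if worst_idx is None:
            break
        del cps[worst_idx]
    return cps


def _changepoint_p(seg: np.ndarray, k: int, alpha: float, n_perm: int, rng: np.random.Generator) -> float:
    """Permutation p-value of the split at position ``k`` of ``seg``.

    The observed statistic is evaluated at the located split, but the null
    distribution is the permutation maximum over all linear splits — the
    split position was chosen by maximization, so the null must account for
    that selection or the validation would be anti-conservative.  Stops
    early once significance is excluded; the returned estimate is then a
    value above ``alpha``, which is all pruning needs.
    """
    m = len(seg)
    if k <= 0 or k >= m:
        return 1.0
    sd = seg.std()
    if sd == 0:
        return 1.0
    mean = seg.sum() / m
    ks = np.arange(1, m)
    denom = sd * np.sqrt(ks * (1 - ks / m))
    obs = abs(seg[:k].sum() - k * mean) / (sd * math.sqrt(k * (1 - k / m)))
    threshold_count = int(alpha * n_perm)
    exceed = 0
    done = 0
    block = 200
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.empty((b, m))
        for r in range(b):
            perms[r] = rng.permutation(seg)
        Sp = np.cumsum(perms, axis=1)
        stats = np.abs(Sp[:, :-1] - ks * mean) / denom
        exceed += int(np.sum(stats.max(axis=1) >= obs - 1e-12))
        done += b
        if exceed > threshold_count:
            break
    return exceed / done if done else 1.0


def segment_series(
    series: np.ndarray,
    alpha_find: float = DEFAULT_ALPHA_FIND,
    alpha_validate: float = DEFAULT_ALPHA_VALIDATE,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[int]:
    """CBS plus the over-segmentation merge, on a plain 1-D series.

    Returns the final interior changepoint indices after adjacent segments
    closer than the 20th percentile of all pairwise mean differences have
    been merged — the same two-stage procedure the genome pipeline applies.
    """
    x = np.asarray(series, dtype=float)
    cps = cbs_segment(x, alpha_find, alpha_validate, n_perm, seed=seed)
    if not cps:
        return []
    bounds = [0] + cps + [len(x)]
    segs = [
        CopyNumberSegment(
            interval=GenomicInterval("series", lo, hi),
            mean_log2r=float(x[lo:hi].mean()),
            n_bins=hi - lo,
            bin_indices=(lo, hi),
        )
        for lo, hi in zip(bounds, bounds[1:])
    ]
    merged = merge_segments(segs)
    return [s.interval.start for s in merged[1:]]


# ---------------------------------------------------------------------------
# Segment assembly and merging

def segments_from_changepoints(
    bins: Sequence[CopyNumberBin],
    changepoints_per_contig: dict[str, list[int]],
) -> list[CopyNumberSegment]:
    """Assemble segments from per-contig changepoints over the retained bins.

    Changepoint indices refer to positions within each contig's retained-bin
    list.  Segments exactly tile the retained bins.
    """
    segments: list[CopyNumberSegment] = []
    by_contig: dict[str, list[CopyNumberBin]] = {}
    for b in bins:
        if not b.excluded and b.log2r is not None:
            by_contig.setdefault(b.interval.contig, []).append(b)
    offset = 0
    for contig in by_contig:
        cbins = by_contig[contig]
        cps = sorted(changepoints_per_contig.get(contig, []))
        bounds = [0] + cps + [len(cbins)]
        for lo, hi in zip(bounds, bounds[1:]):
            if hi <= lo:
                continue
            part = cbins[lo:hi]
            segments.append(
                CopyNumberSegment(
                    interval=GenomicInterval(contig, part[0].interval.start, part[-1].interval.end),
                    mean_log2r=float(np.mean([b.log2r for b in part])),
                    n_bins=len(part),
                    bin_indices=(offset + lo, offset + hi),
                )
            )
        offset += len(cbins)
    return segments


def merge_segments(segments: list[CopyNumberSegment], bins: Optional[Sequence[CopyNumberBin]] = None) -> list[CopyNumberSegment]:
    """Merge adjacent same-contig segments whose mean-log2R difference falls
    below the 20th percentile of all pairwise segment differences genome-wide.

    The threshold is computed once from the input segmentation; merging then
    iterates (recomputing merged means from member bins when available) until
    no adjacent pair qualifies.  Exactly equal neighbors always merge.
    """
    if len(segments) < 2:
        return list(segments)
    means = np.array([s.mean_log2r for s in segments])
    diffs = np.abs(means[:, None] - means[None, :])
    pair_diffs = diffs[np.triu_indices(len(means), k=1)]
    threshold = float(np.percentile(pair_diffs, MERGE_PERCENTILE))

    retained = None
    if bins is not None:
        retained = [b for b in bins if not b.excluded and b.log2r is not None]

    segs = list(segments)
    merged = True
    while merged and len(segs) > 1:
        merged = False
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.interval.contig != b.interval.contig:
                continue
            delta = abs(a.mean_log2r - b.mean_log2r)
            if delta < threshold or delta == 0.0:
                lo, hi = a.bin_indices[0], b.bin_indices[1]
                if retained is not None:
                    mean = float(np.mean([x.log2r for x in retained[lo:hi]]))
                else:
                    mean = (a.mean_log2r * a.n_bins + b.mean_log2r * b.n_bins) / (a.n_bins + b.n_bins)
                segs[i] = CopyNumberSegment(
                    interval=GenomicInterval(a.interval.contig, a.interval.start, b.interval.end),
                    mean_log2r=mean,
                    n_bins=a.n_bins + b.n_bins,
                    bin_indices=(lo, hi),
                )
                del segs[i + 1]
                merged = True
                break
    return segs


# ---------------------------------------------------------------------------
# Whole-genome driver

@dataclass
class CopyNumberResult:
    bins: list[CopyNumberBin]
    segments: list[CopyNumberSegment]
    changepoints: list[tuple[str, int]]  # (contig, genomic position) boundaries


def run_copy_number(
    bins: list[CopyNumberBin],
    mode: str = "paired",
    alpha_find: float = DEFAULT_ALPHA_FIND,
    alpha_validate: float = DEFAULT_ALPHA_VALIDATE,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> CopyNumberResult:
    """Normalize counted bins, smooth, stabilize, segment and merge."""
    normalize_log2(bins, mode=mode)
    by_contig: dict[str, list[CopyNumberBin]] = {}
    for b in bins:
        if not b.excluded and b.log2r is not None:
            by_contig.setdefault(b.interval.contig, []).append(b)
    cps_per_contig: dict[str, list[int]] = {}
    genome_cps: list[tuple[str, int]] = []
    for ci, (contig, cbins) in enumerate(sorted(by_contig.items())):
        log2r = smooth_outliers(np.array([b.log2r for b in cbins]))
        for b, v in zip(cbins, log2r):
            b.log2r = float(v)
        transformed = variance_stabilize(log2r)
        cps = cbs_segment(transformed, alpha_find, alpha_validate, n_perm, seed=seed + ci)
        cps_per_contig[contig] = cps
        for cp in cps:
            genome_cps.append((contig, cbins[cp].interval.start))
    segments = segments_from_changepoints(bins, cps_per_contig)
    segments = merge_segments(segments, bins)
    # changepoints after merging: interior segment boundaries
    final_cps = []
    for a, b in zip(segments, segments[1:]):
        if a.interval.contig == b.interval.contig:
            final_cps.append((b.interval.contig, b.interval.start))
    return CopyNumberResult(bins=bins, segments=segments, changepoints=final_cps)
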