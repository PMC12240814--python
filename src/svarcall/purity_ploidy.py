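"""Tumor purity and ploidy inference from BAF and log2 depth ratios.

Purity is read off the B-allele-frequency split at regions of loss of
heterozygosity: in a CN-neutral LOH block, heterozygous SNPs separate into an
upper mode at BAF_A = 1 - (1-rho)/2 and a lower mode at BAF_B = (1-rho)/2, so
rho = 1 - 2*BAF_B.  Blocks are ranked by the bimodality coefficient of their
BAF distribution and the top ten eligible blocks are averaged:

    rho = (1/10) * sum_i [ (1 - 2(1 - med BAF_A_i)) + (1 - 2 med BAF_B_i) ] / 2

Ploidy is then fitted by grid search: for each (purity, ploidy) candidate the
absolute copy number of every segment is

    CN = ploidy + (2^log2R - 1) * (ploidy + 2/purity - 2)

and the goodness-of-fit is the segment-size-weighted deviation of CN from the
nearest integers (RMSD or MAD), with sanity flags on the fraction of
zero-copy genome, the fraction of near-integer segments, and the step between
the two most frequent states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from svarcall.copy_number import CopyNumberSegment
from svarcall.io_formats import GenomicInterval, SnpSite

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 1_200_000
DEFAULT_MIN_SNPS = 10
DEFAULT_TOP_K = 10
DEFAULT_PURITY_HALFWIDTH = 0.1
DEFAULT_PURITY_STEP = 0.01
DEFAULT_PLOIDY_MIN = 1.50
DEFAULT_PLOIDY_MAX = 5.00
DEFAULT_PLOIDY_STEP = 0.01
NEAR_INTEGER_TOL = 0.25
MAX_ZERO_PROPORTION = 0.1
MIN_CLOSE_PROPORTION = 0.5
MAX_STATE_STEP = 2


@dataclass
class SnpBafObservation:
    site: SnpSite
    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def baf(self) -> float:
        return self.alt_count / self.depth


@dataclass
class LohBlock:
    interval: GenomicInterval
    snp_count: int
    mean_depth: float
    bimodality: float
    median_baf_upper: float  # BAF_A
    median_baf_lower: float  # BAF_B


@dataclass
class PurityPloidyFit:
    purity: float
    ploidy: float
    fitness: float
    prop_zero_ok: bool = True
    prop_integer_ok: bool = True
    step_size_ok: bool = True

    @property
    def accepted(self) -> bool:
        return self.prop_zero_ok and self.prop_integer_ok and self.step_size_ok


# ---------------------------------------------------------------------------
# BAF computation

def compute_baf(
    snp_sites: Sequence[SnpSite],
    bam_path: str,
    min_depth: int = 1,
    min_mapq: int = 5,
) -> list[SnpBafObservation]:
    """Allele counts per heterozygous SNP from a pileup of primary alignments."""
    import pysam

    out: list[SnpBafObservation] = []
    with pysam.AlignmentFile(bam_path) as bam:
        refs = set(bam.references)
        for site in snp_sites:
            if site.contig not in refs:
                continue
            ref_n = alt_n = 0
            for col in bam.pileup(
                site.contig,
                site.position - 1,
                site.position,
                truncate=True,
                min_mapping_quality=min_mapq,
                ignore_overlaps=False,
            ):
                for read in col.pileups:
                    if read.is_del or read.is_refskip or read.query_position is None:
                        continue
                    if read.alignment.is_secondary or read.alignment.is_supplementary:
                        continue
                    base = read.alignment.query_sequence[read.query_position].upper()
                    if base == site.ref_allele.upper():
                        ref_n += 1
                    elif base == site.alt_allele.upper():
                        alt_n += 1
            if ref_n + alt_n >= max(min_depth, 1):
                out.append(SnpBafObservation(site, ref_n, alt_n))
    return out


def baf_observations_from_table(rows: Iterable[tuple[str, int, int, int]]) -> list[SnpBafObservation]:
    """Build observations from (contig, 1-based pos, ref_count, alt_count)."""
    out = []
    for contig, pos, ref_n, alt_n in rows:
        if ref_n + alt_n > 0:
            out.append(SnpBafObservation(SnpSite(contig, pos, "A", "B"), ref_n, alt_n))
    return out


# ---------------------------------------------------------------------------
# Bimodality and block selection

def bimodality_coefficient(values: Sequence[float]) -> Optional[float]:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3)))
    with g1 the sample skewness and g2 the excess kurtosis; > 5/9 suggests
    bimodality.  None for degenerate samples (n < 4 or zero variance)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return None
    g1 = float(sps.skew(x, bias=False))
    g2 = float(sps.kurtosis(x, bias=False))
    denom = g2 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    if denom == 0:
        return None
    return (g1 ** 2 + 1) / denom


def select_loh_blocks(
    observations: Sequence[SnpBafObservation],
    contig_lengths: dict[str, int],
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_snps: int = DEFAULT_MIN_SNPS,
    depth_cap_factor: float = 2.0,
    top_k: int = DEFAULT_TOP_K,
) -> list[LohBlock]:
    """Rank fixed genomic blocks by BAF bimodality and return the top ``top_k``.

    Blocks with fewer than ``min_snps`` heterozygous SNPs are ineligible, as
    are blocks whose mean depth exceeds ``depth_cap_factor`` times the
    genome-wide mean (amplified regions would bias the BAF split).  Mode
    medians are taken on either side of BAF 0.5.
    """
    if not observations:
        return []
    genome_mean_depth = float(np.mean([o.depth for o in observations]))
    blocks: dict[tuple[str, int], list[SnpBafObservation]] = {}
    for o in observations:
        key = (o.site.contig, (o.site.position - 1) // block_size)
        blocks.setdefault(key, []).append(o)
    candidates: list[LohBlock] = []
    for (contig, idx), obs in sorted(blocks.items()):
        if len(obs) < min_snps:
            continue
        mean_depth = float(np.mean([o.depth for o in obs]))
        if mean_depth > depth_cap_factor * genome_mean_depth:
            continue
        bafs = np.array([o.baf for o in obs])
        b = bimodality_coefficient(bafs)
        if b is None:
            continue
        upper = bafs[bafs >= 0.5]
        lower = bafs[bafs < 0.5]
        if upper.size == 0 or lower.size == 0:
            continue
        start = idx * block_size
        end = min(start + block_size, contig_lengths.get(contig, start + block_size))
        candidates.append(
            LohBlock(
                interval=GenomicInterval(contig, start, end),
                snp_count=len(obs),
                mean_depth=mean_depth,
                bimodality=b,
                median_baf_upper=float(np.median(upper)),
                median_baf_lower=float(np.median(lower)),
            )
        )
    candidates.sort(key=lambda blk: (-blk.bimodality, blk.interval))
    return candidates[:top_k]


def estimate_purity(blocks: Sequence[LohBlock]) -> float:
    """Average the per-block purity implied by the LOH BAF split.

    Each block contributes [(1 - 2(1 - BAF_A)) + (1 - 2 BAF_B)] / 2; blocks
    fewer than ten are averaged over what exists (with a warning).
    """
    if not blocks:
        raise ValueError("no eligible LOH blocks; supply purity manually")
    if len(blocks) < DEFAULT_TOP_K:
        logger.warning("only %d eligible LOH blocks (10 expected); averaging over them", len(blocks))
    terms = [
        ((1 - 2 * (1 - blk.median_baf_upper)) + (1 - 2 * blk.median_baf_lower)) / 2
        for blk in blocks
    ]
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# Absolute copy number and ploidy grid search

def absolute_copy_number(log2r: float | np.ndarray, purity: float, ploidy: float) -> float | np.ndarray:
    """CN = ploidy + (2^log2R - 1) * (ploidy + 2/purity - 2)."""
    r = np.power(2.0, log2r)
    cn = ploidy + (r - 1) * (ploidy + 2.0 / purity - 2.0)
    if np.isscalar(log2r):
        return float(cn)
    return cn


def _evaluate_grid_point(
    cn: np.ndarray, weights: np.ndarray, metric: str
) -> tuple[float, bool, bool, bool]:
    nearest = np.round(cn)
    dev = np.abs(cn - nearest)
    if metric == "rmsd":
        fitness = float(np.sqrt(np.sum(weights * dev ** 2) / np.sum(weights)))
    elif metric == "mad":
        fitness = float(np.sum(weights * dev) / np.sum(weights))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    wnorm = weights / weights.sum()
    prop_zero = float(np.sum(wnorm[nearest <= 0]))
    prop_close = float(np.mean(dev < NEAR_INTEGER_TOL))
    states, state_w = np.unique(nearest, return_counts=False), None
    # two most frequent states by total segment size
    sizes: dict[float, float] = {}
    for s, w in zip(nearest, weights):
        sizes[float(s)] = sizes.get(float(s), 0.0) + float(w)
    ranked = sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) >= 2:
        step = abs(ranked[0][0] - ranked[1][0])
        step_ok = step < MAX_STATE_STEP
    else:
        step_ok = True
    return fitness, prop_zero < MAX_ZERO_PROPORTION, prop_close > MIN_CLOSE_PROPORTION, step_ok


def grid_search(
    segments: Sequence[CopyNumberSegment],
    purity_hat: float,
    purity_halfwidth: float = DEFAULT_PURITY_HALFWIDTH,
    purity_step: float = DEFAULT_PURITY_STEP,
    ploidy_min: float = DEFAULT_PLOIDY_MIN,
    ploidy_max: float = DEFAULT_PLOIDY_MAX,
    ploidy_step: float = DEFAULT_PLOIDY_STEP,
    metric: str = "rmsd",
    tie_margin: float = 0.02,
) -> tuple[PurityPloidyFit, list[PurityPloidyFit]]:
    """Fit (purity, ploidy) on a grid around the BAF-derived purity estimate.

    Grid points failing any acceptance flag are discarded.  Among the rest,
    all points whose fitness lies within ``tie_margin`` of the minimum are
    treated as equivalent (whole-genome +1 shifts of the copy-number scale
    fit the integers essentially as well as the truth); the most parsimonious
    of them wins — lowest ploidy, then purity nearest the BAF estimate.
    Raises when every point is rejected.
    """
    log2r = np.array([s.mean_log2r for s in segments])
    weights = np.array([s.size for s in segments], dtype=float)
    if log2r.size == 0:
        raise ValueError("no segments to fit")
    n_p = int(round(2 * purity_halfwidth / purity_step)) + 1
    purities = np.round(purity_hat - purity_halfwidth + purity_step * np.arange(n_p), 10)
    purities = purities[(purities > 0) & (purities <= 1)]
    n_q = int(round((ploidy_max - ploidy_min) / ploidy_step)) + 1
    ploidies = np.round(ploidy_min + ploidy_step * np.arange(n_q), 10)
    grid: list[PurityPloidyFit] = []
    for rho in purities:
        for psi in ploidies:
            cn = absolute_copy_number(log2r, float(rho), float(psi))
            fitness, zero_ok, close_ok, step_ok = _evaluate_grid_point(cn, weights, metric)
            grid.append(
                PurityPloidyFit(
                    purity=float(rho),
                    ploidy=float(psi),
                    fitness=fitness,
                    prop_zero_ok=zero_ok,
                    prop_integer_ok=close_ok,
                    step_size_ok=step_ok,
                )
            )
    accepted = [g for g in grid if g.accepted]
    if not accepted:
        raise ValueError("no purity-ploidy combination passed the acceptance flags; supply purity/ploidy manually")
    f_min = min(g.fitness for g in accepted)
    near = [g for g in accepted if g.fitness <= f_min + tie_margin]
    # near-equivalent fits form basins around integer-consistent solutions
    # roughly one ploidy unit apart; keep the lowest-ploidy basin, then take
    # its best-fitting point
    p_min = min(g.ploidy for g in near)
    basin = [g for g in near if g.ploidy <= p_min + 0.25]
    best = min(basin, key=lambda g: (g.fitness, abs(g.purity - purity_hat), g.ploidy))
    return best, grid


# ---------------------------------------------------------------------------
# Allele-specific copy number

def allele_specific_cn(
    segments: Sequence[CopyNumberSegment],
    baf_per_segment: Sequence[Optional[float]],
    purity: float,
    min_total_cn: float = 0.0,
) -> list[CopyNumberSegment]:
    """Minor copy number per segment from the mirrored median BAF.

    With b the median BAF folded to <= 0.5 and n_T the (rounded) total copy
    number, the BAF mixture model b = (rho n_B + (1-rho)) / (rho n_T + 2(1-rho))
    inverts to n_B = (b (rho n_T + 2(1-rho)) - (1-rho)) / rho, rounded and
    clamped to [0, floor(n_T / 2)].
    """
    out = []
    for seg, baf in zip(segments, baf_per_segment):
        if seg.absolute_cn is None or baf is None:
            out.append(seg)
            continue
        b = min(baf, 1.0 - baf)
        n_t = max(round(seg.absolute_cn), 0)
        if purity <= 0:
            raise ValueError("purity must be positive")
        n_b = (b * (purity * n_t + 2 * (1 - purity)) - (1 - purity)) / purity
        n_b = int(round(n_b))
        seg.minor_cn = max(0, min(n_b, n_t // 2))
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# Driver

@dataclass
class PurityPloidyResult:
    purity_baf: float
    fit: PurityPloidyFit
    grid: list[PurityPloidyFit]
    blocks: list[LohBlock]
    segments: list[CopyNumberSegment]


def fit_purity_ploidy(
    segments: Sequence[CopyNumberSegment],
    baf_observations: Sequence[SnpBafObservation],
    contig_lengths: dict[str, int],
    block_size: int = DEFAULT_BLOCK_SIZE,
    metric: str = "rmsd",
    baf_per_segment: Optional[Sequence[Optional[float]]] = None,
) -> PurityPloidyResult:
    """Estimate purity from LOH BAF, fit ploidy by grid search, and annotate
    segments with absolute (and, when BAF is supplied, minor) copy number."""
    blocks = select_loh_blocks(baf_observations, contig_lengths, block_size=block_size)
    purity_baf = estimate_purity(blocks)
    best, grid = grid_search(segments, purity_baf, metric=metric)
    for seg in segments:
        seg.absolute_cn = float(absolute_copy_number(seg.mean_log2r, best.purity, best.ploidy))
    if baf_per_segment is None:
        baf_per_segment = _segment_bafs(segments, baf_observations)
    allele_specific_cn(segments, baf_per_segment, best.purity)
    return PurityPloidyResult(purity_baf, best, grid, blocks, list(segments))


def _segment_bafs(
    segments: Sequence[CopyNumberSegment],
    observations: Sequence[SnpBafObservation],
    min_snps: int = 5,
) -> list[Optional[float]]:
    out: list[Optional[float]] = []
    for seg in segments:
        iv = seg.interval
        vals = [
            o.baf
            for o in observations
            if o.site.contig == iv.contig and iv.start < o.site.position <= iv.end
        ]
        if len(vals) < min_snps:
            out.append(None)
        else:
            mirrored = [min(v, 1 - v) for v in vals]
            out.append(float(np.median(mirrored)))
    return out
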