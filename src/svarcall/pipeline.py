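"""End-to-end orchestration of the paired and tumor-only pipelines.

discovery -> clustering -> feature encoding -> classification (+ conformal
regions) -> copy number -> purity/ploidy -> changepoint rescue -> final VCF.
The rescue loop runs exactly once.  All stages are seeded; rerunning with the
same inputs and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from svarcall import classify as cls
from svarcall import clustering, copy_number as cn, discovery, purity_ploidy as pp
from svarcall.io_formats import NORMAL, TUMOR, GenomicInterval, write_breakpoint_vcf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    tumor_bam: str
    normal_bam: Optional[str] = None
    out_dir: str = "."
    mode: str = "paired"  # or "tumor_only"
    seed: int = 0
    min_mapq: float = 5
    min_sv_length: int = 30
    af_min: float = cls.DEFAULT_AF_MIN
    support_min: int = cls.DEFAULT_SUPPORT_MIN
    epsilon: float = cls.DEFAULT_EPSILON
    cn_bin_size: int = cn.DEFAULT_BIN_SIZE
    n_perm: int = cn.DEFAULT_N_PERM
    loh_block_size: int = pp.DEFAULT_BLOCK_SIZE
    coverage_bin_size: int = discovery.DEFAULT_COVERAGE_BIN

    def __post_init__(self) -> None:
        if self.mode == "paired" and self.normal_bam is None:
            raise ValueError("paired mode requires a normal alignment file")


@dataclass
class PipelineResult:
    clusters: list
    classified: list
    pass_clusters: list
    cn_result: Optional[cn.CopyNumberResult] = None
    purity_ploidy: Optional[pp.PurityPloidyResult] = None
    vcf_path: Optional[str] = None
    manifest: dict = field(default_factory=dict)


def _contig_lengths(bam_path: str) -> dict[str, int]:
    with pysam.AlignmentFile(bam_path) as bam:
        return dict(zip(bam.references, bam.lengths))


def bins_from_table(df: pd.DataFrame) -> list[cn.CopyNumberBin]:
    """CopyNumberBin list from a (contig, start, end, tumor_count[, normal_count]) table."""
    bins = []
    has_normal = "normal_count" in df.columns
    for row in df.itertuples(index=False):
        bins.append(
            cn.CopyNumberBin(
                interval=GenomicInterval(row.contig, int(row.start), int(row.end)),
                tumor_count=int(row.tumor_count),
                normal_count=int(row.normal_count) if has_normal else None,
            )
        )
    return bins


def call_svs(
    config: RunConfig,
    model: cls.SomaticBreakpointClassifier,
    mcp: Optional[cls.MondrianConformalClassifier] = None,
) -> tuple[list, list, discovery.CoverageTrack, Optional[discovery.CoverageTrack]]:
    """Discovery + clustering + classification for one tumor(/normal) pair."""
    contigs = _contig_lengths(config.tumor_bam)
    t0 = time.monotonic()
    disc_t = discovery.discover_sample(
        config.tumor_bam,
        TUMOR,
        contigs,
        min_mapq=config.min_mapq,
        min_sv_length=config.min_sv_length,
        coverage_bin_size=config.coverage_bin_size,
    )
    breakpoints = list(disc_t.breakpoints)
    coverage_n = None
    if config.normal_bam is not None:
        disc_n = discovery.discover_sample(
            config.normal_bam,
            NORMAL,
            contigs,
            min_mapq=config.min_mapq,
            min_sv_length=config.min_sv_length,
            coverage_bin_size=config.coverage_bin_size,
        )
        breakpoints.extend(disc_n.breakpoints)
        coverage_n = disc_n.coverage
    logger.info("discovery: %d putative breakpoints (%.1fs)", len(breakpoints), time.monotonic() - t0)

    clusters = clustering.cluster_breakpoints(breakpoints)
    # tumor-supported clusters only are candidates; normal-only clusters are
    # germline evidence consumed via co-clustering
    candidates = [c for c in clusters if c.tumor_support > 0]
    cls.annotate_normal_any_support(clusters)
    features = [cls.encode_features(c, disc_t.coverage, coverage_n) for c in candidates]
    classified = cls.classify_and_filter(
        model,
        candidates,
        features,
        af_min=config.af_min,
        support_min=config.support_min,
        mcp=mcp,
        epsilon=config.epsilon,
    )
    return candidates, classified, disc_t.coverage, coverage_n


def run_pipeline(
    config: RunConfig,
    model: cls.SomaticBreakpointClassifier,
    mcp: Optional[cls.MondrianConformalClassifier] = None,
    cn_bins: Optional[Sequence[cn.CopyNumberBin]] = None,
    baf_observations: Optional[Sequence[pp.SnpBafObservation]] = None,
    population_svs=(),
    pon_svs=(),
) -> PipelineResult:
    """Run the full caller.

    ``cn_bins`` may be precomputed (counted) bins; otherwise bins are built
    from the contig table and counted from the alignment files.
    ``baf_observations`` likewise bypasses the pileup when provided.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    contigs = _contig_lengths(config.tumor_bam)
    candidates, classified, cov_t, cov_n = call_svs(config, model, mcp)

    if config.mode == "tumor_only" and (population_svs or pon_svs):
        kept, germline = cls.filter_germline_panels(
            [cb.cluster for cb in classified], population_svs, pon_svs
        )
        keep_ids = {id(c) for c in kept}
        classified = [cb for cb in classified if id(cb.cluster) in keep_ids]

    pass_breakends = []
    for cb in classified:
        if cb.filter_status == cls.PASS:
            pass_breakends.append((cb.cluster.locus_a[0], cb.cluster.locus_a[1]))
            if cb.cluster.locus_b is not None:
                pass_breakends.append((cb.cluster.locus_b[0], cb.cluster.locus_b[1]))

    cn_result = None
    pp_result = None
    if cn_bins is None:
        bins = cn.build_bins(contigs, bin_size=config.cn_bin_size, breakpoints=pass_breakends)
        cn.count_reads(config.tumor_bam, bins, which="tumor")
        if config.normal_bam is not None:
            cn.count_reads(config.normal_bam, bins, which="normal")
    else:
        bins = list(cn_bins)
    try:
        mode = "paired" if (config.normal_bam is not None and bins and bins[0].normal_count is not None) else "tumor_only"
        cn_result = cn.run_copy_number(bins, mode=mode, n_perm=config.n_perm, seed=config.seed)
    except ValueError as exc:
        logger.warning("copy-number stage skipped: %s", exc)

    if cn_result is not None and baf_observations:
        try:
            pp_result = pp.fit_purity_ploidy(
                cn_result.segments,
                baf_observations,
                contigs,
                block_size=config.loh_block_size,
            )
        except ValueError as exc:
            logger.warning("purity/ploidy stage skipped: %s", exc)

    if cn_result is not None:
        cls.rescue_by_changepoints(classified, cn_result.changepoints)

    vcf_path = os.path.join(config.out_dir, "breakpoints.vcf")
    write_breakpoint_vcf([cb.cluster for cb in classified], vcf_path, contigs)
    _write_tables(config.out_dir, cn_result, pp_result)

    manifest = dict(
        seed=config.seed,
        mode=config.mode,
        n_candidates=len(candidates),
        n_pass=sum(1 for cb in classified if cb.filter_status == cls.PASS),
        n_rescued=sum(1 for cb in classified if cb.rescued),
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(
        clusters=candidates,
        classified=classified,
        pass_clusters=[cb.cluster for cb in classified if cb.filter_status == cls.PASS],
        cn_result=cn_result,
        purity_ploidy=pp_result,
        vcf_path=vcf_path,
        manifest=manifest,
    )


def train_on_simulated(seed: int = 0, tmp_dir: Optional[str] = None):
    """Train the somatic classifier and conformal predictor on a simulated
    labeled cohort (true SVs plus injected noise).  Returns (model, mcp)."""
    import tempfile

    from svarcall.simulate import simulate_sv_alignments, training_config

    tmp_dir = tmp_dir or tempfile.mkdtemp(prefix="svarcall_train_")
    tcfg = training_config(seed)
    res = simulate_sv_alignments(tcfg, tmp_dir)
    disc_t = discovery.discover_sample(res["paths"]["tumor"], TUMOR, tcfg.contigs)
    disc_n = discovery.discover_sample(res["paths"]["normal"], NORMAL, tcfg.contigs)
    clusters = clustering.cluster_breakpoints(disc_t.breakpoints + disc_n.breakpoints)
    candidates = [c for c in clusters if c.tumor_support > 0]
    cls.annotate_normal_any_support(clusters)
    features = [cls.encode_features(c, disc_t.coverage, disc_n.coverage) for c in candidates]
    _, kept_features, labels = cls.build_training_labels(
        candidates, features, res["truth_breakends"]
    )
    model = cls.train_classifier(kept_features, labels, seed=seed)
    mcp = cls.mcp_calibrate(kept_features, labels, seed=seed)
    return model, mcp


def _write_tables(out_dir: str, cn_result, pp_result) -> None:
    if cn_result is not None:
        rows = [
            (
                b.interval.contig,
                b.interval.start,
                b.interval.end,
                b.tumor_count,
                b.normal_count if b.normal_count is not None else "",
                f"{b.log2r:.6f}" if b.log2r is not None else "",
                b.exclusion_reason or "",
            )
            for b in cn_result.bins
        ]
        pd.DataFrame(
            rows, columns=["contig", "start", "end", "tumor_count", "normal_count", "log2r", "excluded_reason"]
        ).to_csv(os.path.join(out_dir, "cn_bins.tsv"), sep="\t", index=False)
        seg_rows = [
            (
                s.interval.contig,
                s.interval.start,
                s.interval.end,
                s.n_bins,
                f"{s.mean_log2r:.6f}",
                f"{s.absolute_cn:.4f}" if s.absolute_cn is not None else "",
                s.minor_cn if s.minor_cn is not None else "",
            )
            for s in cn_result.segments
        ]
        pd.DataFrame(
            seg_rows, columns=["contig", "start", "end", "n_bins", "mean_log2r", "absolute_cn", "minor_cn"]
        ).to_csv(os.path.join(out_dir, "cn_segments.tsv"), sep="\t", index=False)
    if pp_result is not None:
        with open(os.path.join(out_dir, "purity_ploidy.json"), "w") as fh:
            json.dump(
                dict(
                    purity_baf=pp_result.purity_baf,
                    purity=pp_result.fit.purity,
                    ploidy=pp_result.fit.ploidy,
                    fitness=pp_result.fit.fitness,
                ),
                fh,
                indent=2,
            )
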