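"""Seeded synthetic inputs: toy genomes, SV-bearing alignments, CN/BAF tables.

Alignments are synthesized directly as coordinate-level records (CIGAR plus SA
tags) rather than by simulating and re-aligning bases: the caller consumes
alignment geometry, not base-level signal, so fixtures stay desk-scale while
exercising every evidence channel — split reads, gapped alignments, long soft
clips, fold-back artifacts, haplotype tags.

Copy-number and BAF tables invert the model the inference assumes: a bin in a
segment of total copy number CN has expected depth ratio
r = (rho*CN + 2(1-rho)) / (rho*psi + 2(1-rho)) with lognormal noise, and a
heterozygous SNP on a segment with (n_T, n_B) draws its alternate-allele count
from Binomial(depth, (rho*n_B + (1-rho)) / (rho*n_T + 2(1-rho))), with the
B allele placed on either parental haplotype at random.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from svarcall.io_formats import Breakend, sort_and_index_bam

BASES = np.array(list("ACGT"))


@dataclass
class SvSpec:
    """One planted SV: type, locus, geometry, target allele fraction."""

    kind: str  # del_cigar | del_split | del_merged | dup | inv_pp | inv_mm | tra | ins | sbnd
    contig: str
    position: int
    length: int = 0
    contig2: Optional[str] = None  # translocations
    position2: Optional[int] = None
    af: float = 0.5
    germline: bool = False
    haplotype: int = 1

    def breakends(self) -> list[Breakend]:
        p, L = self.position, self.length
        if self.kind in ("del_cigar", "del_split", "del_merged"):
            return [Breakend(self.contig, p, "+"), Breakend(self.contig, p + L, "-")]
        if self.kind == "dup":
            return [Breakend(self.contig, p, "-"), Breakend(self.contig, p + L, "+")]
        if self.kind == "inv_pp":
            return [Breakend(self.contig, p, "+"), Breakend(self.contig, p + L, "+")]
        if self.kind == "inv_mm":
            return [Breakend(self.contig, p, "-"), Breakend(self.contig, p + L, "-")]
        if self.kind == "tra":
            return [Breakend(self.contig, p, "+"), Breakend(self.contig2, self.position2, "-")]
        if self.kind == "ins":
            return [Breakend(self.contig, p, "+", "INS")]
        if self.kind == "sbnd":
            return [Breakend(self.contig, p, "-", "SBND")]
        raise ValueError(f"unknown SV kind {self.kind!r}")


@dataclass
class CnSegmentSpec:
    contig: str
    start: int
    end: int
    total_cn: int
    minor_cn: int


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: dict = field(default_factory=lambda: {"chr1": 1_200_000, "chr2": 1_200_000})
    sv_list: list = field(default_factory=list)
    depth: int = 30
    read_length: tuple = (8_000, 12_000)
    unphased_fraction: float = 0.1
    foldback_count: int = 0
    noise_loci: int = 0  # scattered low-support, low-MAPQ junction artifacts
    microsatellite_loci: int = 0  # clustered near-threshold indel noise
    cn_profile: list = field(default_factory=list)
    purity: float = 0.6
    snp_spacing: int = 800  # bp between heterozygous SNPs
    snp_depth: int = 30
    cn_bin_size: int = 10_000
    cn_base_depth: int = 400  # expected reads per bin in the normal
    log2r_noise_sd: float = 0.1

    @property
    def ploidy(self) -> float:
        if not self.cn_profile:
            return 2.0
        sizes = np.array([s.end - s.start for s in self.cn_profile], dtype=float)
        cns = np.array([s.total_cn for s in self.cn_profile], dtype=float)
        return float(np.sum(sizes * cns) / np.sum(sizes))


# ---------------------------------------------------------------------------
# Alignment simulation

_CARRIER_FLANK = 400  # junction must sit this far inside a carrier read


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _sa_entry(contig: str, pos0: int, strand: str, cigar: str, mapq: int) -> str:
    return f"{contig},{pos0 + 1},{strand},{cigar},{mapq},0;"


class _Read:
    __slots__ = ("name", "contig", "start", "length", "haplotype", "records")

    def __init__(self, name, contig, start, length, haplotype):
        self.name = name
        self.contig = contig
        self.start = start
        self.length = length
        self.haplotype = haplotype
        self.records: list[dict] = []


def _plain_record(read: _Read, mapq: int = 60) -> dict:
    return dict(
        contig=read.contig,
        pos=read.start,
        strand="+",
        cigar=f"{read.length}M",
        mapq=mapq,
        supplementary=False,
        seq=None,
    )


def _carrier_records(read: _Read, sv: SvSpec, rng: np.random.Generator, mapq: int = 60) -> list[dict]:
    """Alignment records representing ``read`` crossing the SV junction."""
    p = sv.position
    L = sv.length
    if sv.kind in ("del_cigar", "del_merged", "ins"):
        # gapped representation: the read spans the whole event
        a = p - read.start
        b = read.length - a
        if sv.kind == "del_cigar":
            return [dict(contig=read.contig, pos=read.start, strand="+", cigar=f"{a}M{L}D{b}M", mapq=mapq, supplementary=False, seq=None)]
        if sv.kind == "del_merged":
            # two deletion ops separated by a short matched stretch (< 30 bp)
            gap = 20
            l1 = L // 2
            l2 = L - l1
            return [dict(contig=read.contig, pos=read.start, strand="+", cigar=f"{a}M{l1}D{gap}M{l2}D{b - gap}M", mapq=mapq, supplementary=False, seq=None)]
        seq = _random_seq(rng, read.length)
        return [dict(contig=read.contig, pos=read.start, strand="+", cigar=f"{a}M{L}I{b - L}M", mapq=mapq, supplementary=False, seq=seq)]
    if sv.kind == "sbnd":
        clip = 1100 + (L or 0)
        m = read.length - clip
        if m < 50:
            return [_plain_record(read)]
        seq = _random_seq(rng, read.length)
        return [dict(contig=read.contig, pos=p, strand="+", cigar=f"{clip}S{m}M", mapq=mapq, supplementary=False, seq=seq)]
    # split-read kinds: junction in the middle of the read, primary covers the
    # first half in query order, the supplementary the second half
    a = read.length // 2
    b = read.length - a
    if sv.kind == "del_split":
        prim = dict(contig=read.contig, pos=p - a, strand="+", cigar=f"{a}M{b}S", mapq=mapq, supplementary=False, seq=None)
        supp = dict(contig=read.contig, pos=p + L, strand="+", cigar=f"{a}S{b}M", mapq=mapq, supplementary=True, seq=None)
    elif sv.kind == "dup":
        # read crosses the tandem junction from the end of the duplicated
        # unit back to its start: breakends (- +) at (p, p+L)
        prim = dict(contig=read.contig, pos=p + L - a, strand="+", cigar=f"{a}M{b}S", mapq=mapq, supplementary=False, seq=None)
        supp = dict(contig=read.contig, pos=p, strand="+", cigar=f"{a}S{b}M", mapq=mapq, supplementary=True, seq=None)
    elif sv.kind == "inv_pp":
        # (+ +): forward into the junction at p, reverse piece ending at p+L
        prim = dict(contig=read.contig, pos=p - a, strand="+", cigar=f"{a}M{b}S", mapq=mapq, supplementary=False, seq=None)
        supp = dict(contig=read.contig, pos=p + L - b, strand="-", cigar=f"{b}M{a}S", mapq=mapq, supplementary=True, seq=None)
    elif sv.kind == "inv_mm":
        # (- -): reverse piece starting at p, then forward from p+L
        prim = dict(contig=read.contig, pos=p, strand="-", cigar=f"{b}S{a}M", mapq=mapq, supplementary=False, seq=None)
        supp = dict(contig=read.contig, pos=p + L, strand="+", cigar=f"{a}S{b}M", mapq=mapq, supplementary=True, seq=None)
    elif sv.kind == "tra":
        prim = dict(contig=read.contig, pos=p - a, strand="+", cigar=f"{a}M{b}S", mapq=mapq, supplementary=False, seq=None)
        supp = dict(contig=sv.contig2, pos=sv.position2, strand="+", cigar=f"{a}S{b}M", mapq=mapq, supplementary=True, seq=None)
    else:
        raise ValueError(f"unknown SV kind {sv.kind!r}")
    prim["sa"] = _sa_entry(supp["contig"], supp["pos"], supp["strand"], supp["cigar"], supp["mapq"])
    supp["sa"] = _sa_entry(prim["contig"], prim["pos"], prim["strand"], prim["cigar"], prim["mapq"])
    return [prim, supp]


def _foldback_records(read: _Read) -> list[dict]:
    """A fold-back artifact: forward then backward over nearly the same locus."""
    half = read.length // 2
    rest = read.length - half
    c1 = f"{half}M{rest}S"
    c2 = f"{rest}M{half}S"  # reverse strand: trailing clip puts it query-second
    e = read.start + half
    prim = dict(contig=read.contig, pos=read.start, strand="+", cigar=c1, mapq=60, supplementary=False, seq=None)
    supp = dict(contig=read.contig, pos=e - rest + 30, strand="-", cigar=c2, mapq=60, supplementary=True, seq=None)
    prim["sa"] = _sa_entry(supp["contig"], supp["pos"], supp["strand"], supp["cigar"], supp["mapq"])
    supp["sa"] = _sa_entry(prim["contig"], prim["pos"], prim["strand"], prim["cigar"], prim["mapq"])
    return [prim, supp]


def _noise_junction_records(read: _Read, locus: int, rng: np.random.Generator) -> list[dict]:
    """A low-quality chimeric junction: scattered positions, low MAPQ."""
    jitter = int(rng.integers(-40, 41))
    p = locus + jitter
    a = max(200, p - read.start)
    b = max(200, read.length - a)
    mapq = int(rng.integers(6, 25))
    target = int(rng.integers(0, max(read.start - 50_000, 1))) if read.start > 60_000 else read.start + 60_000
    c1 = f"{a}M{b}S"
    c2 = f"{a}S{b}M"
    prim = dict(contig=read.contig, pos=read.start, strand="+", cigar=c1, mapq=mapq, supplementary=False, seq=None)
    supp = dict(contig=read.contig, pos=target, strand="+", cigar=c2, mapq=mapq, supplementary=True, seq=None)
    prim["sa"] = _sa_entry(supp["contig"], supp["pos"], supp["strand"], supp["cigar"], supp["mapq"])
    supp["sa"] = _sa_entry(prim["contig"], prim["pos"], prim["strand"], prim["cigar"], prim["mapq"])
    return [prim, supp]


def _microsatellite_records(read: _Read, locus: int, rng: np.random.Generator) -> list[dict]:
    """Near-threshold indel noise at an unstable locus."""
    a = locus - read.start + int(rng.integers(-15, 16))
    size = int(rng.integers(31, 45))
    b = read.length - a - size
    if a < 50 or b < 50:
        return [_plain_record(read)]
    mapq = int(rng.integers(20, 45))
    return [dict(contig=read.contig, pos=read.start, strand="+", cigar=f"{a}M{size}D{b}M", mapq=mapq, supplementary=False, seq=None)]


def _emit(bam: pysam.AlignmentFile, read: _Read, rec: dict, contig_ids: dict[str, int], phase_set: int = 1) -> None:
    a = pysam.AlignedSegment(header=bam.header)
    a.query_name = read.name
    a.reference_id = contig_ids[rec["contig"]]
    a.reference_start = rec["pos"]
    a.mapping_quality = rec["mapq"]
    a.cigarstring = rec["cigar"]
    flag = 0
    if rec["strand"] == "-":
        flag |= 16
    if rec["supplementary"]:
        flag |= 2048
    a.flag = flag
    if rec.get("seq"):
        a.query_sequence = rec["seq"]
        a.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
    tags = []
    if rec.get("sa"):
        tags.append(("SA", rec["sa"]))
    if read.haplotype in (1, 2):
        tags.append(("HP", read.haplotype))
        tags.append(("PS", phase_set))
    a.set_tags(tags)
    bam.write(a)


def simulate_sv_alignments(config: SimulationConfig, out_dir: str) -> dict:
    """Write tumor.bam, normal.bam and truth.vcf implementing the configured SVs.

    Somatic SVs appear in the tumor only; germline SVs in both samples.
    Fold-back artifacts, noise junctions and microsatellite indel noise are
    injected into the tumor at the configured counts.  Deterministic given
    (config, seed).
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    contig_ids = {name: i for i, name in enumerate(config.contigs)}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in config.contigs.items()],
    }
    paths = {}
    truth_breakends: list[Breakend] = []
    mean_len = sum(config.read_length) / 2

    noise = {"foldback": [], "junction": [], "microsatellite": []}
    for contig, length in config.contigs.items():
        for _ in range(config.noise_loci // max(len(config.contigs), 1)):
            noise["junction"].append((contig, int(rng.integers(100_000, length - 100_000))))
        for _ in range(config.microsatellite_loci // max(len(config.contigs), 1)):
            noise["microsatellite"].append((contig, int(rng.integers(100_000, length - 100_000))))

    for sample in ("tumor", "normal"):
        path = os.path.join(out_dir, f"{sample}.bam")
        paths[sample] = path
        reads: list[_Read] = []
        for contig, length in config.contigs.items():
            n_reads = int(round(config.depth * length / mean_len))
            starts = rng.integers(0, length - config.read_length[1], size=n_reads)
            lens = rng.integers(config.read_length[0], config.read_length[1] + 1, size=n_reads)
            haps = rng.choice([1, 2, 0], size=n_reads, p=[
                (1 - config.unphased_fraction) / 2,
                (1 - config.unphased_fraction) / 2,
                config.unphased_fraction,
            ])
            for i in range(n_reads):
                reads.append(_Read(f"{sample}_{contig}_{i}", contig, int(starts[i]), int(lens[i]), int(haps[i])))
        # mark carriers per SV
        assigned: set[str] = set()
        for sv in config.sv_list:
            if sample == "normal" and not sv.germline:
                continue
            if sv.kind in ("del_cigar", "del_merged", "ins"):
                # gapped representation: the read must span the whole event
                lo = sv.position - _CARRIER_FLANK
                hi = sv.position + sv.length + _CARRIER_FLANK
            else:
                # split/clip representation: the read only crosses the junction
                lo = sv.position - _CARRIER_FLANK
                hi = sv.position + _CARRIER_FLANK
            covering = [
                r
                for r in reads
                if r.contig == sv.contig and r.start <= lo and r.start + r.length >= hi and r.name not in assigned
            ]
            k = int(round(sv.af * len(covering)))
            if sv.af > 0 and k == 0 and covering:
                k = 1
            if sv.af <= 0.55:
                preferred = [r for r in covering if r.haplotype == sv.haplotype]
                others = [r for r in covering if r.haplotype != sv.haplotype]
                chosen = (preferred + others)[:k]
            else:
                chosen = covering[:k]
            for r in chosen:
                r.records = _carrier_records(r, sv, rng)
                assigned.add(r.name)
        if sample == "tumor":
            free = [r for r in reads if not r.records and r.length > 4000]
            fi = 0
            for _ in range(config.foldback_count):
                if fi >= len(free):
                    break
                free[fi].records = _foldback_records(free[fi])
                fi += 1
            for contig, locus in noise["junction"]:
                support = int(rng.integers(1, 3))
                cands = [
                    r
                    for r in free[fi:]
                    if r.contig == contig and r.start + 300 < locus < r.start + r.length - 300 and not r.records
                ][:support]
                for r in cands:
                    r.records = _noise_junction_records(r, locus, rng)
            for contig, locus in noise["microsatellite"]:
                support = int(rng.integers(2, 5))
                cands = [
                    r
                    for r in free[fi:]
                    if r.contig == contig and r.start + 300 < locus < r.start + r.length - 300 and not r.records
                ][:support]
                for r in cands:
                    r.records = _microsatellite_records(r, locus, rng)
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for r in reads:
                if not r.records:
                    r.records = [_plain_record(r)]
                for rec in r.records:
                    _emit(bam, r, rec, contig_ids)
        sort_and_index_bam(path)

    for sv in config.sv_list:
        if not sv.germline:
            truth_breakends.extend(sv.breakends())
    truth_path = os.path.join(out_dir, "truth.vcf")
    _write_truth_vcf(truth_path, config, [sv for sv in config.sv_list if not sv.germline])
    paths["truth"] = truth_path
    return dict(paths=paths, truth_breakends=truth_breakends, noise_loci=noise)


def _write_truth_vcf(path: str, config: SimulationConfig, svs: Sequence[SvSpec]) -> None:
    from svarcall.clustering import BreakpointCluster
    from svarcall.io_formats import write_breakpoint_vcf

    clusters = []
    for sv in svs:
        bes = sv.breakends()
        notation = "INS" if sv.kind == "ins" else ("SBND" if sv.kind == "sbnd" else bes[0].orientation + bes[-1].orientation)
        cluster = BreakpointCluster(
            notation=notation,
            locus_a=(bes[0].contig, bes[0].position, bes[0].orientation),
            locus_b=(bes[1].contig, bes[1].position, bes[1].orientation) if len(bes) > 1 else None,
            members=[],
            stats={"sv_length_median": sv.length},
        )
        if sv.kind == "ins":
            cluster.insert_size = sv.length
        clusters.append(cluster)
    write_breakpoint_vcf(clusters, path, config.contigs)


# ---------------------------------------------------------------------------
# Copy-number / BAF simulation

def profile_for_ploidy(psi: float, contig: str, length: int) -> list[CnSegmentSpec]:
    """A segmented integer-CN profile with length-weighted mean ``psi``.

    Each template mimics what a tumor genome at that ploidy looks like: a
    CN-neutral LOH compartment (>= 10 blocks of 100 kbp on a 10 Mbp genome)
    anchoring the purity estimate, a deleted CN-1 compartment of at least 10%
    (a whole-genome shift of the fit would push it to zero copies and trip
    the zero-state sanity flag), several distinct states interleaved along
    the genome, and adjacent two-most-frequent states.
    """
    templates = {
        1.8: [((2, 1), 0.35), ((1, 0), 0.10), ((2, 0), 0.10), ((2, 1), 0.35), ((1, 0), 0.10)],
        2.0: [((2, 1), 0.30), ((2, 0), 0.15), ((3, 1), 0.10), ((2, 1), 0.35), ((1, 0), 0.10)],
        3.1: [((3, 1), 0.20), ((4, 2), 0.15), ((2, 0), 0.15), ((3, 1), 0.20), ((5, 2), 0.10),
              ((4, 2), 0.10), ((1, 0), 0.10)],
        4.0: [((4, 2), 0.15), ((5, 2), 0.15), ((2, 0), 0.10), ((4, 2), 0.10), ((6, 3), 0.15),
              ((5, 2), 0.15), ((3, 1), 0.10), ((1, 0), 0.10)],
    }
    key = round(psi, 2)
    if key not in templates:
        raise ValueError(f"no profile template for ploidy {psi}")
    segments = []
    pos = 0
    for (total, minor), frac in templates[key]:
        size = int(round(frac * length))
        segments.append(CnSegmentSpec(contig, pos, min(pos + size, length), total, minor))
        pos += size
    segments[-1] = CnSegmentSpec(contig, segments[-1].start, length, segments[-1].total_cn, segments[-1].minor_cn)
    return segments


def simulate_cn_data(config: SimulationConfig) -> dict:
    """Bin-count and SNP-BAF tables under the configured profile and purity.

    Returns {"bins": DataFrame, "snps": DataFrame, "truth": dict}; the truth
    records the purity, the (derived) ploidy, per-segment copy numbers and the
    changepoint positions.
    """
    rng = np.random.default_rng(config.seed + 1)
    rho, psi = config.purity, config.ploidy
    denom = rho * psi + 2 * (1 - rho)
    bin_rows = []
    snp_rows = []
    sigma = config.log2r_noise_sd * math.log(2)
    for seg in config.cn_profile:
        r = (rho * seg.total_cn + 2 * (1 - rho)) / denom
        for start in range(seg.start, seg.end, config.cn_bin_size):
            end = min(start + config.cn_bin_size, seg.end)
            if end - start < config.cn_bin_size // 2:
                continue
            mu_t = config.cn_base_depth * r * math.exp(rng.normal(0, sigma))
            tumor = max(int(rng.poisson(mu_t)), 0)
            normal = max(int(rng.poisson(config.cn_base_depth)), 0)
            bin_rows.append((seg.contig, start, end, tumor, normal))
        p_alt_base = (rho * seg.minor_cn + (1 - rho)) / (rho * seg.total_cn + 2 * (1 - rho))
        for pos in range(seg.start + config.snp_spacing, seg.end, config.snp_spacing):
            depth = max(int(rng.poisson(config.snp_depth)), 1)
            p = p_alt_base if rng.random() < 0.5 else 1 - p_alt_base
            alt = int(rng.binomial(depth, p))
            snp_rows.append((seg.contig, pos + 1, depth - alt, alt))
    bins = pd.DataFrame(bin_rows, columns=["contig", "start", "end", "tumor_count", "normal_count"])
    snps = pd.DataFrame(snp_rows, columns=["contig", "position", "ref_count", "alt_count"])
    changepoints = []
    prev = None
    for seg in config.cn_profile:
        if prev is not None and prev.contig == seg.contig:
            changepoints.append((seg.contig, seg.start))
        prev = seg
    truth = dict(
        purity=rho,
        ploidy=psi,
        segments=[asdict(s) for s in config.cn_profile],
        changepoints=changepoints,
    )
    return dict(bins=bins, snps=snps, truth=truth)


# ---------------------------------------------------------------------------
# Worked example

def worked_example_config(seed: int = 0) -> SimulationConfig:
    """The bundled tiny study: 2 contigs of 1.2 Mbp, 12 somatic SVs spanning
    every notation, purity 0.6, derived ploidy 2.0."""
    c1, c2 = "chr1", "chr2"
    svs = [
        SvSpec("del_cigar", c1, 100_000, 500, af=0.7, haplotype=1),
        SvSpec("del_split", c1, 160_000, 5_000, af=0.8, haplotype=2),
        SvSpec("del_merged", c1, 220_000, 120, af=0.7, haplotype=1),
        SvSpec("dup", c1, 280_000, 40_000, af=0.7, haplotype=2),
        SvSpec("inv_pp", c1, 400_000, 50_000, af=0.8, haplotype=1),
        SvSpec("inv_mm", c1, 520_000, 60_000, af=0.7, haplotype=2),
        SvSpec("ins", c1, 650_000, 400, af=0.8, haplotype=1),
        SvSpec("tra", c1, 720_000, 0, contig2=c2, position2=300_000, af=0.8, haplotype=2),
        SvSpec("del_split", c2, 100_000, 30_000, af=1.0, haplotype=1),
        SvSpec("ins", c2, 480_000, 150, af=0.8, haplotype=2),
        SvSpec("dup", c2, 600_000, 25_000, af=0.7, haplotype=1),
        SvSpec("sbnd", c2, 900_000, 0, af=0.8, haplotype=2),
    ]
    profile = [
        CnSegmentSpec(c1, 0, 200_000, 2, 1),
        CnSegmentSpec(c1, 200_000, 600_000, 3, 1),
        CnSegmentSpec(c1, 600_000, 1_100_000, 2, 0),
        CnSegmentSpec(c1, 1_100_000, 1_200_000, 2, 1),
        CnSegmentSpec(c2, 0, 200_000, 2, 1),
        CnSegmentSpec(c2, 200_000, 600_000, 1, 0),
        CnSegmentSpec(c2, 600_000, 1_100_000, 2, 0),
        CnSegmentSpec(c2, 1_100_000, 1_200_000, 2, 1),
    ]
    return SimulationConfig(
        seed=seed,
        contigs={c1: 1_200_000, c2: 1_200_000},
        sv_list=svs,
        depth=30,
        purity=0.6,
        cn_profile=profile,
        cn_base_depth=2000,
        log2r_noise_sd=0.03,
    )


def training_config(seed: int = 0) -> SimulationConfig:
    """A larger fixture for classifier training: true SVs plus injected noise."""
    rng = np.random.default_rng(seed + 17)
    contigs = {"chr1": 2_000_000, "chr2": 2_000_000}
    svs = []
    kinds = ["del_cigar", "del_split", "dup", "inv_pp", "inv_mm", "ins"]
    for ci, contig in enumerate(contigs):
        for k in range(24):
            pos = 120_000 + k * 75_000
            kind = kinds[(k + ci) % len(kinds)]
            length = int(rng.integers(200, 40_000)) if kind not in ("ins", "del_cigar") else int(rng.integers(60, 500))
            svs.append(
                SvSpec(kind, contig, pos, length, af=float(rng.uniform(0.25, 0.6)), haplotype=1 + (k % 2))
            )
    return SimulationConfig(
        seed=seed,
        contigs=contigs,
        sv_list=svs,
        depth=30,
        noise_loci=50,
        microsatellite_loci=20,
    )


def make_worked_example(out_dir: str, seed: int = 0) -> dict:
    """Generate the worked-example fixture: alignments, truth VCF, CN/BAF tables."""
    config = worked_example_config(seed)
    result = simulate_sv_alignments(config, out_dir)
    cn = simulate_cn_data(config)
    cn["bins"].to_csv(os.path.join(out_dir, "bins.tsv"), sep="\t", index=False)
    cn["snps"].to_csv(os.path.join(out_dir, "snps.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(
            dict(seed=config.seed, contigs=config.contigs, purity=config.purity, ploidy=config.ploidy,
                 n_svs=len(config.sv_list)),
            fh,
            indent=2,
        )
    result["cn"] = cn
    result["config"] = config
    return result
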