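"""Evaluation machinery: replicate splitting, breakend matching, read-backed
phasing consistency, and the fold-back artifact rate.

Replicate splitting assigns every read (all of its records together) to one of
two output alignment files by a seeded fair coin, enabling
caller-vs-own-replicate concordance and normal-vs-normal specificity
experiments.  Breakend matching is greedy nearest-first one-to-one within a
100 bp buffer and yields precision/recall/F.  The phasing test asks whether an
SV's supporting reads come from a single parental allele, as expected for a
true somatic SV outside LOH: SVs with reads on both alleles get a one-tailed
binomial test (success probability 0.95 for the majority allele) with
Benjamini-Hochberg correction across SVs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from svarcall.io_formats import Breakend, GenomicInterval, sort_and_index_bam

CONCORDANT = "concordant"
DISCORDANT = "discordant"
INCONCLUSIVE = "inconclusive"


# ---------------------------------------------------------------------------
# Replicate splitting

def split_replicates(bam_path: str, out_a: str, out_b: str, seed: int = 0) -> tuple[int, int]:
    """Split a BAM into two replicates by read: a seeded fair coin per read
    name sends all of that read's records to the same output.  Both outputs
    are coordinate-sorted and indexed.  Returns the read counts per output."""
    with pysam.AlignmentFile(bam_path) as bam:
        names = sorted({rec.query_name for rec in bam.fetch(until_eof=True)})
    rng = random.Random(seed)
    assignment = {name: rng.random() < 0.5 for name in names}
    counts = [0, 0]
    with pysam.AlignmentFile(bam_path) as bam:
        with pysam.AlignmentFile(out_a, "wb", template=bam) as fa, pysam.AlignmentFile(
            out_b, "wb", template=bam
        ) as fb:
            seen_a: set = set()
            seen_b: set = set()
            for rec in bam.fetch(until_eof=True):
                if assignment[rec.query_name]:
                    fa.write(rec)
                    seen_a.add(rec.query_name)
                else:
                    fb.write(rec)
                    seen_b.add(rec.query_name)
    sort_and_index_bam(out_a)
    sort_and_index_bam(out_b)
    return len(seen_a), len(seen_b)


# ---------------------------------------------------------------------------
# Breakend matching

@dataclass
class MatchResult:
    matched: list[tuple[Breakend, Breakend, int]]
    unmatched_calls: list[Breakend]
    unmatched_truth: list[Breakend]

    @property
    def true_positives(self) -> int:
        return len(self.matched)

    @property
    def precision(self) -> float:
        denom = self.true_positives + len(self.unmatched_calls)
        return self.true_positives / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.true_positives + len(self.unmatched_truth)
        return self.true_positives / denom if denom else float("nan")

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def match_breakends(calls: Iterable[Breakend], truth: Iterable[Breakend], buffer: int = 100) -> MatchResult:
    """Greedy nearest-first one-to-one matching of breakends within ``buffer``.

    Insertions are compared record-to-record (an INS call can only match an
    INS truth entry); every truth breakend is matched at most once.
    """
    calls = sorted(set(calls))
    truth = sorted(set(truth))
    candidates: list[tuple[int, int, int]] = []  # (distance, call idx, truth idx)
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            if c.contig != t.contig:
                continue
            if (c.svtype == "INS") != (t.svtype == "INS"):
                continue
            d = abs(c.position - t.position)
            if d <= buffer:
                candidates.append((d, i, j))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[Breakend, Breakend, int]] = []
    for d, i, j in candidates:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        matched.append((calls[i], truth[j], d))
    unmatched_calls = [c for i, c in enumerate(calls) if i not in used_c]
    unmatched_truth = [t for j, t in enumerate(truth) if j not in used_t]
    return MatchResult(matched, unmatched_calls, unmatched_truth)


# ---------------------------------------------------------------------------
# Read-backed phasing consistency

@dataclass
class PhasingVerdict:
    sv_id: str
    allele1_count: int
    allele2_count: int
    verdict: str
    p_value: Optional[float] = None
    fdr_q: Optional[float] = None


def phasing_consistency(
    sv_support: Sequence[tuple[str, int, int]],
    sv_loci: Optional[Sequence[tuple[str, int]]] = None,
    loh_regions: Sequence[GenomicInterval] = (),
    p_success: float = 0.95,
    fdr: float = 0.05,
) -> list[PhasingVerdict]:
    """Classify SVs by haplotype support: concordant (single allele),
    discordant (significantly many minority-allele reads) or inconclusive.

    ``sv_support`` is (sv_id, allele1 reads, allele2 reads).  SVs inside LOH
    regions are excluded (a false positive there would also look single-
    allele).  For an SV with reads on both alleles, the majority-allele count
    is tested against Binomial(n, 0.95) one-tailed; BH-corrected q <= ``fdr``
    means discordant.
    """
    loci = sv_loci or [None] * len(sv_support)
    verdicts: list[PhasingVerdict] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for i, ((sv_id, a1, a2), locus) in enumerate(zip(sv_support, loci)):
        if locus is not None and any(
            r.contig == locus[0] and r.start <= locus[1] < r.end for r in loh_regions
        ):
            continue
        if a1 < 0 or a2 < 0:
            raise ValueError("negative allele counts")
        if a1 == 0 and a2 == 0:
            verdicts.append(PhasingVerdict(sv_id, a1, a2, INCONCLUSIVE))
            continue
        if a1 == 0 or a2 == 0:
            verdicts.append(PhasingVerdict(sv_id, a1, a2, CONCORDANT))
            continue
        n = a1 + a2
        k = max(a1, a2)
        p = float(sps.binomtest(k, n, p_success, alternative="less").pvalue)
        verdicts.append(PhasingVerdict(sv_id, a1, a2, INCONCLUSIVE, p_value=p))
        tested_idx.append(len(verdicts) - 1)
        pvals.append(p)
    if pvals:
        reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for idx, rej, q in zip(tested_idx, reject, qvals):
            verdicts[idx].fdr_q = float(q)
            verdicts[idx].verdict = DISCORDANT if rej else INCONCLUSIVE
    return verdicts


# ---------------------------------------------------------------------------
# Fold-back artifact rate

def foldback_rate(
    bam_path: str,
    mapq_min: int = 20,
    end_distance: int = 150,
) -> tuple[int, int, float]:
    """Estimate the per-read rate of fold-back-like inversion artifacts.

    A read counts as an artifact when (1) it has exactly one primary and one
    supplementary alignment, both MAPQ >= ``mapq_min``; (2) the two alignments
    overlap on the reference in opposite orientations; and (3) the reference
    positions of the read's start and end are less than ``end_distance`` bp
    apart.  The denominator is all reads with a primary alignment of MAPQ >=
    ``mapq_min``.  Returns (artifacts, eligible reads, rate).
    """
    reads: dict[str, dict] = {}
    with pysam.AlignmentFile(bam_path) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            entry = reads.setdefault(rec.query_name, {"primary": [], "supplementary": []})
            key = "supplementary" if rec.is_supplementary else "primary"
            entry[key].append(
                dict(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    qstart=_read_coord_interval(rec)[0],
                    qend=_read_coord_interval(rec)[1],
                )
            )
    eligible = 0
    artifacts = 0
    for name, entry in reads.items():
        primaries = entry["primary"]
        if len(primaries) != 1 or primaries[0]["mapq"] < mapq_min:
            continue
        eligible += 1
        supps = entry["supplementary"]
        if len(supps) != 1:
            continue
        p, s = primaries[0], supps[0]
        if s["mapq"] < mapq_min:
            continue
        if p["contig"] != s["contig"] or p["strand"] == s["strand"]:
            continue
        if min(p["end"], s["end"]) <= max(p["start"], s["start"]):
            continue  # no reference overlap
        # reference positions of the read's first and last base
        pieces = sorted([p, s], key=lambda e: e["qstart"])
        first, last = pieces[0], pieces[-1]
        pos_read_start = first["start"] if first["strand"] == "+" else first["end"]
        pos_read_end = last["end"] if last["strand"] == "+" else last["start"]
        if abs(pos_read_start - pos_read_end) < end_distance:
            artifacts += 1
    rate = artifacts / eligible if eligible else float("nan")
    return artifacts, eligible, rate


def _read_coord_interval(rec: pysam.AlignedSegment) -> tuple[int, int]:
    from svarcall.io_formats import _CIGAR_OPS, cigar_query_alignment

    cigar = [(_CIGAR_OPS[op], length) for op, length in rec.cigartuples or []]
    strand = "-" if rec.is_reverse else "+"
    qs, qe, _cl, _cr = cigar_query_alignment(cigar, strand)
    return qs, qe
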