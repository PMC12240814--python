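"""Discovery of putative breakpoints from split, gapped and clipped alignments.

A read crossing an SV junction is aligned as two or more segments (primary
plus supplementary alignments, linked through the SA tag), as a gapped
alignment with a long insertion/deletion CIGAR operation, or — when only one
side of the new adjacency maps — with a long terminal soft clip.  Each source
yields putative breakpoints tagged with orientation, phasing and read
identity; fold-back-like inversion artifacts common in nanopore data are
suppressed at this stage.  A per-haplotype coverage track is accumulated
alongside for later depth annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from svarcall.io_formats import (
    NORMAL,
    TUMOR,
    UNPHASED,
    AlignmentSegment,
    cigar_query_alignment,
    cigar_reference_length,
    parse_cigar,
    segment_from_record,
)

logger = logging.getLogger(__name__)

SPLIT = "split"
CIGAR_DELETION = "cigar_deletion"
CIGAR_INSERTION = "cigar_insertion"
SOFTCLIP_SBND = "softclip_sbnd"

DEFAULT_MIN_SV_LENGTH = 30
DEFAULT_FOLDBACK_WINDOW = 200
DEFAULT_MIN_SOFTCLIP = 1000
DEFAULT_COVERAGE_BIN = 5
DEFAULT_NORMAL_LENGTH_FRACTION = 0.20


@dataclass
class PutativeBreakpoint:
    """A single-read observation of a candidate SV junction."""

    locus_a: tuple[str, int, str]  # (contig, 0-based position, orientation)
    locus_b: Optional[tuple[str, int, str]]
    kind: str
    sv_length: int
    read_name: str
    sample: str = TUMOR
    haplotype: int = UNPHASED
    phase_set: Optional[int] = None
    mapq: float = 60.0
    inserted_sequence: Optional[str] = None
    span: int = 0  # reference span of the merged region for merged deletions

    def __post_init__(self) -> None:
        if (self.locus_b is None) != (self.kind == SOFTCLIP_SBND):
            raise ValueError("locus_b must be absent exactly for single-breakend candidates")
        if self.sv_length < 0:
            raise ValueError("sv_length must be >= 0")

    @property
    def notation(self) -> str:
        if self.kind == SOFTCLIP_SBND:
            return "SBND"
        if self.kind == CIGAR_INSERTION:
            return "INS"
        return self.locus_a[2] + self.locus_b[2]


@dataclass
class SbndCandidate:
    """Clipped sequence adjacent to a low-quality supplementary alignment."""

    contig: str
    position: int
    orientation: str
    sequence: Optional[str]
    read_name: str


# ---------------------------------------------------------------------------
# Segment extraction

def _parse_sa_tag(sa: str) -> list[dict]:
    entries = []
    for part in sa.rstrip(";").split(";"):
        if not part:
            continue
        fields = part.split(",")
        if len(fields) < 6:
            raise ValueError(f"short SA entry {part!r}")
        entries.append(
            dict(
                contig=fields[0],
                pos=int(fields[1]) - 1,
                strand=fields[2],
                cigar=parse_cigar(fields[3]),
                mapq=int(fields[4]),
            )
        )
    return entries


def segments_from_read(
    primary: AlignmentSegment,
    sa_tag: Optional[str] = None,
    sbnd_mode: bool = False,
    supp_mapq_floor: float = 5,
) -> tuple[list[AlignmentSegment], list[SbndCandidate]]:
    """Expand a primary alignment plus its SA tag into query-ordered segments.

    Supplementary entries below ``supp_mapq_floor`` are treated as unmapped;
    in single-breakend mode their clipped sequence and the flanking mapped
    position are kept as SBND candidates instead.
    """
    segments = [primary]
    candidates: list[SbndCandidate] = []
    if sa_tag:
        try:
            entries = _parse_sa_tag(sa_tag)
        except (ValueError, IndexError) as exc:
            logger.warning("malformed SA tag for read %s: %s", primary.read_name, exc)
            return sorted(segments, key=lambda s: s.query_start), candidates
        for entry in entries:
            qs, qe, cl, cr = cigar_query_alignment(entry["cigar"], entry["strand"])
            ref_len = cigar_reference_length(entry["cigar"])
            if entry["mapq"] < supp_mapq_floor:
                if sbnd_mode:
                    # clipped piece of the read abuts the primary's mapped end
                    orient = "+" if qs > primary.query_start else "-"
                    pos = primary.end if orient == "+" else primary.start
                    seq = None
                    if primary.query_sequence:
                        seq = primary.query_sequence[qs:qe].upper()
                    candidates.append(
                        SbndCandidate(primary.contig, pos, orient, seq, primary.read_name)
                    )
                continue
            segments.append(
                AlignmentSegment(
                    read_name=primary.read_name,
                    contig=entry["contig"],
                    start=entry["pos"],
                    end=entry["pos"] + ref_len,
                    strand=entry["strand"],
                    mapq=entry["mapq"],
                    cigar=entry["cigar"],
                    is_supplementary=True,
                    haplotype=primary.haplotype,
                    phase_set=primary.phase_set,
                    query_start=qs,
                    query_end=qe,
                    sample=primary.sample,
                    clipped_left=cl,
                    clipped_right=cr,
                )
            )
    segments.sort(key=lambda s: s.query_start)
    return segments, candidates


# ---------------------------------------------------------------------------
# Fold-back artifact suppression

def detect_foldback_pair(seg_i: AlignmentSegment, seg_next: AlignmentSegment, window: int = DEFAULT_FOLDBACK_WINDOW) -> bool:
    """True when two query-adjacent segments look like a fold-back artifact.

    Nanopore reads occasionally re-read the same template backwards, producing
    a forward and a reverse alignment over the same locus whose reference ends
    nearly coincide — indistinguishable locally from an inversion junction.
    Such junctions are suppressed rather than reported as inversions.
    """
    if seg_i.contig != seg_next.contig or seg_i.strand == seg_next.strand:
        return False
    return abs(seg_i.end - seg_next.end) <= window


# ---------------------------------------------------------------------------
# Breakpoints from split reads

def _junction_breakends(seg1: AlignmentSegment, seg2: AlignmentSegment) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
    """Breakend loci for the junction between two query-adjacent segments.

    Orientation '+': retained sequence to the left of the breakend.  A segment
    leaves the junction at its reference end when on '+' strand and at its
    reference start when on '-'; the mirror rule applies to the entering
    segment.
    """
    if seg1.strand == "+":
        a = (seg1.contig, seg1.end, "+")
    else:
        a = (seg1.contig, seg1.start, "-")
    if seg2.strand == "+":
        b = (seg2.contig, seg2.start, "-")
    else:
        b = (seg2.contig, seg2.end, "+")
    return a, b


def breakpoints_from_split(
    segments: Sequence[AlignmentSegment],
    foldback_window: int = DEFAULT_FOLDBACK_WINDOW,
) -> list[PutativeBreakpoint]:
    """One putative breakpoint per adjacent segment pair, fold-backs suppressed.

    Breakends are ordered by genomic position (contig, then coordinate) so that
    deletion-like junctions read (+ -), duplication-like (- +), and inversions
    (+ +) or (- -).
    """
    out: list[PutativeBreakpoint] = []
    for seg1, seg2 in zip(segments, segments[1:]):
        if detect_foldback_pair(seg1, seg2, foldback_window):
            continue
        a, b = _junction_breakends(seg1, seg2)
        if (a[0], a[1]) > (b[0], b[1]):
            a, b = b, a
        sv_length = abs(b[1] - a[1]) if a[0] == b[0] else 0
        out.append(
            PutativeBreakpoint(
                locus_a=a,
                locus_b=b,
                kind=SPLIT,
                sv_length=sv_length,
                read_name=seg1.read_name,
                sample=seg1.sample,
                haplotype=seg1.haplotype,
                phase_set=seg1.phase_set,
                mapq=(seg1.mapq + seg2.mapq) / 2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Breakpoints from CIGAR operations

def effective_min_sv_length(min_sv_length: int, sample_role: str, normal_length_fraction: float = DEFAULT_NORMAL_LENGTH_FRACTION) -> float:
    """Minimum indel size to track; relaxed for the normal so that germline
    indels just under the tumor cutoff still veto somatic status."""
    if sample_role == NORMAL:
        return min_sv_length * (1 - normal_length_fraction)
    return float(min_sv_length)


def breakpoints_from_cigar(
    segment: AlignmentSegment,
    min_sv_length: int = DEFAULT_MIN_SV_LENGTH,
    merge_gap: int = 30,
    normal_length_fraction: float = DEFAULT_NORMAL_LENGTH_FRACTION,
) -> list[PutativeBreakpoint]:
    """Deletion/insertion breakpoints from long CIGAR operations.

    Adjacent deletions separated by matched stretches shorter than
    ``merge_gap`` are merged into one event whose length is the sum of deleted
    bases (the reference span of the merged region is kept separately).
    """
    threshold = effective_min_sv_length(min_sv_length, segment.sample, normal_length_fraction)
    events: list[dict] = []  # raw D/I ops above threshold, in reference order
    ref = segment.start
    query = segment.query_start if segment.strand == "+" else segment.query_end
    qdir = 1 if segment.strand == "+" else -1
    for op, length in segment.cigar:
        if op == "D" and length > threshold:
            events.append(dict(kind="D", ref_start=ref, ref_end=ref + length, length=length))
        elif op == "I" and length > threshold:
            seq = None
            if segment.query_sequence is not None:
                if segment.strand == "+":
                    seq = segment.query_sequence[query : query + length].upper()
                else:
                    seq = segment.query_sequence[query - length : query].upper()
            events.append(dict(kind="I", ref_start=ref, ref_end=ref, length=length, seq=seq))
        if op in "MDN=X":
            ref += length
        if op in "MI=X":
            query += qdir * length

    # merge adjacent deletions interspersed by short matched stretches
    merged: list[dict] = []
    for ev in events:
        if (
            merged
            and ev["kind"] == "D"
            and merged[-1]["kind"] == "D"
            and ev["ref_start"] - merged[-1]["ref_end"] < merge_gap
        ):
            merged[-1]["ref_end"] = ev["ref_end"]
            merged[-1]["length"] += ev["length"]
        else:
            merged.append(dict(ev))

    out: list[PutativeBreakpoint] = []
    for ev in merged:
        common = dict(
            read_name=segment.read_name,
            sample=segment.sample,
            haplotype=segment.haplotype,
            phase_set=segment.phase_set,
            mapq=segment.mapq,
        )
        if ev["kind"] == "D":
            out.append(
                PutativeBreakpoint(
                    locus_a=(segment.contig, ev["ref_start"], "+"),
                    locus_b=(segment.contig, ev["ref_end"], "-"),
                    kind=CIGAR_DELETION,
                    sv_length=ev["length"],
                    span=ev["ref_end"] - ev["ref_start"],
                    **common,
                )
            )
        else:
            out.append(
                PutativeBreakpoint(
                    locus_a=(segment.contig, ev["ref_start"], "+"),
                    locus_b=(segment.contig, ev["ref_start"], "-"),
                    kind=CIGAR_INSERTION,
                    sv_length=ev["length"],
                    inserted_sequence=ev.get("seq"),
                    **common,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Single breakends from long soft clips

def sbnd_from_softclips(
    segment: AlignmentSegment,
    min_clip: int = DEFAULT_MIN_SOFTCLIP,
    sa_query_intervals: Sequence[tuple[int, int]] = (),
) -> list[PutativeBreakpoint]:
    """Single-breakend candidates from terminal soft clips with no
    supplementary alignment covering the clipped read interval."""
    out: list[PutativeBreakpoint] = []
    clips = []
    lead = segment.cigar[0] if segment.cigar else None
    tail = segment.cigar[-1] if segment.cigar else None
    if lead and lead[0] == "S" and lead[1] > min_clip:
        # clip on the reference-left side of the aligned block
        clip_len = lead[1]
        if segment.strand == "+":
            qiv = (segment.query_start - clip_len, segment.query_start)
        else:
            qiv = (segment.query_end, segment.query_end + clip_len)
        clips.append(("-", segment.start, qiv, clip_len, True))
    if tail and tail[0] == "S" and tail[1] > min_clip:
        clip_len = tail[1]
        if segment.strand == "+":
            qiv = (segment.query_end, segment.query_end + clip_len)
        else:
            qiv = (segment.query_start - clip_len, segment.query_start)
        clips.append(("+", segment.end, qiv, clip_len, False))
    for orient, pos, qiv, clip_len, left in clips:
        covered = any(qs < qiv[1] and qe > qiv[0] for qs, qe in sa_query_intervals)
        if covered:
            continue
        seq = None
        if segment.query_sequence is not None:
            # query_sequence from pysam is already in read orientation of storage;
            # slice by reference-side position within the stored sequence
            if left:
                seq = segment.query_sequence[:clip_len].upper()
            else:
                seq = segment.query_sequence[-clip_len:].upper()
        out.append(
            PutativeBreakpoint(
                locus_a=(segment.contig, pos, orient),
                locus_b=None,
                kind=SOFTCLIP_SBND,
                sv_length=0,
                read_name=segment.read_name,
                sample=segment.sample,
                haplotype=segment.haplotype,
                phase_set=segment.phase_set,
                mapq=segment.mapq,
                inserted_sequence=seq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Coverage track

HAPLOTYPES = (1, 2, UNPHASED)


class CoverageTrack:
    """Per-haplotype alignment counts in fixed-size bins along each contig."""

    def __init__(self, contig_lengths: dict[str, int], bin_size: int = DEFAULT_COVERAGE_BIN, sample: str = TUMOR):
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = bin_size
        self.sample = sample
        self.contig_lengths = dict(contig_lengths)
        self.counts: dict[tuple[str, int], np.ndarray] = {}
        for contig, length in contig_lengths.items():
            n_bins = math.ceil(length / bin_size)
            for hap in HAPLOTYPES:
                self.counts[(contig, hap)] = np.zeros(n_bins, dtype=np.int32)

    def add_segment(self, segment: AlignmentSegment) -> None:
        hap = segment.haplotype if segment.haplotype in (1, 2) else UNPHASED
        arr = self.counts[(segment.contig, hap)]
        first = segment.start // self.bin_size
        last = (segment.end - 1) // self.bin_size
        arr[first : last + 1] += 1

    def at(self, contig: str, position: int) -> dict:
        """Haplotype counts and their total at the bin containing ``position``."""
        if contig not in self.contig_lengths:
            raise ValueError(f"unknown contig {contig!r}")
        if not (0 <= position < self.contig_lengths[contig]):
            raise ValueError(f"position {position} outside contig {contig}")
        b = position // self.bin_size
        per_hap = {hap: int(self.counts[(contig, hap)][b]) for hap in HAPLOTYPES}
        per_hap["total"] = sum(per_hap[h] for h in HAPLOTYPES)
        return per_hap

    def total_array(self, contig: str) -> np.ndarray:
        return sum(self.counts[(contig, hap)] for hap in HAPLOTYPES)


def build_coverage(
    segments: Iterable[AlignmentSegment],
    contig_lengths: dict[str, int],
    bin_size: int = DEFAULT_COVERAGE_BIN,
    sample: str = TUMOR,
) -> CoverageTrack:
    track = CoverageTrack(contig_lengths, bin_size=bin_size, sample=sample)
    for seg in segments:
        track.add_segment(seg)
    return track


def coverage_at(track: CoverageTrack, contig: str, position: int) -> dict:
    return track.at(contig, position)


# ---------------------------------------------------------------------------
# Whole-sample discovery driver

@dataclass
class DiscoveryResult:
    breakpoints: list[PutativeBreakpoint]
    coverage: CoverageTrack
    sbnd_candidates: list[SbndCandidate] = field(default_factory=list)


def discover_sample(
    bam_path: str,
    sample_role: str,
    contig_lengths: dict[str, int],
    min_mapq: float = 5,
    normal_leniency_fraction: float = 0.5,
    min_sv_length: int = DEFAULT_MIN_SV_LENGTH,
    merge_gap: int = 30,
    normal_length_fraction: float = DEFAULT_NORMAL_LENGTH_FRACTION,
    foldback_window: int = DEFAULT_FOLDBACK_WINDOW,
    min_softclip: int = DEFAULT_MIN_SOFTCLIP,
    coverage_bin_size: int = DEFAULT_COVERAGE_BIN,
    genome_bin_size: int = 100_000_000,
    sbnd_mode: bool = True,
    supp_mapq_floor: float = 5,
) -> DiscoveryResult:
    """Scan one sample's alignments and collect putative breakpoints.

    The genome is processed in non-overlapping bins (100 Mbp by default); a
    read belongs to the bin containing its primary-alignment start, so
    multi-bin reads are never double-counted.  At this scale the bins simply
    define a deterministic processing order.
    """
    from svarcall.io_formats import read_alignments

    breakpoints: list[PutativeBreakpoint] = []
    sbnd_candidates: list[SbndCandidate] = []
    coverage = CoverageTrack(contig_lengths, bin_size=coverage_bin_size, sample=sample_role)

    with pysam.AlignmentFile(bam_path) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            threshold = min_mapq if sample_role == TUMOR else min_mapq * normal_leniency_fraction
            if rec.mapping_quality < threshold:
                continue
            seg = segment_from_record(rec, sample_role)
            if rec.is_supplementary:
                # supplementaries contribute to coverage and CIGAR events only;
                # the junction itself is emitted from the primary's SA walk
                coverage.add_segment(seg)
                breakpoints.extend(
                    breakpoints_from_cigar(seg, min_sv_length, merge_gap, normal_length_fraction)
                )
                continue
            sa_tag = rec.get_tag("SA") if rec.has_tag("SA") else None
            segments, candidates = segments_from_read(
                seg, sa_tag, sbnd_mode=sbnd_mode, supp_mapq_floor=supp_mapq_floor
            )
            sbnd_candidates.extend(candidates)
            coverage.add_segment(seg)
            breakpoints.extend(
                breakpoints_from_cigar(seg, min_sv_length, merge_gap, normal_length_fraction)
            )
            if len(segments) > 1:
                breakpoints.extend(breakpoints_from_split(segments, foldback_window))
            sa_qivs = [(s.query_start, s.query_end) for s in segments if s is not seg]
            breakpoints.extend(sbnd_from_softclips(seg, min_softclip, sa_qivs))
    breakpoints.sort(key=lambda b: (b.locus_a[0], b.locus_a[1], b.kind, b.read_name))
    return DiscoveryResult(breakpoints, coverage, sbnd_candidates)
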