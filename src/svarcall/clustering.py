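"""Grouping of putative breakpoints into candidate SV clusters.

Single-linkage chaining along the genome with type-specific windows (10 bp by
default, 250 bp for insertions because their mapped location is noisier),
followed by a mate-side refinement pass (50 bp window) and insertion-size
grouping.  Tumor and normal observations co-cluster; normal membership later
drives somatic filtering.  Single breakends survive only when nothing else
explains the locus.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from svarcall.discovery import (
    CIGAR_DELETION,
    CIGAR_INSERTION,
    SOFTCLIP_SBND,
    SPLIT,
    PutativeBreakpoint,
)
from svarcall.io_formats import NORMAL, TUMOR, UNPHASED

DEFAULT_CLUSTER_WINDOW = 10
DEFAULT_INSERTION_WINDOW = 250
DEFAULT_MATE_WINDOW = 50
DEFAULT_INSERTION_SIZE_REL_TOL = 0.25

NOTATIONS = ("+-", "-+", "++", "--", "INS", "SBND")


def _median_int(values: Sequence[int]) -> int:
    """Median with ties broken toward the lower value (deterministic)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


@dataclass
class BreakpointCluster:
    """A candidate SV: two breakends (one for SBND) plus supporting evidence."""

    notation: str
    locus_a: tuple[str, int, str]
    locus_b: Optional[tuple[str, int, str]]
    members: list[PutativeBreakpoint]
    tumor_read_names: set[str] = field(default_factory=set)
    normal_read_names: set[str] = field(default_factory=set)
    stats: dict = field(default_factory=dict)
    insert_size: Optional[int] = None
    inserted_sequence: Optional[str] = None
    haplotype_support: dict = field(default_factory=dict)
    # filled in by the classifier stage
    class_label: Optional[str] = None
    class_probability: Optional[float] = None
    conformal_region: Optional[str] = None
    filter_status: Optional[str] = None
    rescued: bool = False
    allele_fraction: Optional[float] = None

    @property
    def tumor_support(self) -> int:
        return len(self.tumor_read_names)

    @property
    def normal_support(self) -> int:
        return len(self.normal_read_names)

    @property
    def interchromosomal(self) -> bool:
        return self.locus_b is not None and self.locus_a[0] != self.locus_b[0]


# ---------------------------------------------------------------------------
# Stage 1: positional chaining

def _chain(items: list, position, window: float) -> list[list]:
    """Single-linkage chaining: an item joins the open group iff its position
    is within ``window`` of the previous item's position."""
    groups: list[list] = []
    prev = None
    for item in items:
        pos = position(item)
        if prev is not None and pos - prev <= window:
            groups[-1].append(item)
        else:
            groups.append([item])
        prev = pos
    return groups


def _kind_group(bp: PutativeBreakpoint) -> str:
    # CIGAR deletions co-cluster with split (+ -) junctions: both are typed
    # (+ -) so gapped and supplementary evidence for one deletion groups
    if bp.kind == CIGAR_INSERTION:
        return "INS"
    if bp.kind == SOFTCLIP_SBND:
        return "SBND"
    return bp.notation


def cluster_by_position(
    breakpoints: Iterable[PutativeBreakpoint],
    window_default: int = DEFAULT_CLUSTER_WINDOW,
    window_insertion: int = DEFAULT_INSERTION_WINDOW,
) -> list[list[PutativeBreakpoint]]:
    """Chain breakpoints of one notation group along (contig, position)."""
    keyed: dict[tuple[str, str], list[PutativeBreakpoint]] = {}
    for bp in breakpoints:
        keyed.setdefault((_kind_group(bp), bp.locus_a[0]), []).append(bp)
    proto: list[list[PutativeBreakpoint]] = []
    for (group, _contig), items in sorted(keyed.items()):
        window = window_insertion if group == "INS" else window_default
        items.sort(key=lambda b: (b.locus_a[1], b.read_name))
        proto.extend(_chain(items, lambda b: b.locus_a[1], window))
    return proto


# ---------------------------------------------------------------------------
# Stage 2: mate-side refinement

def refine_by_mate(proto_cluster: list[PutativeBreakpoint], mate_window: int = DEFAULT_MATE_WINDOW) -> list[list[PutativeBreakpoint]]:
    """Partition a positional cluster by mate contig, then chain mate positions
    with a larger window so one event's supporting reads stay together."""
    if not proto_cluster or proto_cluster[0].locus_b is None:
        return [proto_cluster]
    by_contig: dict[str, list[PutativeBreakpoint]] = {}
    for bp in proto_cluster:
        by_contig.setdefault(bp.locus_b[0], []).append(bp)
    out: list[list[PutativeBreakpoint]] = []
    for _contig, items in sorted(by_contig.items()):
        items.sort(key=lambda b: (b.locus_b[1], b.read_name))
        out.extend(_chain(items, lambda b: b.locus_b[1], mate_window))
    return out


# ---------------------------------------------------------------------------
# Stage 3: insertion-size grouping

def group_insertions_by_size(
    proto_cluster: list[PutativeBreakpoint],
    rel_tol: float = DEFAULT_INSERTION_SIZE_REL_TOL,
) -> list[list[PutativeBreakpoint]]:
    """Split an insertion cluster so grouped reads support comparable sizes:
    chain along sorted sizes, splitting when consecutive sizes differ by more
    than ``rel_tol`` times the smaller one."""
    items = sorted(proto_cluster, key=lambda b: (b.sv_length, b.read_name))
    groups: list[list[PutativeBreakpoint]] = []
    prev: Optional[int] = None
    for bp in items:
        if prev is not None and bp.sv_length - prev <= rel_tol * prev:
            groups[-1].append(bp)
        else:
            groups.append([bp])
        prev = bp.sv_length
    return groups


# ---------------------------------------------------------------------------
# Finalization

def _summarize(members: list[PutativeBreakpoint]) -> BreakpointCluster:
    notation = _kind_group(members[0]) if members[0].kind != SPLIT else members[0].notation
    if members[0].kind == CIGAR_DELETION:
        notation = "+-"
    pos_a = _median_int([m.locus_a[1] for m in members])
    locus_a = (members[0].locus_a[0], pos_a, members[0].locus_a[2])
    locus_b = None
    if members[0].locus_b is not None:
        pos_b = _median_int([m.locus_b[1] for m in members])
        locus_b = (members[0].locus_b[0], pos_b, members[0].locus_b[2])
    lengths = [m.sv_length for m in members]
    starts = [m.locus_a[1] for m in members]
    ends = [m.locus_b[1] for m in members if m.locus_b is not None]
    stats = {
        "sv_length_mean": float(np.mean(lengths)),
        "sv_length_std": float(np.std(lengths)),
        "sv_length_median": float(np.median(lengths)),
        "start_std": float(np.std(starts)),
        "end_std": float(np.std(ends)) if ends else 0.0,
        "mapq_mean": float(np.mean([m.mapq for m in members])),
    }
    cluster = BreakpointCluster(
        notation=notation,
        locus_a=locus_a,
        locus_b=locus_b,
        members=members,
        stats=stats,
    )
    hap: dict[str, dict[int, int]] = {TUMOR: {1: 0, 2: 0, UNPHASED: 0}, NORMAL: {1: 0, 2: 0, UNPHASED: 0}}
    for m in members:
        names = cluster.tumor_read_names if m.sample == TUMOR else cluster.normal_read_names
        if m.read_name not in names:
            names.add(m.read_name)
            h = m.haplotype if m.haplotype in (1, 2) else UNPHASED
            hap[m.sample][h] += 1
    cluster.haplotype_support = hap
    if notation == "INS":
        cluster.insert_size = int(np.median(lengths))
        seqs = [m.inserted_sequence for m in members if m.inserted_sequence]
        if seqs:
            cluster.inserted_sequence = sorted(seqs, key=len)[len(seqs) // 2]
    return cluster


def finalize_clusters(
    groups: list[list[PutativeBreakpoint]],
    window_default: int = DEFAULT_CLUSTER_WINDOW,
) -> list[BreakpointCluster]:
    """Summarize member groups into clusters and apply the SBND-only rule:
    a single-breakend cluster co-located with any non-SBND cluster is dropped,
    because other reads at the locus resolved the full adjacency."""
    clusters = [_summarize(g) for g in groups if g]
    non_sbnd = [c for c in clusters if c.notation != "SBND"]
    kept: list[BreakpointCluster] = []
    for c in clusters:
        if c.notation == "SBND":
            near = any(
                o.locus_a[0] == c.locus_a[0] and abs(o.locus_a[1] - c.locus_a[1]) <= window_default
                or (
                    o.locus_b is not None
                    and o.locus_b[0] == c.locus_a[0]
                    and abs(o.locus_b[1] - c.locus_a[1]) <= window_default
                )
                for o in non_sbnd
            )
            if near:
                continue
        kept.append(c)
    kept.sort(key=lambda c: (c.locus_a[0], c.locus_a[1], c.notation))
    return kept


def cluster_breakpoints(
    breakpoints: Iterable[PutativeBreakpoint],
    window_default: int = DEFAULT_CLUSTER_WINDOW,
    window_insertion: int = DEFAULT_INSERTION_WINDOW,
    mate_window: int = DEFAULT_MATE_WINDOW,
    insertion_size_rel_tol: float = DEFAULT_INSERTION_SIZE_REL_TOL,
) -> list[BreakpointCluster]:
    """Full clustering pipeline: position chaining, mate refinement,
    insertion-size grouping, finalization.  Permutation-invariant: members are
    sorted internally at every stage."""
    proto = cluster_by_position(list(breakpoints), window_default, window_insertion)
    refined: list[list[PutativeBreakpoint]] = []
    for group in proto:
        if not group:
            continue
        if group[0].kind == CIGAR_INSERTION:
            refined.extend(group_insertions_by_size(group, insertion_size_rel_tol))
        elif group[0].locus_b is not None:
            refined.extend(refine_by_mate(group, mate_window))
        else:
            refined.append(group)
    return finalize_clusters(refined, window_default)
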