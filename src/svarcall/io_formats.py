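"""Readers and writers for the standard formats the caller touches.

Alignments come in as coordinate-sorted, indexed BAM/CRAM; breakpoints go out
as VCF 4.2 breakend (BND) records; blacklists and panels come in as BED;
heterozygous SNP sites as VCF or TSV.  All internal coordinates are 0-based
half-open; conversion to the 1-based VCF convention happens only at emission
and parsing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import pysam

UNPHASED = 0  # haplotype code for reads without an HP tag

#: sample roles
TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class AlignmentSegment:
    """One mapped piece of a read (primary or supplementary alignment)."""

    read_name: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    mapq: int
    cigar: list[tuple[str, int]]  # e.g. [('M', 100), ('D', 50), ('M', 100)]
    is_supplementary: bool = False
    haplotype: int = UNPHASED  # 1, 2, or UNPHASED
    phase_set: Optional[int] = None
    query_start: int = 0  # offsets of this segment on the read (read orientation)
    query_end: int = 0
    sample: str = TUMOR
    clipped_left: int = 0  # soft/hard clip lengths flanking the aligned block
    clipped_right: int = 0
    query_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.contig}:{self.start}-{self.end}")

    @property
    def reference_span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, BED semantics."""

    contig: str
    start: int
    end: int
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start > end: {self.contig}:{self.start}-{self.end}")

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SnpSite:
    """A germline heterozygous SNP site (1-based position, VCF convention)."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    source: str = "matched_germline"  # or "population_panel"

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.contig}:{self.position}")


class Breakend(NamedTuple):
    """Normalized breakend: contig, 0-based position, orientation, SV type.

    orientation '+' means the retained sequence lies to the left of the
    breakend (the adjacency continues rightward); '-' the mirror case.
    """

    contig: str
    position: int
    orientation: str
    svtype: str = "BND"


_CIGAR_OPS = "MIDNSHP=XB"
_REF_CONSUMING = set("MDN=X")
_QUERY_CONSUMING = set("MIS=X")


def cigar_tuples_to_str(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{length}{op}" for op, length in cigar)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            out.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"bad CIGAR character {ch!r} in {cigar!r}")
    if num:
        raise ValueError(f"trailing number in CIGAR {cigar!r}")
    return out


def cigar_reference_length(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(length for op, length in cigar if op in _REF_CONSUMING)


def cigar_query_alignment(cigar: Sequence[tuple[str, int]], strand: str) -> tuple[int, int, int, int]:
    """Return (query_start, query_end, clip_left, clip_right) in read coordinates.

    Soft and hard clips at either end offset the aligned block; for a
    reverse-strand alignment the trailing clip in the CIGAR corresponds to the
    start of the read as sequenced.
    """
    clip_head = 0
    i = 0
    while i < len(cigar) and cigar[i][0] in "SH":
        clip_head += cigar[i][1]
        i += 1
    clip_tail = 0
    j = len(cigar) - 1
    while j >= 0 and cigar[j][0] in "SH":
        clip_tail += cigar[j][1]
        j -= 1
    aligned = sum(length for op, length in cigar if op in "MI=X")
    if strand == "+":
        qs = clip_head
        clip_left, clip_right = clip_head, clip_tail
    else:
        qs = clip_tail
        clip_left, clip_right = clip_tail, clip_head
    return qs, qs + aligned, clip_left, clip_right


def segment_from_record(rec: pysam.AlignedSegment, sample: str) -> AlignmentSegment:
    """Convert a pysam record into an AlignmentSegment."""
    strand = "-" if rec.is_reverse else "+"
    cigar = [( _CIGAR_OPS[op], length) for op, length in rec.cigartuples or []]
    qs, qe, cl, cr = cigar_query_alignment(cigar, strand)
    hp = rec.get_tag("HP") if rec.has_tag("HP") else UNPHASED
    ps = rec.get_tag("PS") if rec.has_tag("PS") else None
    return AlignmentSegment(
        read_name=rec.query_name,
        contig=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        strand=strand,
        mapq=rec.mapping_quality,
        cigar=cigar,
        is_supplementary=rec.is_supplementary,
        haplotype=int(hp),
        phase_set=int(ps) if ps is not None else None,
        query_start=qs,
        query_end=qe,
        sample=sample,
        clipped_left=cl,
        clipped_right=cr,
        query_sequence=rec.query_sequence,
    )


def effective_mapq_threshold(min_mapq: float, sample_role: str, normal_leniency_fraction: float = 0.5) -> float:
    """MAPQ gate for a sample: the normal gate is relaxed by a fraction so that
    germline evidence is not missed when discounting somatic candidates."""
    if sample_role == NORMAL:
        return min_mapq * normal_leniency_fraction
    return float(min_mapq)


def read_alignments(
    path: str,
    region: Optional[tuple[str, Optional[int], Optional[int]]] = None,
    sample_role: str = TUMOR,
    min_mapq: float = 5,
    normal_leniency_fraction: float = 0.5,
    with_segments: bool = True,
) -> Iterator[pysam.AlignedSegment | AlignmentSegment]:
    """Stream primary and supplementary alignments passing the sample's MAPQ gate.

    Secondary, unmapped and duplicate-flagged records are excluded.  The
    effective threshold is ``min_mapq`` for the tumor and
    ``min_mapq * normal_leniency_fraction`` for the normal, compared as a real
    number (no rounding).
    """
    if not (0 < normal_leniency_fraction <= 1):
        raise ValueError("normal_leniency_fraction must be in (0, 1]")
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    threshold = effective_mapq_threshold(min_mapq, sample_role, normal_leniency_fraction)
    with pysam.AlignmentFile(path) as bam:
        if region is not None:
            try:
                bam.check_index()
            except (AttributeError, ValueError) as exc:
                raise FileNotFoundError(f"alignment index missing for {path}") from exc
            contig = region[0]
            if contig not in bam.references:
                raise ValueError(f"unknown contig {contig!r} in {path}")
            it = bam.fetch(contig, region[1], region[2])
        else:
            it = bam.fetch(until_eof=True)
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            if rec.mapping_quality < threshold:
                continue
            yield segment_from_record(rec, sample_role) if with_segments else rec


# ---------------------------------------------------------------------------
# VCF breakend output

_VCF_FILTERS = ("LIKELY_NOISE", "LOW_SUPPORT", "LOW_AF", "GERMLINE")

_VCF_INFO_LINES = [
    ('SVTYPE', '1', 'String', 'Type of structural variant'),
    ('MATEID', '1', 'String', 'ID of mate breakend'),
    ('CLASS', '1', 'String', 'Predicted class of the breakpoint (somatic/noise)'),
    ('NOTATION', '1', 'String', 'Breakpoint notation: +-, -+, ++, --, INS or SBND'),
    ('TUMOUR_SUPPORT', '1', 'Integer', 'Number of tumor reads supporting the breakpoint'),
    ('NORMAL_SUPPORT', '1', 'Integer', 'Number of normal reads supporting the breakpoint'),
    ('AF', '1', 'Float', 'Tumor allele fraction of the breakpoint'),
    ('SVLEN', '1', 'Integer', 'Length of the structural variant'),
    ('INSSEQ', '1', 'String', 'Inserted sequence for insertion events'),
    ('HP_SUPPORT', '3', 'Integer', 'Tumor supporting reads on haplotype 1, 2 and unphased'),
    ('PS', '1', 'Integer', 'Phase set of supporting reads when phased'),
    ('RESCUED', '0', 'Flag', 'Breakpoint rescued by a nearby copy-number changepoint'),
    ('CONF_REGION', '1', 'String', 'Conformal prediction region (somatic/noise/both/null)'),
]


def _bnd_alt(orientation: str, mate: Optional[tuple[str, int, str]], ref: str = "N") -> str:
    """VCF ALT for a breakend with the given orientation and (optional) mate.

    The mate position is given 0-based and converted here.
    """
    if mate is None:
        return f"{ref}." if orientation == "+" else f".{ref}"
    mcontig, mpos0, morient = mate
    loc = f"{mcontig}:{mpos0 + 1}"
    bracket = "]" if morient == "+" else "["
    piece = f"{bracket}{loc}{bracket}"
    return f"{ref}{piece}" if orientation == "+" else f"{piece}{ref}"


def write_breakpoint_vcf(clusters: Iterable, path: str, contigs: dict[str, int], sample_name: str = "TUMOUR") -> None:
    """Write finalized breakpoint clusters as a VCF 4.2 breakend file.

    Paired breakends are emitted as two BND records with reciprocal MATEID;
    insertions as a single record carrying the inserted sequence; single
    breakends with the single-breakend ALT syntax and SVTYPE=SBND.
    """
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for filt in _VCF_FILTERS:
        header.filters.add(filt, None, None, f"Breakpoint filtered as {filt}")
    for name, number, vtype, desc in _VCF_INFO_LINES:
        header.info.add(name, number, vtype, desc)
    header.add_sample(sample_name)
    header.formats.add('GT', '1', 'String', 'Genotype')

    try:
        vcf = pysam.VariantFile(path, "w", header=header)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    with vcf:
        for idx, cluster in enumerate(sorted(clusters, key=_cluster_sort_key)):
            for rec in _cluster_records(vcf, cluster, idx):
                vcf.write(rec)


def _cluster_sort_key(cluster) -> tuple:
    return (cluster.locus_a[0], cluster.locus_a[1], cluster.notation)


def _common_info(cluster) -> dict:
    info = {
        'CLASS': getattr(cluster, "class_label", None) or ".",
        'NOTATION': cluster.notation,
        'TUMOUR_SUPPORT': len(cluster.tumor_read_names),
        'NORMAL_SUPPORT': len(cluster.normal_read_names),
    }
    af = getattr(cluster, "allele_fraction", None)
    if af is not None:
        info['AF'] = float(af)
    svlen = cluster.stats.get("sv_length_median") if getattr(cluster, "stats", None) else None
    if svlen is not None:
        info['SVLEN'] = int(round(svlen))
    hp = getattr(cluster, "haplotype_support", None)
    if hp:
        t = hp.get(TUMOR, {})
        info['HP_SUPPORT'] = (t.get(1, 0), t.get(2, 0), t.get(UNPHASED, 0))
    if getattr(cluster, "rescued", False):
        info['RESCUED'] = True
    region = getattr(cluster, "conformal_region", None)
    if region:
        info['CONF_REGION'] = region
    return info


def _cluster_records(vcf: pysam.VariantFile, cluster, idx: int):
    filt = getattr(cluster, "filter_status", None) or "PASS"
    info = _common_info(cluster)
    ca, pa, oa = cluster.locus_a

    def base_record(contig: str, pos0: int, alt: str, rid: str):
        rec = vcf.new_record(contig=contig, start=pos0, alleles=("N", alt), id=rid, filter=filt)
        for key, val in info.items():
            rec.info[key] = val
        rec.samples[0]['GT'] = (None,)
        return rec

    if cluster.notation == "INS":
        rec = base_record(ca, pa, "N" + (cluster.inserted_sequence or "<INS>"), f"SV{idx}")
        rec.info['SVTYPE'] = "INS"
        rec.info['SVLEN'] = int(cluster.insert_size or 0)
        if cluster.inserted_sequence:
            rec.info['INSSEQ'] = cluster.inserted_sequence
        yield rec
    elif cluster.notation == "SBND":
        rec = base_record(ca, pa, _bnd_alt(oa, None), f"SV{idx}")
        rec.info['SVTYPE'] = "SBND"
        yield rec
    else:
        cb, pb, ob = cluster.locus_b
        rec1 = base_record(ca, pa, _bnd_alt(oa, (cb, pb, ob)), f"SV{idx}_1")
        rec1.info['SVTYPE'] = "BND"
        rec1.info['MATEID'] = f"SV{idx}_2"
        rec2 = base_record(cb, pb, _bnd_alt(ob, (ca, pa, oa)), f"SV{idx}_2")
        rec2.info['SVTYPE'] = "BND"
        rec2.info['MATEID'] = f"SV{idx}_1"
        yield rec1
        yield rec2


# ---------------------------------------------------------------------------
# VCF breakend / SV input

def _parse_bnd_alt(alt: str) -> tuple[str, Optional[tuple[str, int, str]]]:
    """Parse a BND ALT; return (orientation, mate or None for single breakends)."""
    if "[" not in alt and "]" not in alt:
        # single breakend: 's.' or '.s'
        if alt.endswith("."):
            return "+", None
        if alt.startswith("."):
            return "-", None
        raise ValueError(f"unparseable breakend ALT {alt!r}")
    bracket = "[" if "[" in alt else "]"
    fields = alt.split(bracket)
    # form t[...[ or ]...]t
    orientation = "+" if alt[0] not in "[]" else "-"
    loc = fields[1]
    mcontig, mpos = loc.rsplit(":", 1)
    morient = "+" if bracket == "]" else "-"
    return orientation, (mcontig, int(mpos) - 1, morient)


_SVTYPE_ORIENTATIONS = {
    "DEL": ("+", "-"),
    "DUP": ("-", "+"),
    "INV": ("+", "+"),
}


def read_truth_vcf(path: str, dialect: str = "auto") -> set[Breakend]:
    """Read an SV VCF into a normalized breakend set.

    Handles both per-breakend BND files (each breakend one line, deduplicated
    via mate coordinates) and single-line records with SVTYPE/END (expanded to
    two breakends, except insertions which stay single records).
    """
    breakends: set[Breakend] = set()
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    with vcf:
        for n, rec in enumerate(vcf, start=1):
            try:
                svtype = rec.info.get("SVTYPE", "BND")
                pos0 = rec.start
                if svtype in ("BND", "SBND"):
                    alt = rec.alts[0]
                    orientation, mate = _parse_bnd_alt(alt)
                    kind = "SBND" if mate is None else "BND"
                    breakends.add(Breakend(rec.contig, pos0, orientation, kind))
                    if mate is not None:
                        breakends.add(Breakend(mate[0], mate[1], mate[2], "BND"))
                elif svtype == "INS":
                    breakends.add(Breakend(rec.contig, pos0, "+", "INS"))
                else:
                    end0 = int(rec.stop) - 1  # rec.stop is 1-based END
                    o1, o2 = _SVTYPE_ORIENTATIONS.get(svtype, ("+", "-"))
                    breakends.add(Breakend(rec.contig, pos0, o1, "BND"))
                    breakends.add(Breakend(rec.contig, end0, o2, "BND"))
            except (KeyError, IndexError, ValueError) as exc:
                raise ValueError(f"malformed VCF record at line-record {n} of {path}: {exc}") from exc
    return breakends


# ---------------------------------------------------------------------------
# BED intervals and SNP sites

def read_intervals(path: str) -> list[GenomicInterval]:
    """Read BED (0-based half-open) intervals, validated and sorted.

    Overlapping intervals are preserved as given (no merging).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise ValueError(f"{path}:{n}: start > end ({start} > {end})")
            label = fields[3] if len(fields) > 3 else None
            out.append(GenomicInterval(contig, start, end, label))
    return sorted(out)


def read_snp_sites(path: str, source: str = "matched_germline") -> list[SnpSite]:
    """Read heterozygous SNP sites from a VCF or a TSV (contig, pos, ref, alt)."""
    sites: list[SnpSite] = []
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                if rec.alts is None or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                    continue
                sites.append(SnpSite(rec.contig, rec.pos, rec.ref, rec.alts[0], source))
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                contig, pos, ref, alt = line.split()[:4]
                sites.append(SnpSite(contig, int(pos), ref, alt, source))
    return sorted(sites, key=lambda s: (s.contig, s.position))


def sort_and_index_bam(path: str) -> None:
    """Coordinate-sort a BAM in place and build its index."""
    tmp = path + ".sort.tmp.bam"
    pysam.sort("-o", tmp, path)
    os.replace(tmp, path)
    pysam.index(path)
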