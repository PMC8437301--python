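"""Split-read extraction and the stringent single-read junction filter.

A split read is a single sequencing read aligned in exactly two pieces: a
soft-clipped primary alignment plus one supplementary alignment recorded in
the primary's ``SA:Z`` tag.  Because every junction is supported by just one
read, the filter is deliberately stringent: both aligned segments must reach
a minimum aligned length (default 40bp), both must carry the aligner's
maximum mapping quality (default 60, BWA-MEM's ceiling), and neither segment
may be clipped on both of its ends.  Junctions joining the start and end of
a circular contig (the mitochondrial chromosome) are alignment artefacts of
linearising a circle and are removed.

All coordinates are 0-based half-open internally; SAM input is converted at
parse time and BEDPE output is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .genome import GenomeModel

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

REJECT_SHORT = "short_segment"
REJECT_MAPQ = "low_mapq"
REJECT_DOUBLE_CLIP = "double_clipped"


class AlignmentDataError(ValueError):
    """Fatal stream-level problems (missing file, contig mismatch, ...)."""


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned piece of a split read.

    ``read_start``/``read_end`` delimit the part of the *original* read the
    segment consumes (clips excluded), expressed in original-read orientation
    regardless of the alignment strand, so the two segments of a split read
    can be compared directly in read space.
    """

    contig: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    read_start: int
    read_end: int
    clip_left: int
    clip_right: int

    @property
    def aligned_read_length(self) -> int:
        return self.read_end - self.read_start

    @property
    def double_clipped(self) -> bool:
        return self.clip_left > 0 and self.clip_right > 0

    @property
    def junction_proximal(self) -> int:
        """Reference base adjacent to the clipped (junction) side, 0-based."""
        if self.clip_left > 0:
            return self.ref_start
        return self.ref_end - 1


def segment_from_cigar(
    cigar: str, contig: str, pos0: int, strand: str, mapq: int
) -> AlignedSegment:
    """Build an :class:`AlignedSegment` from a CIGAR string.

    ``pos0`` is the 0-based leftmost reference coordinate.  Raises
    ``ValueError`` on malformed CIGAR.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(n + op for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    lens = [(int(n), op) for n, op in ops]
    clip_left = sum(n for i, (n, op) in enumerate(lens) if op in "SH" and i < _first_aln(lens))
    clip_right = sum(n for i, (n, op) in enumerate(lens) if op in "SH" and i >= _last_aln(lens))
    read_consumed = sum(n for n, op in lens if op in "MI=X")
    ref_consumed = sum(n for n, op in lens if op in "MDN=X")
    if read_consumed == 0:
        raise ValueError(f"CIGAR {cigar!r} consumes no read bases")
    read_length = clip_left + read_consumed + clip_right
    if strand == "+":
        read_start = clip_left
    else:
        # record is on the reverse strand: flip into original-read orientation
        read_start = clip_right
    return AlignedSegment(
        contig=contig,
        ref_start=pos0,
        ref_end=pos0 + ref_consumed,
        strand=strand,
        mapq=mapq,
        read_start=read_start,
        read_end=read_start + read_consumed,
        clip_left=clip_left,
        clip_right=clip_right,
    )


def _first_aln(lens) -> int:
    for i, (_, op) in enumerate(lens):
        if op not in "SH":
            return i
    return len(lens)


def _last_aln(lens) -> int:
    for i in range(len(lens) - 1, -1, -1):
        if lens[i][1] not in "SH":
            return i + 1
    return 0


@dataclass(frozen=True)
class SplitRead:
    read_id: str
    segment_primary: AlignedSegment
    segment_supplementary: AlignedSegment
    read_length: int

    @property
    def segments(self) -> tuple[AlignedSegment, AlignedSegment]:
        return (self.segment_primary, self.segment_supplementary)


@dataclass
class FilterConfig:
    """The single-read filter: 40bp minimum segments, maximal MAPQ, one-sided clips."""

    min_segment_length: int = 40
    required_mapq: int = 60
    forbid_double_clipped: bool = True
    circular_end_window: int = 126  # one read length

    def __post_init__(self) -> None:
        if self.min_segment_length < 1:
            raise ValueError("min_segment_length must be >= 1")


@dataclass(frozen=True)
class Junction:
    """Two breakends in canonical order plus an optional breakpoint signature."""

    contig_a: str
    pos_a: int
    strand_a: str
    contig_b: str
    pos_b: int
    strand_b: str
    sig_class: str | None = None
    sig_length: int | None = None
    sample_id: str = ""
    read_id: str = ""


@dataclass
class ExtractionStats:
    n_records: int = 0
    n_mapped_primary: int = 0
    n_split_candidates: int = 0
    n_multi_supplementary: int = 0
    n_parse_errors: int = 0
    n_indel_reads: int = 0
    rejections: dict = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1


def _parse_sa_entries(sa_tag: str) -> list[tuple[str, int, str, str, int]]:
    """Parse an ``SA:Z`` value into (contig, pos0, strand, cigar, mapq) tuples."""
    out = []
    for entry in sa_tag.rstrip(";").split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        if len(parts) != 6:
            raise ValueError(f"malformed SA entry {entry!r}")
        rname, pos, strand, cigar, mapq, _nm = parts
        out.append((rname, int(pos) - 1, strand, cigar, int(mapq)))
    return out


def _cigar_has_indel(cigartuples) -> bool:
    return any(op in (1, 2) for op, _ in cigartuples or ())


def iter_alignments(path: str | Path):
    """Yield pysam records from a SAM/BAM file; fatal error if unreadable."""
    path = Path(path)
    if not path.exists():
        raise AlignmentDataError(f"alignment file not found: {path}")
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if not fh.references:
            raise AlignmentDataError(f"{path}: SAM header has no @SQ lines")
        yield from fh


def scan_stream(path: str | Path) -> tuple[list[SplitRead], ExtractionStats]:
    """Single pass over an alignment stream.

    Collects split reads (exactly one primary with exactly one SA entry),
    counts mapped primary records and indel-bearing non-split reads, and
    tallies parse errors and multi-supplementary discards.
    """
    stats = ExtractionStats()
    splits: list[SplitRead] = []
    for rec in iter_alignments(path):
        stats.n_records += 1
        if rec.is_unmapped or rec.is_secondary:
            continue
        if rec.is_supplementary:
            continue  # represented via the primary's SA tag
        stats.n_mapped_primary += 1
        if not rec.has_tag("SA"):
            if _cigar_has_indel(rec.cigartuples):
                stats.n_indel_reads += 1
            continue
        stats.n_split_candidates += 1
        try:
            sa_entries = _parse_sa_entries(rec.get_tag("SA"))
            if len(sa_entries) != 1:
                stats.n_multi_supplementary += 1
                continue
            primary = segment_from_cigar(
                rec.cigarstring,
                rec.reference_name,
                rec.reference_start,
                "-" if rec.is_reverse else "+",
                rec.mapping_quality,
            )
            sc, sp, sstrand, scigar, smapq = sa_entries[0]
            supp = segment_from_cigar(scigar, sc, sp, sstrand, smapq)
            read_length = rec.infer_read_length()
        except (ValueError, TypeError) as exc:
            stats.n_parse_errors += 1
            logger.warning("skipping unparsable split read %s: %s", rec.query_name, exc)
            continue
        splits.append(SplitRead(rec.query_name, primary, supp, read_length))
    return splits, stats


def extract_split_reads(path: str | Path) -> list[SplitRead]:
    """Split reads with exactly one primary + one supplementary alignment."""
    return scan_stream(path)[0]


def count_indel_reads(path: str | Path) -> int:
    """Non-split mapped reads whose CIGAR contains at least one I or D op.

    Each read counts once no matter how many indel ops it carries; split
    reads are excluded even if their CIGARs contain indels.
    """
    return scan_stream(path)[1].n_indel_reads


def filter_split_read(
    split_read: SplitRead,
    config: FilterConfig | None = None,
    contig_rank: dict[str, int] | None = None,
    sample_id: str = "",
) -> tuple[Junction | None, str | None]:
    """Apply the single-read filter; return (junction, None) or (None, reason).

    Rejection reasons are ``short_segment``, ``low_mapq`` and
    ``double_clipped``, checked in that order.
    """
    config = config or FilterConfig()
    segs = split_read.segments
    if any(s.aligned_read_length < config.min_segment_length for s in segs):
        return None, REJECT_SHORT
    if any(s.mapq != config.required_mapq for s in segs):
        return None, REJECT_MAPQ
    if config.forbid_double_clipped and any(s.double_clipped for s in segs):
        return None, REJECT_DOUBLE_CLIP
    return make_junction(split_read, contig_rank, sample_id=sample_id), None


def make_junction(
    split_read: SplitRead,
    contig_rank: dict[str, int] | None = None,
    sample_id: str = "",
    signature=None,
) -> Junction:
    """Canonically ordered junction from a split read's proximal coordinates."""
    ends = [
        (s.contig, s.junction_proximal, s.strand) for s in split_read.segments
    ]

    def key(e):
        contig, pos, strand = e
        rank = contig_rank.get(contig, len(contig_rank)) if contig_rank else contig
        return (rank, pos, strand)

    a, b = sorted(ends, key=key)
    sig_class = signature.sig_class if signature is not None else None
    sig_length = signature.length if signature is not None else None
    return Junction(
        contig_a=a[0], pos_a=a[1], strand_a=a[2],
        contig_b=b[0], pos_b=b[1], strand_b=b[2],
        sig_class=sig_class, sig_length=sig_length,
        sample_id=sample_id, read_id=split_read.read_id,
    )


def apply_circularity_filter(
    junctions: list[Junction],
    genome: GenomeModel,
    end_window: int = 126,
) -> list[Junction]:
    """Drop artefactual junctions spanning a circular contig's linearisation point.

    A junction is removed iff both breakends lie on the same circular contig
    with one within *end_window* of position 0 and the other within
    *end_window* of the contig end.
    """
    circular = set(genome.circular_contigs)
    lengths = genome.lengths
    kept = []
    for j in junctions:
        if j.contig_a == j.contig_b and j.contig_a in circular:
            lo, hi = sorted((j.pos_a, j.pos_b))
            length = lengths[j.contig_a]
            if lo < end_window and hi >= length - end_window:
                continue
        kept.append(j)
    return kept


@dataclass
class SampleMetrics:
    sample_id: str
    day: int | None = None
    genotype: str = ""
    replicate: int | None = None
    mapped_reads: int = 0
    junction_count: int = 0
    indel_read_count: int = 0

    @property
    def jpmr(self) -> float:
        return self.junction_count / self.mapped_reads if self.mapped_reads else 0.0

    @property
    def ipmr(self) -> float:
        return self.indel_read_count / self.mapped_reads if self.mapped_reads else 0.0


def junctions_to_frame(junctions: list[Junction], **extra) -> pd.DataFrame:
    rows = []
    for j in junctions:
        row = {
            "sample_id": j.sample_id,
            "contig_a": j.contig_a, "pos_a": j.pos_a, "strand_a": j.strand_a,
            "contig_b": j.contig_b, "pos_b": j.pos_b, "strand_b": j.strand_b,
            "sig_class": j.sig_class, "sig_length": j.sig_length,
            "read_id": j.read_id,
        }
        row.update(extra)
        rows.append(row)
    cols = ["sample_id", "contig_a", "pos_a", "strand_a", "contig_b", "pos_b",
            "strand_b", "sig_class", "sig_length", "read_id", *extra]
    return pd.DataFrame(rows, columns=cols)


def call_sample(
    sam_path: str | Path,
    genome: GenomeModel,
    config: FilterConfig | None = None,
    sample_meta: dict | None = None,
) -> tuple[pd.DataFrame, SampleMetrics, ExtractionStats]:
    """Full per-sample pipeline: extract -> filter -> circularity -> classify.

    Returns the junction table, the sample's rate metrics and the extraction
    / rejection tallies.  The SAM header contigs must all be present in the
    genome model.
    """
    from .signatures import classify_junction

    config = config or FilterConfig()
    meta = sample_meta or {}
    sample_id = meta.get("sample_id", Path(sam_path).stem)

    if not Path(sam_path).exists():
        raise AlignmentDataError(f"alignment file not found: {sam_path}")
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        unknown = set(fh.references) - set(genome.contig_names)
    if unknown:
        raise AlignmentDataError(
            f"{sam_path}: contigs {sorted(unknown)} absent from the genome model"
        )

    splits, stats = scan_stream(sam_path)
    rank = genome.rank
    junctions: list[Junction] = []
    for sr in splits:
        junction, reason = filter_split_read(sr, config, rank, sample_id=sample_id)
        if junction is None:
            stats.reject(reason)
            continue
        sig = classify_junction(sr)
        junctions.append(
            make_junction(sr, rank, sample_id=sample_id, signature=sig)
        )
    junctions = apply_circularity_filter(junctions, genome, config.circular_end_window)

    metrics = SampleMetrics(
        sample_id=sample_id,
        day=meta.get("day"),
        genotype=meta.get("genotype", ""),
        replicate=meta.get("replicate"),
        mapped_reads=stats.n_mapped_primary,
        junction_count=len(junctions),
        indel_read_count=stats.n_indel_reads,
    )
    df = junctions_to_frame(junctions)
    if "day" in meta:
        df["day"] = meta["day"]
    if "replicate" in meta:
        df["replicate"] = meta["replicate"]
    if "genotype" in meta:
        df["genotype"] = meta["genotype"]
    return df, metrics, stats
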