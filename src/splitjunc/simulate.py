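"""Synthetic split-read fixtures: planted rearrangements, SAM records, ageing series.

The generator emits *already-aligned* SAM rather than FASTQ: every planted
rearrangement becomes one chimeric read written as a soft-clipped primary
alignment plus a hard-clipped supplementary cross-referenced by an ``SA:Z``
tag, exactly the evidence structure the caller consumes.  A matching truth
table records each event's breakend coordinates and breakpoint signature so
downstream calling and classification can be scored exactly.

Microhomology is planted by *editing the reference* so both joined loci
genuinely share the seed sequence; blunt joins are exact concatenations; and
non-homologous insertions carry bases found at neither flank boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Contig, Feature, GenomeModel, GenomeError, random_positions

DEFAULT_READ_LENGTH = 126
MIN_SEGMENT = 40  # mirrors the caller's minimum aligned-segment length

SIG_MICROHOMOLOGY = "microhomology"
SIG_BLUNT = "blunt"
SIG_INSERTION = "insertion"

JUNCTION_COLUMNS = [
    "sample_id",
    "day",
    "replicate",
    "genotype",
    "contig_a",
    "pos_a",
    "strand_a",
    "contig_b",
    "pos_b",
    "strand_b",
    "sig_class",
    "sig_length",
    "read_id",
]


class SimulationError(ValueError):
    pass


@dataclass
class PlantedRearrangement:
    """Ground truth for one planted junction.

    ``breakend_a``/``breakend_b`` are (contig, coordinate, strand) with the
    coordinate being the junction-proximal reference base of each joined
    segment (0-based).  ``read_offset`` is the read coordinate at which the
    second segment starts; for a microhomology of length ``m`` the two
    segments overlap by ``m`` read bases.
    """

    breakend_a: tuple[str, int, str]
    breakend_b: tuple[str, int, str]
    signature_class: str
    signature_length: int
    inserted_seq: str = ""
    read_offset: int = DEFAULT_READ_LENGTH // 2
    read_length: int = DEFAULT_READ_LENGTH
    recoverable: bool = True
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.signature_class not in (SIG_MICROHOMOLOGY, SIG_BLUNT, SIG_INSERTION):
            raise SimulationError(f"unknown signature class {self.signature_class!r}")
        if (self.signature_class == SIG_BLUNT) != (self.signature_length == 0):
            raise SimulationError("blunt signature iff length == 0")
        if self.signature_class == SIG_INSERTION and len(self.inserted_seq) != self.signature_length:
            raise SimulationError("insertion length must match inserted_seq")

    @property
    def segment_read_lengths(self) -> tuple[int, int]:
        """Read-space lengths of the two aligned segments."""
        o, L = self.read_offset, self.read_length
        if self.signature_class == SIG_MICROHOMOLOGY:
            return o + self.signature_length, L - o
        if self.signature_class == SIG_BLUNT:
            return o, L - o
        return o, L - o - self.signature_length

    def signed_length(self) -> int:
        if self.signature_class == SIG_INSERTION:
            return -self.signature_length
        return self.signature_length


@dataclass
class AgeingSeriesDesign:
    """Study design for a chronological-ageing sequencing time course.

    Defaults emulate a six-timepoint, eight-replicate design sequenced with
    126nt reads; junction/indel rates are expected events per mapped read
    and may vary by day to model age-dependent accumulation.
    """

    days: Sequence[int] = (0, 1, 2, 3, 4, 5)
    replicates: int = 8
    junction_rate_per_day: Sequence[float] = (1e-4, 2e-4, 4e-4, 8e-4, 1.6e-3, 3.2e-3)
    indel_rate_per_day: Sequence[float] = (5e-4,) * 6
    background_reads: int = 5_000
    read_length: int = DEFAULT_READ_LENGTH
    genotype: str = "wt"
    coding_depletion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.junction_rate_per_day) != len(self.days):
            raise SimulationError("one junction rate per day required")
        if len(self.indel_rate_per_day) != len(self.days):
            raise SimulationError("one indel rate per day required")
        if any(r < 0 for r in self.junction_rate_per_day) or any(
            r < 0 for r in self.indel_rate_per_day
        ):
            raise SimulationError("rates must be >= 0")
        if self.read_length <= 2 * MIN_SEGMENT:
            raise SimulationError("read length must exceed twice the minimum segment length")


@dataclass
class TruthTable:
    """Planted events per sample; the oracle for calling and classification."""

    events: list[PlantedRearrangement] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        ids = [e.read_id for e in self.events if e.read_id]
        if len(ids) != len(set(ids)):
            raise SimulationError("carrier read ids must be unique")

    def recoverable(self) -> list[PlantedRearrangement]:
        return [e for e in self.events if e.recoverable]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "contig_a": e.breakend_a[0],
                    "pos_a": e.breakend_a[1],
                    "strand_a": e.breakend_a[2],
                    "contig_b": e.breakend_b[0],
                    "pos_b": e.breakend_b[1],
                    "strand_b": e.breakend_b[2],
                    "sig_class": e.signature_class,
                    "sig_length": e.signature_length,
                    "read_offset": e.read_offset,
                    "recoverable": e.recoverable,
                    "read_id": e.read_id,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "contig_a", "pos_a", "strand_a", "contig_b", "pos_b",
                "strand_b", "sig_class", "sig_length", "read_offset", "recoverable",
                "read_id",
            ],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def _as_editable(genome: GenomeModel) -> dict[str, bytearray]:
    return {c.name: bytearray(c.seq.encode("ascii")) for c in genome.contigs}


def _rebuild(genome: GenomeModel, seqs: dict[str, bytearray]) -> GenomeModel:
    contigs = [Contig(c.name, seqs[c.name].decode("ascii"), c.circular) for c in genome.contigs]
    return GenomeModel(contigs, list(genome.features))


def _check_locus(genome: GenomeModel, contig: str, pos: int, margin: int = 40) -> None:
    length = genome.lengths[contig]
    circular = contig in genome.circular_contigs
    if not circular and not margin <= pos < length - margin:
        raise SimulationError(
            f"locus {contig}:{pos} closer than {margin}bp to a linear contig end"
        )
    if not 0 <= pos < length:
        raise SimulationError(f"locus {contig}:{pos} outside contig")


def plant_rearrangement(
    genome: GenomeModel,
    sig_class: str,
    length: int,
    locus_a: tuple[str, int],
    locus_b: tuple[str, int],
    *,
    read_length: int = DEFAULT_READ_LENGTH,
    read_offset: int | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[PlantedRearrangement, GenomeModel]:
    """Plant one rearrangement and return (truth event, edited genome).

    ``locus_a`` is the junction-proximal base of the left-joined segment and
    ``locus_b`` the junction-proximal (first) base of the right-joined
    segment.  For the microhomology class the reference is edited so that the
    ``length`` bases starting at ``locus_b`` equal the ``length`` bases ending
    at ``locus_a``, i.e. both joined loci genuinely share the seed sequence.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seqs = _as_editable(genome)
    event = _plant_into(
        seqs, genome, sig_class, length, locus_a, locus_b,
        read_length=read_length, read_offset=read_offset, rng=rng,
    )
    return event, _rebuild(genome, seqs)


def _plant_into(
    seqs: dict[str, bytearray],
    genome: GenomeModel,
    sig_class: str,
    length: int,
    locus_a: tuple[str, int],
    locus_b: tuple[str, int],
    *,
    read_length: int,
    read_offset: int | None,
    rng: np.random.Generator,
) -> PlantedRearrangement:
    ca, pa = locus_a
    cb, pb = locus_b
    _check_locus(genome, ca, pa)
    _check_locus(genome, cb, pb)
    if sig_class == SIG_MICROHOMOLOGY:
        if not 1 <= length <= 20:
            raise SimulationError("microhomology length must be 1-20")
    m = length if sig_class == SIG_MICROHOMOLOGY else 0
    ins_len = length if sig_class == SIG_INSERTION else 0
    if read_offset is None:
        read_offset = (read_length - m + ins_len) // 2
    o = read_offset
    seg_a = o + m if sig_class == SIG_MICROHOMOLOGY else o
    seg_b = read_length - o - ins_len if sig_class == SIG_INSERTION else read_length - o
    if seg_a > pa + 1:
        raise SimulationError("left flank shorter than requested segment")
    if pb + seg_b > len(seqs[cb]):
        raise SimulationError("right flank shorter than requested segment")
    if sig_class == SIG_MICROHOMOLOGY:
        if m > seg_a or m > seg_b:
            raise SimulationError("requested microhomology longer than flank")
        seed_seq = bytes(seqs[ca][pa - m + 1 : pa + 1])
        seqs[cb][pb : pb + m] = seed_seq
    inserted = ""
    if sig_class == SIG_INSERTION:
        if length < 1:
            raise SimulationError("insertion length must be >= 1")
        inserted = _novel_insert(seqs, ca, pa, cb, pb, length, rng)
    recoverable = min(seg_a, seg_b) >= MIN_SEGMENT and seg_a <= read_length and seg_b <= read_length
    return PlantedRearrangement(
        breakend_a=(ca, pa, "+"),
        breakend_b=(cb, pb, "+"),
        signature_class=sig_class,
        signature_length=length,
        inserted_seq=inserted,
        read_offset=o,
        read_length=read_length,
        recoverable=recoverable,
    )


def _novel_insert(seqs, ca, pa, cb, pb, length, rng) -> str:
    """Random insert whose boundary bases differ from both flank boundaries."""
    bases = "ACGT"
    ins = [bases[i] for i in rng.integers(0, 4, size=length)]
    left_flank = chr(seqs[ca][pa])  # base the insert follows
    right_flank = chr(seqs[cb][pb])  # base the insert precedes
    if ins[0] == right_flank:
        ins[0] = bases[(bases.index(ins[0]) + 1) % 4]
    if ins[-1] == left_flank:
        ins[-1] = bases[(bases.index(ins[-1]) + 1) % 4]
        if length == 1 and ins[0] == right_flank:
            choices = [b for b in bases if b not in (left_flank, right_flank)]
            ins[0] = choices[int(rng.integers(0, len(choices)))]
    return "".join(ins)


# ---------------------------------------------------------------------------
# SAM synthesis
# ---------------------------------------------------------------------------

def _chimeric_read_seq(seqs: dict[str, bytearray], ev: PlantedRearrangement) -> str:
    ca, pa, _ = ev.breakend_a
    cb, pb, _ = ev.breakend_b
    o, L, m = ev.read_offset, ev.read_length, 0
    if ev.signature_class == SIG_MICROHOMOLOGY:
        m = ev.signature_length
    seg_a, seg_b = ev.segment_read_lengths
    a_part = bytes(seqs[ca][pa - seg_a + 1 : pa + 1]).decode("ascii")
    b_part = bytes(seqs[cb][pb + m : pb + seg_b]).decode("ascii")
    return a_part + ev.inserted_seq + b_part


def sam_header(genome: GenomeModel) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for c in genome.contigs:
        lines.append(f"@SQ\tSN:{c.name}\tLN:{len(c.seq)}")
    lines.append("@PG\tID:splitjunc\tPN:splitjunc")
    return "\n".join(lines) + "\n"


def synthesize_split_reads(
    genome: GenomeModel,
    events: Iterable[PlantedRearrangement],
    *,
    read_length: int = DEFAULT_READ_LENGTH,
    n_background_reads: int = 0,
    n_indel_reads: int = 0,
    substitution_rate: float = 0.0,
    mapq: int = 60,
    sample_id: str = "sample",
    rng: np.random.Generator | int = 0,
) -> tuple[str, TruthTable]:
    """Render events plus background as sorted SAM text; return (SAM, truth).

    Each event yields one chimeric read: a soft-clipped primary alignment and
    a hard-clipped supplementary, mutually referenced through ``SA:Z`` tags.
    Background reads align contiguously (``{L}M``) with no clipping; indel
    reads carry a single 1bp I or 2bp D op.  Events whose segments cannot
    both reach the caller's 40bp minimum are still emitted but flagged
    unrecoverable in the truth table rather than dropped.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seqs = _as_editable(genome)
    rank = genome.rank
    records: list[tuple[int, int, str]] = []  # (contig rank, 0-based pos, line)

    truth_events: list[PlantedRearrangement] = []
    for i, ev in enumerate(events):
        ev = dataclasses.replace(ev, read_id=f"{sample_id}.ev{i:05d}")
        truth_events.append(ev)
        ca, pa, _ = ev.breakend_a
        cb, pb, _ = ev.breakend_b
        seg_a, seg_b = ev.segment_read_lengths
        L = ev.read_length
        read = _chimeric_read_seq(seqs, ev)
        if substitution_rate > 0:
            read = _mutate(read, substitution_rate, rng)
        assert len(read) == L, (len(read), L)
        a_start = pa - seg_a + 1  # 0-based ref start of segment A
        b2 = L - seg_b  # read start of segment B
        cigar_primary = f"{seg_a}M{L - seg_a}S"
        cigar_supp_sa = f"{b2}S{seg_b}M"
        cigar_supp = f"{b2}H{seg_b}M"
        sa_on_primary = f"SA:Z:{cb},{pb + 1},+,{cigar_supp_sa},{mapq},0;"
        sa_on_supp = f"SA:Z:{ca},{a_start + 1},+,{cigar_primary},{mapq},0;"
        qual = "I" * L
        records.append(
            (
                rank[ca],
                a_start,
                "\t".join(
                    [ev.read_id, "0", ca, str(a_start + 1), str(mapq), cigar_primary,
                     "*", "0", "0", read, qual, sa_on_primary]
                ),
            )
        )
        records.append(
            (
                rank[cb],
                pb,
                "\t".join(
                    [ev.read_id, "2048", cb, str(pb + 1), str(mapq), cigar_supp,
                     "*", "0", "0", read[b2:], "I" * seg_b, sa_on_supp]
                ),
            )
        )

    _append_background(records, seqs, genome, n_background_reads, n_indel_reads,
                       read_length, mapq, sample_id, rng)

    records.sort(key=lambda r: (r[0], r[1]))
    sam = sam_header(genome) + "\n".join(line for _, _, line in records)
    if records:
        sam += "\n"
    return sam, TruthTable(truth_events, sample_id=sample_id)


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(read)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = "ACGT"[(("ACGT".index(arr[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def _append_background(records, seqs, genome, n_background, n_indel, read_length,
                       mapq, sample_id, rng) -> None:
    rank = genome.rank
    qual = "I" * read_length
    for label, count, indel in (("bg", n_background, False), ("id", n_indel, True)):
        if count == 0:
            continue
        for j, (contig, pos) in enumerate(
            random_positions(genome, count, rng, nuclear_only=False, margin=0)
        ):
            clen = genome.lengths[contig]
            pos = min(pos, max(0, clen - read_length - 3))
            seq = bytes(seqs[contig][pos : pos + read_length]).decode("ascii")
            if indel:
                x = int(rng.integers(20, read_length - 20))
                if rng.random() < 0.5:
                    cigar = f"{x}M1I{read_length - 1 - x}M"
                else:
                    cigar = f"{x}M2D{read_length - x}M"
            else:
                cigar = f"{read_length}M"
            records.append(
                (
                    rank[contig],
                    pos,
                    "\t".join(
                        [f"{sample_id}.{label}{j:06d}", "0", contig, str(pos + 1),
                         str(mapq), cigar, "*", "0", "0", seq, qual]
                    ),
                )
            )


def write_sample(
    path,
    genome: GenomeModel,
    events: Iterable[PlantedRearrangement],
    **kwargs,
) -> TruthTable:
    """Synthesize one sample straight to a SAM file; returns its truth table."""
    sam, truth = synthesize_split_reads(genome, events, **kwargs)
    Path(path).write_text(sam)
    return truth


def export_fastq(sam_text: str, path) -> int:
    """Optional FASTQ export of primary records, for users running a real aligner."""
    n = 0
    with open(path, "w") as fh:
        for line in sam_text.splitlines():
            if line.startswith("@"):
                continue
            f = line.split("\t")
            if int(f[1]) & 0x900:
                continue
            fh.write(f"@{f[0]}\n{f[9]}\n+\n{f[10]}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Event sampling and the ageing series
# ---------------------------------------------------------------------------

#: Default breakpoint-signature mixture: microhomology lengths peaked at
#: 5-6bp dominate, with minority blunt and short-insertion classes.
DEFAULT_SIGNATURE_WEIGHTS: dict[tuple[str, int], float] = {
    **{(SIG_MICROHOMOLOGY, k): w for k, w in zip(range(1, 21),
        np.exp(-0.5 * ((np.arange(1, 21) - 5.5) / 2.5) ** 2))},
    (SIG_BLUNT, 0): 0.6,
    (SIG_INSERTION, 1): 0.4,
    (SIG_INSERTION, 2): 0.15,
    (SIG_INSERTION, 3): 0.08,
    (SIG_INSERTION, 4): 0.04,
    (SIG_INSERTION, 5): 0.02,
}


def _sample_signatures(n: int, weights: dict, rng) -> list[tuple[str, int]]:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def _cds_tree(genome: GenomeModel):
    from intervaltree import IntervalTree

    trees = {}
    for f in genome.features_of("CDS"):
        trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end)
    return trees


def sample_breakend_positions(
    genome: GenomeModel,
    n: int,
    rng: np.random.Generator,
    *,
    coding_depletion: float = 1.0,
    nuclear_only: bool = False,
    margin: int = DEFAULT_READ_LENGTH + 5,
) -> list[tuple[str, int]]:
    """Draw breakend positions, thinning those inside CDS by *coding_depletion*.

    A factor of 1 gives the uniform (length-proportional) null; 0.5 accepts
    coding positions with probability one half, creating genuine depletion
    signal for the intersection analyses.
    """
    if coding_depletion >= 1.0:
        return random_positions(genome, n, rng, nuclear_only=nuclear_only, margin=margin)
    trees = _cds_tree(genome)
    out: list[tuple[str, int]] = []
    while len(out) < n:
        batch = random_positions(genome, n - len(out), rng, nuclear_only=nuclear_only, margin=margin)
        for contig, pos in batch:
            tree = trees.get(contig)
            if tree is not None and tree.overlaps_point(pos) and rng.random() >= coding_depletion:
                continue
            out.append((contig, pos))
    return out


def random_events(
    genome: GenomeModel,
    n: int,
    rng: np.random.Generator,
    *,
    read_length: int = DEFAULT_READ_LENGTH,
    signature_weights: dict | None = None,
    coding_depletion: float = 1.0,
    seqs: dict[str, bytearray] | None = None,
) -> list[PlantedRearrangement]:
    """Plant *n* random junction events (editing *seqs* in place when given)."""
    weights = signature_weights or DEFAULT_SIGNATURE_WEIGHTS
    own = seqs is None
    if own:
        seqs = _as_editable(genome)
    sigs = _sample_signatures(n, weights, rng)
    pos_a = sample_breakend_positions(genome, n, rng, coding_depletion=coding_depletion)
    pos_b = sample_breakend_positions(genome, n, rng, coding_depletion=coding_depletion)
    events = []
    for (cls, ln), la, lb in zip(sigs, pos_a, pos_b):
        events.append(
            _plant_into(seqs, genome, cls, ln, la, lb,
                        read_length=read_length, read_offset=None, rng=rng)
        )
    return events


def plant_events(
    genome: GenomeModel,
    signatures: Sequence[tuple[str, int]],
    rng: np.random.Generator | int = 0,
    *,
    read_length: int = DEFAULT_READ_LENGTH,
    coding_depletion: float = 1.0,
) -> tuple[list[PlantedRearrangement], GenomeModel]:
    """Plant one event per requested (class, length) at random loci.

    Returns the truth events and the edited genome (microhomology events
    modify the reference so the joined loci share their seed sequence).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seqs = _as_editable(genome)
    n = len(signatures)
    pos_a = sample_breakend_positions(genome, n, rng, coding_depletion=coding_depletion)
    pos_b = sample_breakend_positions(genome, n, rng, coding_depletion=coding_depletion)
    events = [
        _plant_into(seqs, genome, cls, ln, la, lb,
                    read_length=read_length, read_offset=None, rng=rng)
        for (cls, ln), la, lb in zip(signatures, pos_a, pos_b)
    ]
    return events, _rebuild(genome, seqs)


@dataclass
class SimulatedSample:
    sample_id: str
    day: int
    replicate: int
    genotype: str
    mapped_reads: int
    sam_path: Path | None
    truth: TruthTable


@dataclass
class SimulationBundle:
    genome: GenomeModel
    samples: list[SimulatedSample]
    design: AgeingSeriesDesign

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "replicate": s.replicate,
                    "day": s.day,
                    "genotype": s.genotype,
                    "mapped_reads": s.mapped_reads,
                    "sam_path": str(s.sam_path) if s.sam_path else "",
                }
                for s in self.samples
            ]
        )

    def truth_junctions(self) -> pd.DataFrame:
        """All planted events as one junction-table DataFrame."""
        frames = []
        for s in self.samples:
            df = s.truth.to_frame()
            df["day"] = s.day
            df["replicate"] = s.replicate
            df["genotype"] = s.genotype
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=JUNCTION_COLUMNS)
        return pd.concat(frames, ignore_index=True)


def simulate_ageing_series(
    design: AgeingSeriesDesign,
    genome: GenomeModel,
    outdir: str | Path | None = None,
    *,
    signature_weights: dict | None = None,
    emit_sam: bool = True,
) -> SimulationBundle:
    """Simulate a full chronological-ageing sequencing series.

    Per sample, the number of planted junctions is Poisson with mean
    ``junction_rate[day] x mapped_reads`` (likewise indel reads), and every
    junction is supported by exactly one chimeric read, emulating rare
    heterogeneous events in a non-dividing population.  With ``emit_sam``
    each sample is written as ``<outdir>/<sample>.sam`` plus truth TSV and a
    joint metadata table.
    """
    rng = np.random.default_rng(design.seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    samples: list[SimulatedSample] = []
    for d_idx, day in enumerate(design.days):
        jrate = design.junction_rate_per_day[d_idx]
        irate = design.indel_rate_per_day[d_idx]
        for rep in range(1, design.replicates + 1):
            sample_id = f"{design.genotype}_d{day}_r{rep}"
            n_events = int(rng.poisson(jrate * design.background_reads))
            n_indels = int(rng.poisson(irate * design.background_reads))
            seqs = _as_editable(genome)
            events = random_events(
                genome, n_events, rng,
                read_length=design.read_length,
                signature_weights=signature_weights,
                coding_depletion=design.coding_depletion,
                seqs=seqs,
            )
            sam_path = None
            if emit_sam:
                edited = _rebuild(genome, seqs)
                sam, truth = synthesize_split_reads(
                    edited, events,
                    read_length=design.read_length,
                    n_background_reads=design.background_reads,
                    n_indel_reads=n_indels,
                    sample_id=sample_id,
                    rng=rng,
                )
                if outdir is not None:
                    sam_path = outdir / f"{sample_id}.sam"
                    sam_path.write_text(sam)
                    truth.write_tsv(outdir / f"{sample_id}.truth.tsv")
                else:
                    sam_path = None
                    # SAM text discarded when no outdir; truth retained
            else:
                for i, ev in enumerate(events):
                    events[i] = dataclasses.replace(ev, read_id=f"{sample_id}.ev{i:05d}")
                truth = TruthTable(events, sample_id=sample_id)
            mapped = design.background_reads + n_indels + len(events)
            samples.append(
                SimulatedSample(sample_id, day, rep, design.genotype, mapped, sam_path, truth)
            )
    bundle = SimulationBundle(genome, samples, design)
    if outdir is not None:
        bundle.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        genome.write_fasta(outdir / "genome.fa")
        genome.write_gff3(outdir / "genome.gff3")
    return bundle


def simulate_hotspot_series(
    genome: GenomeModel,
    *,
    days: Sequence[int] = (0, 1, 2, 3, 4, 5),
    replicates: int = 8,
    background_per_sample: int = 200,
    hotspot_bin: tuple[str, int] | None = None,
    n_partner_bins: int = 25,
    links_per_partner: float = 1.0,
    onset_day: int = 3,
    window_size: int = 20_000,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.DataFrame, tuple[str, int], list[tuple[str, int]]]:
    """Junction table with one planted global hotspot emerging late in life.

    From *onset_day* on, the hotspot bin gains Poisson(*links_per_partner*)
    junctions to each of *n_partner_bins* fixed remote bins per sample, on
    top of a uniform background present at all ages.  Returns the junction
    DataFrame, the planted hotspot bin and the partner bins.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rank = genome.rank
    nuclear = genome.nuclear_contigs
    bins = [
        (c, w)
        for c in nuclear
        for w in range(-(-genome.lengths[c] // window_size))
    ]
    if hotspot_bin is None:
        hotspot_bin = bins[int(rng.integers(0, len(bins)))]
    others = [b for b in bins if b != hotspot_bin]
    idx = rng.choice(len(others), size=min(n_partner_bins, len(others)), replace=False)
    partners = [others[i] for i in idx]

    def bin_pos(b: tuple[str, int]) -> tuple[str, int]:
        c, w = b
        hi = min((w + 1) * window_size, genome.lengths[c])
        return c, int(rng.integers(w * window_size, hi))

    rows = []
    for day in days:
        for rep in range(1, replicates + 1):
            sample_id = f"hs_d{day}_r{rep}"
            ends_a = random_positions(genome, background_per_sample, rng, nuclear_only=True)
            ends_b = random_positions(genome, background_per_sample, rng, nuclear_only=True)
            pairs = list(zip(ends_a, ends_b))
            if day >= onset_day:
                for pb in partners:
                    for _ in range(int(rng.poisson(links_per_partner))):
                        pairs.append((bin_pos(hotspot_bin), bin_pos(pb)))
            for i, ((ca, pa), (cb, pb_)) in enumerate(pairs):
                if (rank[ca], pa) > (rank[cb], pb_):
                    (ca, pa), (cb, pb_) = (cb, pb_), (ca, pa)
                rows.append(
                    {
                        "sample_id": sample_id, "day": day, "replicate": rep,
                        "genotype": "wt", "contig_a": ca, "pos_a": pa, "strand_a": "+",
                        "contig_b": cb, "pos_b": pb_, "strand_b": "+",
                        "sig_class": SIG_MICROHOMOLOGY, "sig_length": 5,
                        "read_id": f"{sample_id}.j{i:05d}",
                    }
                )
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS), hotspot_bin, partners
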