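"""Toy genome models with annotations.

A :class:`GenomeModel` stands in for a reference assembly (FASTA) plus its
feature annotation (GFF3): a handful of nuclear contigs, at most one small
circular contig playing the role of the mitochondrial chromosome, and
non-overlapping gene models (5'UTR / CDS / 3'UTR on a strand) with scattered
tRNA genes.  Everything is deterministic for a fixed seed so generated
genomes can serve as frozen test fixtures without shipping any data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FEATURE_KINDS = ("CDS", "5UTR", "3UTR", "tRNA", "gene")


class GenomeError(ValueError):
    """Raised for invalid genome construction requests (e.g. infeasible sizing)."""


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 0-based half-open, on a named contig."""

    contig: str
    start: int
    end: int
    strand: str
    kind: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeError(f"feature {self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise GenomeError(f"feature {self.gene_id}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise GenomeError(f"feature {self.gene_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    name: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeModel:
    """A reference genome: contigs (one optionally circular) plus annotations."""

    contigs: list[Contig]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def contig_names(self) -> list[str]:
        return [c.name for c in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: len(c.seq) for c in self.contigs}

    @property
    def rank(self) -> dict[str, int]:
        """Canonical contig ordering used to order breakends and matrices."""
        return {c.name: i for i, c in enumerate(self.contigs)}

    def contig(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def seq(self, name: str) -> str:
        return self.contig(name).seq

    @property
    def circular_contigs(self) -> list[str]:
        return [c.name for c in self.contigs if c.circular]

    @property
    def nuclear_contigs(self) -> list[str]:
        return [c.name for c in self.contigs if not c.circular]

    def features_of(self, kind: str, contig: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind == kind and (contig is None or f.contig == contig)
        ]

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if len(self.circular_contigs) > 1:
            raise GenomeError("at most one contig may be flagged circular")
        lengths = self.lengths
        by_track: dict[tuple[str, str, str], list[Feature]] = {}
        for f in self.features:
            if f.contig not in lengths:
                raise GenomeError(f"feature {f.gene_id} on unknown contig {f.contig}")
            if f.end > lengths[f.contig]:
                raise GenomeError(f"feature {f.gene_id} exceeds contig {f.contig}")
            by_track.setdefault((f.contig, f.strand, f.kind), []).append(f)
        for (contig, strand, kind), feats in by_track.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise GenomeError(
                        f"overlapping {kind} features on {contig}{strand}: "
                        f"{a.gene_id} and {b.gene_id}"
                    )

    # -- I/O ---------------------------------------------------------------
    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for c in self.contigs:
                circ = " circular=true" if c.circular else ""
                fh.write(f">{c.name}{circ}\n")
                for i in range(0, len(c.seq), width):
                    fh.write(c.seq[i : i + width] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in self.contigs:
                fh.write(f"##sequence-region {c.name} 1 {len(c.seq)}\n")
            for i, f in enumerate(sorted(self.features, key=lambda f: (f.contig, f.start))):
                attrs = f"ID={f.kind}:{f.gene_id}:{i};gene_id={f.gene_id}"
                fh.write(
                    "\t".join(
                        [
                            f.contig,
                            "splitjunc",
                            f.kind,
                            str(f.start + 1),  # GFF3 is 1-based inclusive
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_files(
        cls, fasta_path, gff3_path=None, circular: Iterable[str] = ()
    ) -> "GenomeModel":
        """Load a genome from FASTA (+ optional GFF3).

        Contigs whose FASTA description contains ``circular=true``, or whose
        name is listed in *circular*, are flagged circular.
        """
        from Bio import SeqIO

        circular = set(circular)
        contigs = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            circ = rec.id in circular or "circular=true" in rec.description
            contigs.append(Contig(rec.id, str(rec.seq).upper(), circ))
        features: list[Feature] = []
        if gff3_path is not None:
            import gffutils

            db = gffutils.create_db(
                str(gff3_path), ":memory:", merge_strategy="create_unique", force=True
            )
            for f in db.all_features():
                if f.featuretype not in FEATURE_KINDS:
                    continue
                gene_id = f.attributes.get("gene_id", [f.id])[0]
                features.append(
                    Feature(f.seqid, f.start - 1, f.end, f.strand, f.featuretype, gene_id)
                )
        return cls(contigs, features)


# ---------------------------------------------------------------------------
# Random sequence / position helpers
# ---------------------------------------------------------------------------

def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    """Uniform i.i.d. sequence with the requested expected GC content."""
    if not 0 < gc_fraction < 1:
        raise GenomeError("gc_fraction must lie strictly between 0 and 1")
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode("ascii")


def random_positions(
    genome: GenomeModel,
    n: int,
    rng: np.random.Generator,
    nuclear_only: bool = True,
    margin: int = 0,
) -> list[tuple[str, int]]:
    """Draw *n* genomic positions uniformly over the (nuclear) genome.

    Contigs are chosen proportionally to their usable length, then a position
    is drawn uniformly within the contig (excluding *margin* bases at each
    end), so the draw is uniform over the concatenated usable sequence.
    """
    names = genome.nuclear_contigs if nuclear_only else genome.contig_names
    if not names:
        raise GenomeError("genome has no eligible contig")
    lens = np.array([genome.lengths[c] - 2 * margin for c in names], dtype=float)
    if (lens <= 0).any():
        raise GenomeError("margin exceeds contig length")
    p = lens / lens.sum()
    picks = rng.choice(len(names), size=n, p=p)
    offsets = rng.integers(0, lens[picks].astype(np.int64))
    return [(names[k], margin + int(o)) for k, o in zip(picks, offsets)]


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    contig_lengths: Sequence[int],
    gc_fraction: float = 0.36,
    mito_length: int = 20_000,
    n_genes: int = 20,
    utr_lengths: tuple[int, int] = (200, 300),
    cds_length: int = 1_200,
    n_trnas: int | None = None,
    end_margin: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> GenomeModel:
    """Generate a toy genome with gene annotations and a circular mito contig.

    Parameters
    ----------
    contig_lengths
        Lengths of the nuclear contigs (named ``chrI``, ``chrII``, ...).
    gc_fraction
        Expected GC content of every contig (the fission-yeast genome is
        roughly 36% GC, hence the default).
    mito_length
        Length of the circular mitochondrial stand-in contig ``mito``
        (0 disables it).
    n_genes
        Total gene models to place across nuclear contigs, allocated
        proportionally to contig length.  Each gene is 5'UTR + CDS + 3'UTR
        on a random strand, genes never overlap.
    utr_lengths
        (5'UTR, 3'UTR) lengths in bp.
    n_trnas
        tRNA genes scattered in intergenic space (default: ``max(2, n_genes // 10)``).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if any(l < 1_000 for l in contig_lengths):
        raise GenomeError("contig lengths must be >= 1kb")
    if mito_length and mito_length < 1_000:
        raise GenomeError("mito_length must be 0 or >= 1kb")

    utr5, utr3 = utr_lengths
    gene_span = utr5 + cds_length + utr3
    trna_len = 80
    if n_trnas is None:
        n_trnas = max(2, n_genes // 10) if n_genes else 0

    names = [f"chr{_roman(i + 1)}" for i in range(len(contig_lengths))]
    contigs = [Contig(n, random_sequence(l, gc_fraction, rng)) for n, l in zip(names, contig_lengths)]
    if mito_length:
        contigs.append(Contig("mito", random_sequence(mito_length, gc_fraction, rng), circular=True))

    # allocate genes proportionally to nuclear contig length
    total = sum(contig_lengths)
    alloc = [round(n_genes * l / total) for l in contig_lengths]
    while sum(alloc) > n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < n_genes:
        alloc[int(np.argmin(alloc))] += 1

    features: list[Feature] = []
    gene_no = 0
    trna_no = 0
    trna_alloc = _split_count(n_trnas, len(contig_lengths))
    for name, length, n_here, n_trna_here in zip(names, contig_lengths, alloc, trna_alloc):
        usable = length - 2 * end_margin
        slots = n_here + n_trna_here
        need = n_here * gene_span + n_trna_here * trna_len
        if usable < need + slots:  # at least 1bp gap per placed element
            raise GenomeError(
                f"cannot place {n_here} genes + {n_trna_here} tRNAs on a {length}bp contig"
            )
        spare = usable - need
        # random gaps between consecutive elements (and before the first)
        gaps = rng.multinomial(spare - slots, np.full(slots + 1, 1 / (slots + 1))) + 1 if slots else []
        kinds = ["gene"] * n_here + ["tRNA"] * n_trna_here
        rng.shuffle(kinds)
        pos = end_margin
        for k, gap in zip(kinds, gaps):
            pos += int(gap)
            strand = "+" if rng.random() < 0.5 else "-"
            if k == "gene":
                gene_no += 1
                gid = f"gene{gene_no:04d}"
                s = pos
                if strand == "+":
                    parts = [("5UTR", utr5), ("CDS", cds_length), ("3UTR", utr3)]
                else:
                    parts = [("3UTR", utr3), ("CDS", cds_length), ("5UTR", utr5)]
                features.append(Feature(name, s, s + gene_span, strand, "gene", gid))
                for kind, ln in parts:
                    features.append(Feature(name, s, s + ln, strand, kind, gid))
                    s += ln
                pos += gene_span
            else:
                trna_no += 1
                features.append(
                    Feature(name, pos, pos + trna_len, strand, "tRNA", f"trna{trna_no:03d}")
                )
                pos += trna_len
    return GenomeModel(contigs, features)


def _split_count(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if n <= len(numerals) else str(n)


def gc_content(seq: str) -> float:
    """GC fraction of a sequence (0 for an empty sequence)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
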