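"""Breakpoint-signature classification and spectra.

The signature of a junction is read purely from the read-coordinate
intervals of the split read's two aligned segments: an overlap between the
intervals is microhomology of that length, exact adjacency is a blunt join,
and a gap is a non-homologous insertion of the gap length.  Working in read
coordinates (straight off the CIGAR strings) makes the classification
tolerant of imperfect homology within the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import SplitRead
from .genome import GenomeModel, gc_content
from .statutils import StatResult, rank_sum_test

SIG_MICROHOMOLOGY = "microhomology"
SIG_BLUNT = "blunt"
SIG_INSERTION = "insertion"

#: Display cap for spectra: microhomologies/insertions longer than this are
#: pooled into a ">cap" bin for plotting; raw lengths stay in the data.
DISPLAY_CAP = 20


class ContractViolation(ValueError):
    """The split read's segments do not tile the read (should be pre-filtered)."""


@dataclass(frozen=True)
class Signature:
    sig_class: str
    length: int

    def __post_init__(self) -> None:
        if (self.sig_class == SIG_BLUNT) != (self.length == 0):
            raise ValueError("blunt signature iff length == 0")
        if self.length < 0:
            raise ValueError("signature length must be >= 0")

    @property
    def signed_length(self) -> int:
        """Insertion lengths negative, blunt zero, microhomology positive."""
        return -self.length if self.sig_class == SIG_INSERTION else self.length


def classify_intervals(
    interval_1: tuple[int, int], interval_2: tuple[int, int], read_length: int
) -> Signature:
    """Classify from two read-space intervals [a, b).

    Overlap ``b1 - a2 > 0`` is microhomology of that length, ``== 0`` blunt,
    ``< 0`` an insertion of the gap length.  The intervals must jointly tile
    the read apart from the overlap/gap.
    """
    (a1, b1), (a2, b2) = sorted([tuple(interval_1), tuple(interval_2)])
    if a1 != 0 or max(b1, b2) != read_length or b2 < b1:
        raise ContractViolation(
            f"segments {interval_1}, {interval_2} do not tile a {read_length}bp read"
        )
    overlap = b1 - a2
    if overlap > 0:
        return Signature(SIG_MICROHOMOLOGY, overlap)
    if overlap == 0:
        return Signature(SIG_BLUNT, 0)
    return Signature(SIG_INSERTION, -overlap)


def classify_junction(split_read: SplitRead) -> Signature:
    """Breakpoint signature of a filtered split read (symmetric in segment order)."""
    p, s = split_read.segments
    return classify_intervals(
        (p.read_start, p.read_end), (s.read_start, s.read_end), split_read.read_length
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def signed_lengths(junctions: pd.DataFrame) -> pd.Series:
    sign = junctions["sig_class"].map(
        {SIG_INSERTION: -1, SIG_BLUNT: 0, SIG_MICROHOMOLOGY: 1}
    )
    return (junctions["sig_length"] * sign.where(sign != 0, 1)).astype(int)


def build_spectrum(
    junctions: pd.DataFrame, by: tuple[str, ...] = ("sample_id", "day")
) -> pd.DataFrame:
    """Signature spectrum: junction counts per signed length per group.

    Returns long format with columns ``(*by, signed_length, count)``; counts
    within each group sum to that group's junction count.
    """
    by = [c for c in by if c in junctions.columns]
    if junctions.empty:
        return pd.DataFrame(columns=[*by, "signed_length", "count"])
    df = junctions.copy()
    df["signed_length"] = signed_lengths(df)
    grouped = (
        df.groupby([*by, "signed_length"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return grouped


def cap_spectrum(spectrum: pd.DataFrame, cap: int = DISPLAY_CAP) -> pd.DataFrame:
    """Fold |signed_length| > cap into +/-(cap+1) bins for display."""
    out = spectrum.copy()
    out["signed_length"] = out["signed_length"].clip(-(cap + 1), cap + 1)
    keys = [c for c in out.columns if c not in ("count",)]
    return out.groupby(keys, as_index=False)["count"].sum()


# ---------------------------------------------------------------------------
# Flanks and GC bias
# ---------------------------------------------------------------------------

def extract_junction_flanks(
    junctions: pd.DataFrame, genome: GenomeModel, flank: int = 100
) -> list[tuple[str, str]]:
    """Sequence context around each breakend: *flank* bp centred on the coordinate.

    Returns (name, sequence) records, uppercase, clipped (with a warning) at
    contig ends.  One record per breakend, two per junction.
    """
    import logging

    if flank <= 0:
        raise ValueError("flank must be > 0")
    half = flank // 2
    records = []
    lengths = genome.lengths
    for idx, row in junctions.reset_index(drop=True).iterrows():
        for side in "ab":
            contig = row[f"contig_{side}"]
            pos = int(row[f"pos_{side}"])
            if not 0 <= pos < lengths[contig]:
                raise ValueError(f"breakend {contig}:{pos} outside contig")
            lo, hi = pos - half, pos + (flank - half)
            if lo < 0 or hi > lengths[contig]:
                logging.getLogger(__name__).warning(
                    "flank around %s:%d clipped at contig boundary", contig, pos
                )
                lo, hi = max(lo, 0), min(hi, lengths[contig])
            name = f"junction{idx}_{side}_{contig}_{pos}"
            records.append((name, genome.seq(contig)[lo:hi].upper()))
    return records


def write_flank_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def gc_bias_test(
    called_flanks: list[tuple[str, str]] | list[str],
    simulated_flanks: list[tuple[str, str]] | list[str],
) -> StatResult:
    """Rank-sum comparison of per-flank GC content, called vs simulated.

    A non-significant result indicates the caller has no bias toward AT- or
    GC-rich regions.
    """
    def gcs(flanks):
        seqs = [f[1] if isinstance(f, tuple) else f for f in flanks]
        return np.array([gc_content(s) for s in seqs])

    return rank_sum_test(gcs(called_flanks), gcs(simulated_flanks),
                         alternative="two-sided", statistic_name="W")
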