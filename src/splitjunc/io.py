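"""Readers/writers for the pipeline's tabular interchange formats.

Junctions travel as BEDPE (0-based half-open, one line per junction) with
extra columns for the read id, breakpoint signature and sample; depth tracks
are read from bedGraph.  Simple line-oriented text formats are written
directly; SAM parsing lives in :mod:`splitjunc.calling` (pysam).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "sig_class", "sig_length", "sample_id",
]


def write_bedpe(junctions: pd.DataFrame, path) -> None:
    """Write a junction table as BEDPE (+ signature and sample columns)."""
    out = pd.DataFrame(
        {
            "chrom1": junctions["contig_a"],
            "start1": junctions["pos_a"],
            "end1": junctions["pos_a"] + 1,
            "chrom2": junctions["contig_b"],
            "start2": junctions["pos_b"],
            "end2": junctions["pos_b"] + 1,
            "name": junctions["read_id"],
            "score": ".",
            "strand1": junctions["strand_a"],
            "strand2": junctions["strand_b"],
            "sig_class": junctions["sig_class"].fillna("."),
            "sig_length": junctions["sig_length"].fillna(-1).astype(int),
            "sample_id": junctions["sample_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE written by :func:`write_bedpe` back into a junction table."""
    raw = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS)
    df = pd.DataFrame(
        {
            "sample_id": raw["sample_id"],
            "contig_a": raw["chrom1"],
            "pos_a": raw["start1"],
            "strand_a": raw["strand1"],
            "contig_b": raw["chrom2"],
            "pos_b": raw["start2"],
            "strand_b": raw["strand2"],
            "sig_class": raw["sig_class"].replace(".", np.nan),
            "sig_length": raw["sig_length"].replace(-1, np.nan),
            "read_id": raw["name"],
        }
    )
    return df


def write_rejection_summary(stats, path) -> None:
    """Rejection-reason tallies from an ExtractionStats as a two-column TSV."""
    rows = [
        ("records", stats.n_records),
        ("mapped_primary", stats.n_mapped_primary),
        ("split_candidates", stats.n_split_candidates),
        ("multi_supplementary_discarded", stats.n_multi_supplementary),
        ("parse_errors", stats.n_parse_errors),
        ("indel_reads", stats.n_indel_reads),
    ]
    rows += sorted(stats.rejections.items())
    pd.DataFrame(rows, columns=["category", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_bedgraph(path, genome: GenomeModel) -> dict[str, np.ndarray]:
    """Expand a bedGraph file into per-base depth arrays over the genome."""
    tracks = {c: np.zeros(genome.lengths[c]) for c in genome.contig_names}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "value"],
        comment="#",
    )
    for row in df.itertuples():
        if row.contig not in tracks:
            raise ValueError(f"bedGraph contig {row.contig!r} not in genome")
        tracks[row.contig][row.start : row.end] = row.value
    return tracks


def write_bedgraph(depth: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for contig, track in depth.items():
            # run-length encode constant stretches
            change = np.nonzero(np.diff(track))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(track)]])
            for s, e in zip(starts, ends):
                v = track[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def write_matrix_long(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
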