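"""Rearrangement hotspots: binned junction matrices, old/young ratios, scores.

Junctions are binned into fixed windows (default 20kb) by the two breakend
coordinates, giving one symmetric count matrix per contig pair and timepoint.
Element-wise old/young ratios of those matrices highlight age-associated
junction formation, and a bin's *global hotspot score* is the mean of its
ratio row across every window genome-wide, ranking bins that gained
junctions to many remote regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .statutils import StatResult, rank_sum_test

DEFAULT_WINDOW = 20_000


def n_windows(length: int, window_size: int) -> int:
    return -(-length // window_size)  # ceil division; last partial window included


@dataclass
class JunctionMatrix:
    """Per contig-pair junction counts in window space (canonical upper storage)."""

    window_size: int
    contigs: list[str]
    lengths: dict[str, int]
    matrices: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def total(self) -> int:
        return int(sum(m.sum() for m in self.matrices.values()))

    def pair(self, a: str, b: str) -> np.ndarray:
        return self.matrices[(a, b)]

    def to_frame(self, value_name: str = "count") -> pd.DataFrame:
        rows = []
        for (a, b), m in self.matrices.items():
            ii, jj = np.nonzero(m)
            for i, j in zip(ii, jj):
                rows.append({"contig_a": a, "window_a": int(i),
                             "contig_b": b, "window_b": int(j),
                             value_name: m[i, j]})
        return pd.DataFrame(rows, columns=["contig_a", "window_a", "contig_b",
                                           "window_b", value_name])


def bin_junctions(
    junctions: pd.DataFrame, genome: GenomeModel, window_size: int = DEFAULT_WINDOW
) -> JunctionMatrix:
    """Bin each junction into one matrix cell addressed by its two breakends.

    Cells are canonically ordered (contig rank, then window index); for
    same-contig pairs only the upper triangle is populated so nothing is
    double-counted, and the matrix grand total equals the junction count.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    rank = genome.rank
    lengths = genome.lengths
    contigs = genome.contig_names
    jm = JunctionMatrix(window_size, contigs, lengths)
    for i, a in enumerate(contigs):
        for b in contigs[i:]:
            jm.matrices[(a, b)] = np.zeros(
                (n_windows(lengths[a], window_size), n_windows(lengths[b], window_size))
            )
    for row in junctions.itertuples():
        ca, cb = row.contig_a, row.contig_b
        wa, wb = row.pos_a // window_size, row.pos_b // window_size
        if (rank[ca], wa) > (rank[cb], wb):
            ca, cb, wa, wb = cb, ca, wb, wa
        jm.matrices[(ca, cb)][wa, wb] += 1
    return jm


@dataclass
class RatioMatrix:
    """Element-wise old/young ratios with a mask for undefined cells."""

    window_size: int
    contigs: list[str]
    lengths: dict[str, int]
    pseudocount: float
    ratios: dict[tuple[str, str], np.ndarray]
    masks: dict[tuple[str, str], np.ndarray]  # True where the cell is undefined

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), m in self.ratios.items():
            mask = self.masks[(a, b)]
            for i in range(m.shape[0]):
                for j in range(m.shape[1]):
                    if mask[i, j]:
                        continue
                    rows.append({"contig_a": a, "window_a": i, "contig_b": b,
                                 "window_b": j, "ratio": m[i, j]})
        return pd.DataFrame(rows, columns=["contig_a", "window_a", "contig_b",
                                           "window_b", "ratio"])


def old_young_ratio(
    mat_old: JunctionMatrix, mat_young: JunctionMatrix, pseudocount: float = 1.0
) -> RatioMatrix:
    """Element-wise (old + pseudocount) / (young + pseudocount).

    With a zero pseudocount, cells whose young count is zero are masked
    rather than reported as infinite.
    """
    if mat_old.window_size != mat_young.window_size or set(mat_old.matrices) != set(
        mat_young.matrices
    ):
        raise ValueError("matrices have mismatched windowing or contigs")
    ratios, masks = {}, {}
    for key, old in mat_old.matrices.items():
        young = mat_young.matrices[key]
        if old.shape != young.shape:
            raise ValueError(f"shape mismatch for pair {key}")
        denom = young + pseudocount
        mask = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(mask, np.nan, (old + pseudocount) / np.where(mask, 1, denom))
        ratios[key] = r
        masks[key] = mask
    return RatioMatrix(mat_old.window_size, mat_old.contigs, mat_old.lengths,
                       pseudocount, ratios, masks)


def global_hotspot_score(
    ratio: RatioMatrix, include_diagonal: bool = True
) -> pd.DataFrame:
    """Mean ratio of each bin against all windows genome-wide, ranked.

    For bin (contig, window) the score averages its ratio row across every
    window of every contig (masked cells excluded); a fully masked bin is
    reported with a missing score.  Ranked descending, rank 1 = top hotspot.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for c in ratio.contigs:
        nw = n_windows(ratio.lengths[c], ratio.window_size)
        sums[c] = np.zeros(nw)
        counts[c] = np.zeros(nw)

    for (a, b), m in ratio.ratios.items():
        valid = ~ratio.masks[(a, b)] & ~np.isnan(m)
        vals = np.where(valid, m, 0.0)
        if a == b:
            # same-contig matrices are canonically upper-triangle; symmetrise
            # that triangle so each bin sees its full row (diagonal once)
            vals = np.triu(vals)
            valid = np.triu(valid)
            full = vals + vals.T - np.diag(np.diag(vals))
            fvalid = valid | valid.T
            if not include_diagonal:
                np.fill_diagonal(full, 0.0)
                np.fill_diagonal(fvalid, False)
            sums[a] += full.sum(axis=1)
            counts[a] += fvalid.sum(axis=1)
        else:
            sums[a] += vals.sum(axis=1)
            counts[a] += valid.sum(axis=1)
            sums[b] += vals.sum(axis=0)
            counts[b] += valid.sum(axis=0)

    rows = []
    for c in ratio.contigs:
        with np.errstate(invalid="ignore"):
            score = np.where(counts[c] > 0, sums[c] / np.maximum(counts[c], 1), np.nan)
        for w in range(len(score)):
            rows.append({"contig": c, "window": w, "score": score[w]})
    df = pd.DataFrame(rows)
    df["rank"] = df["score"].rank(ascending=False, method="min")
    return df.sort_values("rank", kind="stable").reset_index(drop=True)


def distance_distributions(
    junctions: pd.DataFrame,
    hotspot_bins: set[tuple[str, int]],
    window_size: int = DEFAULT_WINDOW,
) -> tuple[np.ndarray, np.ndarray, StatResult]:
    """Intra-chromosomal breakend distances, hotspot stratum vs the rest.

    A junction belongs to the hotspot stratum when either breakend falls in a
    hotspot bin.  Returns both distance samples and a two-sided rank-sum test.
    """
    intra = junctions[junctions["contig_a"] == junctions["contig_b"]]
    if intra.empty:
        raise ValueError("no intra-chromosomal junctions")
    dist = (intra["pos_b"] - intra["pos_a"]).abs().to_numpy()
    in_hot = np.array(
        [
            (r.contig_a, r.pos_a // window_size) in hotspot_bins
            or (r.contig_b, r.pos_b // window_size) in hotspot_bins
            for r in intra.itertuples()
        ]
    )
    hot, other = dist[in_hot], dist[~in_hot]
    if len(hot) < 2 or len(other) < 2:
        raise ValueError("a distance stratum is empty or too small")
    stat = rank_sum_test(hot, other, alternative="two-sided", statistic_name="W")
    return hot, other, stat


def coverage_ratio(
    depth_old: dict[str, np.ndarray],
    depth_young: dict[str, np.ndarray],
    window_size: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-bin median-depth ratio old/young (repeat-expansion check).

    Bins whose young median depth is zero are masked.  Depth tracks must
    cover the same contigs at the same lengths.
    """
    if set(depth_old) != set(depth_young):
        raise ValueError("depth tracks cover different contigs")
    rows = []
    for contig in depth_old:
        old, young = np.asarray(depth_old[contig]), np.asarray(depth_young[contig])
        if len(old) != len(young):
            raise ValueError(f"depth track length mismatch on {contig}")
        for w in range(n_windows(len(old), window_size)):
            sl = slice(w * window_size, (w + 1) * window_size)
            m_old = float(np.median(old[sl]))
            m_young = float(np.median(young[sl]))
            masked = m_young == 0
            rows.append(
                {
                    "contig": contig, "window": w,
                    "median_old": m_old, "median_young": m_young,
                    "ratio": np.nan if masked else m_old / m_young,
                    "masked": masked,
                }
            )
    return pd.DataFrame(rows)
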