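"""Feature-level junction analyses and ageing rate metrics.

Covers the annotation-aware half of the pipeline: depletion of junctions in
coding regions against matched random junction sets, positional profiles of
junctions around gene starts/ends, recurrently rearranged 3'UTRs, the
per-sample JPMR/IPMR ageing metrics with their Day-0-relative versions, a
feature-level JPMR (junctions near a feature set per mapped read), and
normalised per-feature coverage for pull-down style depth comparisons.

A junction "intersects" a feature when either breakend lies within it
(switchable to requiring both); windows around features are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Feature, GenomeModel
from .statutils import StatResult, one_sample_t_test, paired_t_test, rank_sum_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------

def build_feature_trees(
    features: list[Feature], flank: int = 0
) -> dict[str, IntervalTree]:
    """Interval trees per contig over ``[start - flank, end + flank)``."""
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.contig, IntervalTree()).addi(
            max(0, f.start - flank), f.end + flank, f
        )
    return trees


def junction_hits(
    junctions: pd.DataFrame,
    features: list[Feature],
    flank: int = 0,
    mode: str = "either",
) -> np.ndarray:
    """Boolean mask: does each junction intersect the feature set?

    ``mode='either'`` (default) requires at least one breakend inside a
    (flank-extended) feature; ``'both'`` requires both breakends.
    """
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    trees = build_feature_trees(features, flank)

    def inside(contig: str, pos: int) -> bool:
        tree = trees.get(contig)
        return tree is not None and bool(tree.overlaps_point(pos))

    out = np.zeros(len(junctions), dtype=bool)
    for i, row in enumerate(junctions.itertuples()):
        a = inside(row.contig_a, row.pos_a)
        b = inside(row.contig_b, row.pos_b)
        out[i] = (a or b) if mode == "either" else (a and b)
    return out


# ---------------------------------------------------------------------------
# Coding depletion
# ---------------------------------------------------------------------------

def coding_depletion_test(
    junction_sets: list[pd.DataFrame],
    genome: GenomeModel,
    cds_features: list[Feature] | None = None,
    rng: np.random.Generator | int = 0,
    mode: str = "either",
) -> tuple[np.ndarray, np.ndarray, StatResult]:
    """Observed vs expected proportion of junctions touching coding sequence.

    For every replicate junction set, an equally sized set of randomly
    located (nuclear) junctions is simulated; the one-sided rank-sum U test
    asks whether the observed coding proportions are lower than expected.
    Empty replicates are dropped with a warning.
    """
    from .nullmodels import simulate_random_junctions

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cds = cds_features if cds_features is not None else genome.features_of("CDS")
    if not cds:
        raise ValueError("no CDS features available")
    nuclear = set(genome.nuclear_contigs)

    observed, expected = [], []
    for i, js in enumerate(junction_sets):
        if not js.empty:
            js = js[js["contig_a"].isin(nuclear) & js["contig_b"].isin(nuclear)]
        if js.empty:
            logger.warning("replicate %d has no nuclear junctions; dropped", i)
            continue
        sim = simulate_random_junctions(genome, len(js), nuclear_only=True, rng=rng)
        observed.append(junction_hits(js, cds, mode=mode).mean())
        expected.append(junction_hits(sim, cds, mode=mode).mean())
    if len(observed) < 3:
        raise ValueError("need at least 3 non-empty replicates per side")
    stat = rank_sum_test(observed, expected, alternative="less", statistic_name="U")
    return np.array(observed), np.array(expected), stat


# ---------------------------------------------------------------------------
# Gene-end profiles
# ---------------------------------------------------------------------------

@dataclass
class FeatureProfile:
    """Junction counts by position relative to gene starts/ends.

    Offsets are strand-oriented so that within each anchor profile "inside
    the gene" is a single sign: positive offsets point in the direction of
    transcription (outside at the gene end, inside at the gene start).
    """

    flank: int
    smooth: int
    bin_size: int
    counts: dict[str, np.ndarray]  # anchor -> per-offset counts over [-flank, flank)
    smoothed: dict[str, np.ndarray]
    binned: dict[str, pd.DataFrame]  # anchor -> (bin_start, bin_end, count)

    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank)


def _breakend_offsets(
    junctions: pd.DataFrame, anchors: list[tuple[str, int, str]], flank: int
) -> np.ndarray:
    """Strand-oriented offsets of every breakend within *flank* of an anchor."""
    trees: dict[str, IntervalTree] = {}
    for contig, pos, strand in anchors:
        trees.setdefault(contig, IntervalTree()).addi(
            max(0, pos - flank), pos + flank, (pos, strand)
        )
    offs = []
    for row in junctions.itertuples():
        for contig, pos in ((row.contig_a, row.pos_a), (row.contig_b, row.pos_b)):
            tree = trees.get(contig)
            if tree is None:
                continue
            for iv in tree.at(pos):
                apos, strand = iv.data
                delta = pos - apos
                offs.append(delta if strand == "+" else -delta)
    return np.array(offs, dtype=int)


def gene_end_profile(
    junctions: pd.DataFrame,
    cds_features: list[Feature],
    flank: int = 500,
    smooth: int = 10,
    bin_size: int = 250,
) -> FeatureProfile:
    """Positional junction profile around CDS start and end coordinates.

    Every breakend within *flank* bp of a CDS boundary is recorded at its
    strand-oriented offset; the per-offset track is smoothed with a sliding
    mean (*smooth* bp window) and also aggregated into *bin_size* bp bins.
    """
    if any(f.strand not in "+-" for f in cds_features):
        raise ValueError("CDS features must carry a strand")
    starts, ends = [], []
    for f in cds_features:
        if f.strand == "+":
            starts.append((f.contig, f.start, "+"))
            ends.append((f.contig, f.end - 1, "+"))
        else:
            starts.append((f.contig, f.end - 1, "-"))
            ends.append((f.contig, f.start, "-"))

    counts, smoothed, binned = {}, {}, {}
    for anchor, positions in (("start", starts), ("end", ends)):
        offs = _breakend_offsets(junctions, positions, flank)
        track = np.bincount(offs + flank, minlength=2 * flank)[: 2 * flank].astype(float)
        counts[anchor] = track
        kernel = np.full(smooth, 1.0 / smooth)
        smoothed[anchor] = np.convolve(track, kernel, mode="same")
        edges = np.arange(-flank, flank + 1, bin_size)
        binned[anchor] = pd.DataFrame(
            {
                "bin_start": edges[:-1],
                "bin_end": edges[1:],
                "count": [
                    int(track[e + flank : e2 + flank].sum())
                    for e, e2 in zip(edges[:-1], edges[1:])
                ],
            }
        )
    return FeatureProfile(flank, smooth, bin_size, counts, smoothed, binned)


def profile_bin_tests(
    per_replicate_junctions: list[pd.DataFrame],
    cds_features: list[Feature],
    anchor: str = "end",
    flank: int = 500,
    bin_size: int = 250,
) -> pd.DataFrame:
    """Paired t-tests between adjacent bins of the gene-end profile.

    Bin counts are computed per replicate and each neighbouring bin pair is
    compared with a paired t-test across replicates.
    """
    per_rep = []
    for js in per_replicate_junctions:
        prof = gene_end_profile(js, cds_features, flank=flank, bin_size=bin_size)
        per_rep.append(prof.binned[anchor]["count"].to_numpy())
    mat = np.vstack(per_rep)  # replicates x bins
    edges = np.arange(-flank, flank + 1, bin_size)
    rows = []
    for b in range(mat.shape[1] - 1):
        try:
            stat = paired_t_test(mat[:, b], mat[:, b + 1])
            t, p = stat.value, stat.p_value
        except ValueError:
            t, p = np.nan, np.nan
        rows.append(
            {
                "bin_a": f"[{edges[b]},{edges[b + 1]})",
                "bin_b": f"[{edges[b + 1]},{edges[b + 2]})",
                "t": t,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3'UTR outliers
# ---------------------------------------------------------------------------

def utr_outlier_genes(
    junctions: pd.DataFrame, utr3_features: list[Feature]
) -> pd.DataFrame:
    """Genes whose 3'UTR holds more junctions than mean + 2 population SD.

    Counts junction breakends per 3'UTR, computes the population mean and SD
    of those counts over all UTRs, and flags genes strictly above
    ``mean + 2*SD``; a zero-SD population flags nothing.
    """
    if not utr3_features:
        raise ValueError("no 3'UTR features supplied")
    counts = {f.gene_id: 0 for f in utr3_features}
    lengths = {f.gene_id: f.length for f in utr3_features}
    trees = build_feature_trees(utr3_features)
    for row in junctions.itertuples():
        seen = set()
        for contig, pos in ((row.contig_a, row.pos_a), (row.contig_b, row.pos_b)):
            tree = trees.get(contig)
            if tree is None:
                continue
            for iv in tree.at(pos):
                gid = iv.data.gene_id
                if gid not in seen:  # one junction counts once per UTR
                    counts[gid] += 1
                    seen.add(gid)
    vals = np.array(list(counts.values()), dtype=float)
    mean, sd = vals.mean(), vals.std()  # population SD (divisor n)
    threshold = mean + 2 * sd
    df = pd.DataFrame(
        {
            "gene_id": list(counts),
            "utr_length": [lengths[g] for g in counts],
            "junction_count": list(counts.values()),
        }
    )
    df["population_mean"] = mean
    df["population_sd"] = sd
    df["outlier"] = (df["junction_count"] > threshold) & (sd > 0)
    return df.sort_values("junction_count", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sample metrics (JPMR / IPMR)
# ---------------------------------------------------------------------------

def compute_sample_metrics(samples: pd.DataFrame) -> pd.DataFrame:
    """JPMR/IPMR per sample plus Day-0-median-relative versions per genotype.

    Input columns: ``sample_id, day, genotype, replicate, mapped_reads,
    junction_count, indel_read_count``.  Relative metrics divide by the
    median JPMR/IPMR of the same genotype's Day-0 samples; a genotype
    without Day-0 samples is an error.
    """
    req = {"sample_id", "day", "mapped_reads", "junction_count", "indel_read_count"}
    missing = req - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = samples.copy()
    if "genotype" not in df.columns:
        df["genotype"] = "wt"
    if (df["mapped_reads"] <= 0).any():
        raise ValueError("mapped_reads must be > 0")
    df["jpmr"] = df["junction_count"] / df["mapped_reads"]
    df["ipmr"] = df["indel_read_count"] / df["mapped_reads"]
    day0 = df[df["day"] == 0]
    for genotype, grp in df.groupby("genotype"):
        base = day0[day0["genotype"] == genotype]
        if base.empty:
            raise ValueError(f"no Day-0 sample for genotype {genotype!r}")
        j0, i0 = base["jpmr"].median(), base["ipmr"].median()
        sel = df["genotype"] == genotype
        df.loc[sel, "relative_jpmr"] = df.loc[sel, "jpmr"] / j0 if j0 > 0 else np.nan
        df.loc[sel, "relative_ipmr"] = df.loc[sel, "ipmr"] / i0 if i0 > 0 else np.nan
    return df


def junction_categories(junctions: pd.DataFrame, genome: GenomeModel) -> pd.Series:
    """Categorise junctions as nDNA-nDNA, mtDNA-nDNA or mtDNA-mtDNA."""
    circular = set(genome.circular_contigs)
    def cat(row):
        n = (row.contig_a in circular) + (row.contig_b in circular)
        return ("nDNA-nDNA", "mtDNA-nDNA", "mtDNA-mtDNA")[n]
    return pd.Series(
        [cat(r) for r in junctions.itertuples()], index=junctions.index, name="category"
    )


# ---------------------------------------------------------------------------
# Feature-level JPMR
# ---------------------------------------------------------------------------

def feature_jpmr(
    junctions: pd.DataFrame,
    features: list[Feature],
    sample_metrics: pd.DataFrame,
    flank: int = 500,
    day_pair: tuple[int, int] = (0, 3),
) -> tuple[pd.DataFrame, StatResult | None]:
    """JPMR restricted to junctions near a feature set (feature +/- flank).

    Junctions with at least one breakend within the half-open window
    ``[start - flank, end + flank)`` of any feature are counted per sample
    and divided by that sample's mapped reads, then normalised to the mean
    feature-JPMR of the genotype's Day-0 samples.  The two days of
    *day_pair* are compared with a paired t-test across replicates (skipped
    with a warning when fewer than two matched pairs exist).
    """
    if not features:
        raise ValueError("feature set is empty")
    hits = junction_hits(junctions, features, flank=flank, mode="either")
    near = junctions[hits]
    counts = near.groupby("sample_id").size() if not near.empty else pd.Series(dtype=int)

    df = sample_metrics.copy()
    if "genotype" not in df.columns:
        df["genotype"] = "wt"
    df["feature_junctions"] = df["sample_id"].map(counts).fillna(0).astype(int)
    df["feature_jpmr"] = df["feature_junctions"] / df["mapped_reads"]
    for genotype, grp in df.groupby("genotype"):
        base = grp[grp["day"] == 0]
        if base.empty:
            raise ValueError(f"no Day-0 sample for genotype {genotype!r}")
        mean0 = base["feature_jpmr"].mean()
        sel = df["genotype"] == genotype
        df.loc[sel, "relative_feature_jpmr"] = (
            df.loc[sel, "feature_jpmr"] / mean0 if mean0 > 0 else np.nan
        )

    stat = None
    d0, d1 = day_pair
    if "replicate" in df.columns:
        a = df[df["day"] == d0].set_index(["genotype", "replicate"])["feature_jpmr"]
        b = df[df["day"] == d1].set_index(["genotype", "replicate"])["feature_jpmr"]
        common = a.index.intersection(b.index)
        if len(common) >= 2:
            stat = paired_t_test(a.loc[common], b.loc[common])
        else:
            logger.warning("fewer than 2 matched replicate pairs; paired test skipped")
    return df, stat


# ---------------------------------------------------------------------------
# Normalised feature coverage
# ---------------------------------------------------------------------------

def normalised_feature_coverage(
    depth: dict[str, np.ndarray],
    features: list[Feature],
    mapped_reads: int,
) -> pd.DataFrame:
    """Mean depth over each feature span divided by total mapped reads."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    rows = []
    for f in features:
        track = depth.get(f.contig)
        if track is None or f.end > len(track):
            raise ValueError(f"feature {f.gene_id} outside the depth track")
        rows.append(
            {
                "gene_id": f.gene_id,
                "contig": f.contig,
                "start": f.start,
                "end": f.end,
                "mean_coverage": float(np.mean(track[f.start : f.end])),
            }
        )
    df = pd.DataFrame(rows)
    df["normalised_coverage"] = df["mean_coverage"] / mapped_reads
    return df


def coverage_condition_test(
    cov_a: pd.DataFrame, cov_b: pd.DataFrame
) -> StatResult:
    """One-sample t-test on per-feature normalised-coverage differences (a - b)."""
    merged = cov_a.merge(cov_b, on="gene_id", suffixes=("_a", "_b"))
    diffs = merged["normalised_coverage_a"] - merged["normalised_coverage_b"]
    return one_sample_t_test(diffs)
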