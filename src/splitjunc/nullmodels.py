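"""Simulation-based null models for junction formation.

Three nulls back the observational claims: uniformly placed random junction
sets matched in size to an observed set (for intersection analyses), a
read-share admixture model of which chromosome pairs free DNA ends would
join if they joined at random, and a planted-insertion validation harness
that exercises the whole calling pipeline against a known truth table.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .calling import FilterConfig, call_sample
from .genome import GenomeModel, GenomeError, random_positions


def simulate_random_junctions(
    genome: GenomeModel,
    n: int,
    nuclear_only: bool = True,
    rng: np.random.Generator | int = 0,
    sample_id: str = "simulated",
) -> pd.DataFrame:
    """A size-*n* set of uniformly located junctions (both ends uniform).

    Contigs are chosen proportionally to length so the draw is uniform over
    the (nuclear) genome; used as the matched null for intersection tests.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n < 0:
        raise ValueError("n must be >= 0")
    names = genome.nuclear_contigs if nuclear_only else genome.contig_names
    if not names:
        raise GenomeError("genome has no nuclear contig")
    rank = genome.rank
    ends_a = random_positions(genome, n, rng, nuclear_only=nuclear_only)
    ends_b = random_positions(genome, n, rng, nuclear_only=nuclear_only)
    rows = []
    for i, ((ca, pa), (cb, pb)) in enumerate(zip(ends_a, ends_b)):
        if (rank[ca], pa) > (rank[cb], pb):
            (ca, pa), (cb, pb) = (cb, pb), (ca, pa)
        rows.append(
            {
                "sample_id": sample_id,
                "contig_a": ca, "pos_a": pa, "strand_a": "+",
                "contig_b": cb, "pos_b": pb, "strand_b": "+",
                "sig_class": None, "sig_length": None,
                "read_id": f"{sample_id}.r{i:06d}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "contig_a", "pos_a", "strand_a", "contig_b",
                 "pos_b", "strand_b", "sig_class", "sig_length", "read_id"],
    )


@dataclass
class AdmixtureExpectation:
    """Expected contig-pair junction counts under random end joining.

    ``expected[i, j]`` (upper triangle, i <= j) is the closed-form count
    ``n * 2 * p_i * p_j`` for i != j and ``n * p_i**2`` on the diagonal,
    where p is each contig's share of mapped reads; ``mc_mean``/``mc_sd``
    summarise the Monte-Carlo simulations.
    """

    contigs: list[str]
    proportions: np.ndarray
    n_junctions: int
    expected: np.ndarray
    mc_mean: np.ndarray
    mc_sd: np.ndarray
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.contigs)
        for i in range(k):
            for j in range(i, k):
                rows.append(
                    {
                        "contig_a": self.contigs[i],
                        "contig_b": self.contigs[j],
                        "expected": self.expected[i, j],
                        "mc_mean": self.mc_mean[i, j],
                        "mc_sd": self.mc_sd[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def category_fractions(self, circular: set[str] | list[str]) -> dict[str, float]:
        """Expected fractions of mito-mito / mito-nuclear / nuclear-nuclear pairs."""
        circular = set(circular)
        frac = {"mito-mito": 0.0, "mito-nuclear": 0.0, "nuclear-nuclear": 0.0}
        k = len(self.contigs)
        for i in range(k):
            for j in range(i, k):
                n_circ = (self.contigs[i] in circular) + (self.contigs[j] in circular)
                key = ("nuclear-nuclear", "mito-nuclear", "mito-mito")[n_circ]
                frac[key] += self.expected[i, j]
        total = sum(frac.values())
        return {k_: v / total for k_, v in frac.items()}


def admixture_expectation(
    per_contig_read_counts: dict[str, int],
    n_junctions: int,
    n_sims: int = 1000,
    rng: np.random.Generator | int = 0,
) -> AdmixtureExpectation:
    """Random-admixture expectation of junctions per chromosome pair.

    Each contig's mapped-read count is converted to a proportion of the
    total; every simulated junction draws its two ends independently with
    those proportions (with replacement).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    contigs = list(per_contig_read_counts)
    counts = np.array([per_contig_read_counts[c] for c in contigs], dtype=float)
    if (counts < 0).any() or counts.sum() == 0:
        raise ValueError("read counts must be >= 0 and not all zero")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = counts / counts.sum()
    k = len(contigs)

    expected = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            expected[i, j] = n_junctions * (p[i] ** 2 if i == j else 2 * p[i] * p[j])

    sims = np.zeros((n_sims, k, k))
    for s in range(n_sims):
        ends = rng.choice(k, size=(n_junctions, 2), p=p)
        lo = ends.min(axis=1)
        hi = ends.max(axis=1)
        flat = np.bincount(lo * k + hi, minlength=k * k).reshape(k, k)
        sims[s] = flat
    mc_mean = sims.mean(axis=0)
    mc_sd = sims.std(axis=0, ddof=1) if n_sims > 1 else np.zeros((k, k))
    return AdmixtureExpectation(contigs, p, n_junctions, expected, mc_mean, mc_sd, n_sims)


@dataclass
class HarnessResult:
    sensitivity: float
    n_false_positive: int
    n_truth_junctions: int
    n_recovered: int
    n_called: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def validation_harness(
    genome: GenomeModel | None = None,
    n_events: int = 100,
    fragment_length: int = 100,
    *,
    read_length: int = 126,
    n_background_reads: int = 2_000,
    tolerance: int = 5,
    seed: int = 0,
    workdir: str | Path | None = None,
) -> HarnessResult:
    """Planted-insertion validation of the whole calling pipeline.

    Plants *n_events* insertions of *fragment_length* bp fragments copied
    from elsewhere in the reference, each creating two blunt junctions (one
    per fragment flank).  Reads are synthesized over both flanks, the full
    pipeline is run, and recovered junctions are matched to the truth within
    +/- *tolerance* bp; anything called that matches no truth entry counts
    as a false positive.
    """
    rng = np.random.default_rng(seed)
    if genome is None:
        from .genome import generate_genome

        genome = generate_genome([300_000, 200_000], mito_length=20_000,
                                 n_genes=30, seed=rng.integers(0, 2**31))
    margin = read_length + fragment_length + 10
    origins = random_positions(genome, n_events, rng, nuclear_only=True, margin=margin)
    sites = random_positions(genome, n_events, rng, nuclear_only=True, margin=margin)

    o = read_length // 2
    events = []
    truth_pairs: list[tuple[tuple[str, int], tuple[str, int]]] = []
    for (oc, op), (sc, sp) in zip(origins, sites):
        # left flank junction: genomic site | fragment start
        left = simulate.PlantedRearrangement(
            breakend_a=(sc, sp - 1, "+"), breakend_b=(oc, op, "+"),
            signature_class=simulate.SIG_BLUNT, signature_length=0,
            read_offset=o, read_length=read_length,
        )
        # right flank junction: fragment end | genomic continuation
        right = simulate.PlantedRearrangement(
            breakend_a=(oc, op + fragment_length - 1, "+"), breakend_b=(sc, sp, "+"),
            signature_class=simulate.SIG_BLUNT, signature_length=0,
            read_offset=o, read_length=read_length,
        )
        events.extend([left, right])
        truth_pairs.append(((sc, sp - 1), (oc, op)))
        truth_pairs.append(((oc, op + fragment_length - 1), (sc, sp)))

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        sam_path = Path(tmp) / "harness.sam"
        simulate.write_sample(
            sam_path, genome, events,
            read_length=read_length,
            n_background_reads=n_background_reads,
            sample_id="harness",
            rng=rng,
        )
        called, _, _ = call_sample(sam_path, genome, FilterConfig())

    def matches(row, pair) -> bool:
        (c1, p1), (c2, p2) = pair
        direct = (
            row.contig_a == c1 and abs(row.pos_a - p1) <= tolerance
            and row.contig_b == c2 and abs(row.pos_b - p2) <= tolerance
        )
        flipped = (
            row.contig_a == c2 and abs(row.pos_a - p2) <= tolerance
            and row.contig_b == c1 and abs(row.pos_b - p1) <= tolerance
        )
        return direct or flipped

    recovered = np.zeros(len(truth_pairs), dtype=bool)
    n_fp = 0
    for row in called.itertuples():
        hit = False
        for t, pair in enumerate(truth_pairs):
            if matches(row, pair):
                recovered[t] = True
                hit = True
        if not hit:
            n_fp += 1
    n_truth = len(truth_pairs)
    sensitivity = recovered.sum() / n_truth if n_truth else 1.0
    return HarnessResult(
        sensitivity=float(sensitivity),
        n_false_positive=n_fp,
        n_truth_junctions=n_truth,
        n_recovered=int(recovered.sum()),
        n_called=len(called),
        seed=seed,
    )
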