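"""Feature intersection, depletion/profile/outlier analyses, JPMR metrics."""

import numpy as np
import pandas as pd
import pytest

from splitjunc import (
    coding_depletion_test,
    compute_sample_metrics,
    feature_jpmr,
    gene_end_profile,
    generate_genome,
    junction_hits,
    normalised_feature_coverage,
    utr_outlier_genes,
)
from splitjunc.features import coverage_condition_test, junction_categories
from splitjunc.genome import Feature
from splitjunc.simulate import AgeingSeriesDesign, simulate_ageing_series


def _jdf(rows, **extra):
    df = pd.DataFrame(
        columns=["sample_id", "contig_a", "pos_a", "strand_a", "contig_b", "pos_b", "strand_b", "sig_class", "sig_length", "read_id"],
        data=[
            {"sample_id": s, "contig_a": ca, "pos_a": pa, "strand_a": "+",
             "contig_b": cb, "pos_b": pb, "strand_b": "+",
             "sig_class": "blunt", "sig_length": 0, "read_id": f"r{i}"}
            for i, (s, ca, pa, cb, pb) in enumerate(rows)
        ]
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestIntersection:
    def test_brute_force_interval_oracle(self, genome, rng):
        """Tree-based hit decisions equal an all-pairs containment check."""
        cds = genome.features_of("CDS")
        n = 1_000
        rows = [
            ("s", "chrI", int(rng.integers(0, 100_000)),
             "chrII", int(rng.integers(0, 80_000)))
            for _ in range(n)
        ]
        df = _jdf(rows)
        fast = junction_hits(df, cds)
        slow = np.zeros(n, dtype=bool)
        for i, r in enumerate(df.itertuples()):
            for f in cds:
                if (f.contig == r.contig_a and f.start <= r.pos_a < f.end) or (
                    f.contig == r.contig_b and f.start <= r.pos_b < f.end
                ):
                    slow[i] = True
                    break
        assert (fast == slow).all()

    def test_both_mode_stricter_than_either(self, genome, rng):
        cds = genome.features_of("CDS")
        rows = [("s", "chrI", int(rng.integers(0, 100_000)),
                 "chrI", int(rng.integers(0, 100_000))) for _ in range(300)]
        df = _jdf(rows)
        either = junction_hits(df, cds, mode="either")
        both = junction_hits(df, cds, mode="both")
        assert (both <= either).all()

    def test_flank_window_half_open(self):
        trna = [Feature("chrI", 10_000, 10_080, "+", "tRNA", "t1")]
        inside = _jdf([("s", "chrI", 10_080 + 499, "chrI", 50_000)])
        outside = _jdf([("s", "chrI", 10_080 + 500, "chrI", 50_000)])
        assert junction_hits(inside, trna, flank=500)[0]
        assert not junction_hits(outside, trna, flank=500)[0]


class TestCodingDepletion:
    def test_genome_wide_cds_gives_proportion_one(self, genome):
        cds = [Feature(c, 0, genome.lengths[c], "+", "CDS", f"all_{c}")
               for c in genome.nuclear_contigs]
        sets = [_jdf([("s", "chrI", 5_000 + i, "chrII", 6_000 + i)
                      for i in range(20)]) for _ in range(4)]
        obs, exp, _ = coding_depletion_test(sets, genome, cds, rng=0)
        assert np.allclose(obs, 1.0) and np.allclose(exp, 1.0)

    def test_complete_separation_gives_u_zero(self, genome):
        design = AgeingSeriesDesign(
            days=(0,), replicates=8,
            junction_rate_per_day=(0.1,), indel_rate_per_day=(0.0,),
            background_reads=5_000, coding_depletion=0.0, seed=6,
        )
        bundle = simulate_ageing_series(design, genome, emit_sam=False)
        truth = bundle.truth_junctions()
        sets = [g for _, g in truth.groupby("replicate")]
        obs, exp, stat = coding_depletion_test(sets, genome, rng=1)
        assert obs.max() < exp.min()  # fully depleted -> complete separation
        assert stat.statistic == "U" and stat.value == 0
        assert stat.p_value < 0.001

    def test_empty_replicates_dropped(self, genome):
        sets = [_jdf([]).iloc[0:0]] + [
            _jdf([("s", "chrI", 5_000 + i, "chrII", 6_000)]) for i in range(3)
        ]
        with pytest.raises(ValueError):
            # 3 non-empty replicates remain but each has 1 junction; the
            # empty one must be dropped, not crash
            coding_depletion_test(sets[:2], genome, rng=0)


class TestGeneEndProfile:
    def test_no_junctions_flat_zero(self, genome):
        prof = gene_end_profile(_jdf([]).iloc[0:0], genome.features_of("CDS"))
        assert prof.counts["start"].sum() == 0 and prof.counts["end"].sum() == 0

    def test_minus_strand_offsets_flipped(self):
        # minus-strand CDS end is at its (coordinate) start; 100bp downstream
        # in transcription direction = coordinate start - 100 -> offset +100
        cds = [Feature("chrI", 20_000, 21_000, "-", "CDS", "g1")]
        df = _jdf([("s", "chrI", 20_000 - 100, "chrI", 90_000)])
        prof = gene_end_profile(df, cds, flank=500)
        offsets = np.nonzero(prof.counts["end"])[0] - prof.flank
        assert list(offsets) == [100]

    def test_plus_strand_downstream_positive(self):
        cds = [Feature("chrI", 20_000, 21_000, "+", "CDS", "g1")]
        df = _jdf([("s", "chrI", 21_000 - 1 + 250, "chrI", 90_000)])
        prof = gene_end_profile(df, cds, flank=500)
        offsets = np.nonzero(prof.counts["end"])[0] - prof.flank
        assert list(offsets) == [250]

    def test_defaults_and_bin_conservation(self, genome, rng):
        cds = genome.features_of("CDS")
        rows = [("s", "chrI", int(rng.integers(0, 100_000)),
                 "chrII", int(rng.integers(0, 80_000))) for _ in range(400)]
        prof = gene_end_profile(_jdf(rows), cds)
        assert (prof.flank, prof.smooth, prof.bin_size) == (500, 10, 250)
        for anchor in ("start", "end"):
            assert prof.binned[anchor]["count"].sum() == prof.counts[anchor].sum()

    def test_strandless_features_rejected(self):
        f = Feature("chrI", 100, 200, "+", "CDS", "g")
        bad = Feature("chrI", 300, 400, "-", "CDS", "h")
        object.__setattr__(bad, "strand", "?")
        with pytest.raises(ValueError):
            gene_end_profile(_jdf([]), [f, bad])


class TestUTROutliers:
    def _utrs(self, n=100):
        return [Feature("chrI", 1_000 * i, 1_000 * i + 300, "+", "3UTR", f"g{i}")
                for i in range(1, n + 1)]

    def test_equal_counts_flag_nothing(self):
        utrs = self._utrs(10)
        rows = [("s", "chrI", 1_000 * i + 50, "chrII", 5) for i in range(1, 11)]
        report = utr_outlier_genes(_jdf(rows), utrs)
        assert not report["outlier"].any()  # SD = 0

    def test_single_heavy_utr_flagged(self):
        utrs = self._utrs(100)
        rows = [("s", "chrI", 1_050, "chrII", 5)] * 10  # 10 junctions in g1
        report = utr_outlier_genes(_jdf(rows), utrs)
        # mean 0.1, population SD ~= 0.99, threshold ~= 2.09
        assert report.loc[report["outlier"], "gene_id"].tolist() == ["g1"]

    def test_no_utrs_rejected(self):
        with pytest.raises(ValueError):
            utr_outlier_genes(_jdf([]), [])


class TestSampleMetrics:
    def _samples(self):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "day": [0, 0, 0, 3, 3, 3],
                "genotype": ["wt"] * 6,
                "replicate": [1, 2, 3, 1, 2, 3],
                "mapped_reads": [10**6] * 6,
                "junction_count": [4, 5, 6, 10, 12, 14],
                "indel_read_count": [2, 2, 2, 8, 8, 8],
            }
        )

    def test_jpmr_division(self):
        df = compute_sample_metrics(self._samples())
        assert df.loc[1, "jpmr"] == pytest.approx(5e-6)
        assert df.loc[3, "ipmr"] == pytest.approx(8e-6)

    def test_day0_median_replicate_has_relative_one(self):
        df = compute_sample_metrics(self._samples())
        assert df.loc[1, "relative_jpmr"] == pytest.approx(1.0)  # 5 is the Day-0 median
        assert df.loc[4, "relative_jpmr"] == pytest.approx(12 / 5)

    def test_zero_junctions_zero_jpmr(self):
        s = self._samples()
        s["junction_count"] = 0
        df = compute_sample_metrics(s)
        assert (df["jpmr"] == 0).all()

    def test_missing_day0_rejected(self):
        s = self._samples()
        s["day"] = 3
        with pytest.raises(ValueError):
            compute_sample_metrics(s)

    def test_category_split(self, genome):
        df = _jdf([("s", "chrI", 10, "chrII", 20), ("s", "chrI", 10, "mito", 20),
                   ("s", "mito", 10, "mito", 20)])
        cats = junction_categories(df, genome)
        assert cats.tolist() == ["nDNA-nDNA", "mtDNA-nDNA", "mtDNA-mtDNA"]


class TestFeatureJPMR:
    def _metrics(self, reps=8):
        rows = []
        for day in (0, 3):
            for r in range(1, reps + 1):
                rows.append({"sample_id": f"d{day}r{r}", "day": day, "genotype": "wt",
                             "replicate": r, "mapped_reads": 10**5})
        return pd.DataFrame(rows)

    def test_no_nearby_junctions_zero(self):
        trna = [Feature("chrI", 10_000, 10_080, "+", "tRNA", "t1")]
        df, _ = feature_jpmr(_jdf([]).iloc[0:0], trna, self._metrics(2))
        assert (df["feature_jpmr"] == 0).all()

    def test_flank_boundary_counting(self):
        trna = [Feature("chrI", 10_000, 10_080, "+", "tRNA", "t1")]
        rows = [("d0r1", "chrI", 10_080 + 499, "chrII", 5),
                ("d0r1", "chrI", 10_080 + 501, "chrII", 5)]
        df, _ = feature_jpmr(_jdf(rows), trna, self._metrics(2))
        assert df.set_index("sample_id").loc["d0r1", "feature_junctions"] == 1

    def test_planted_day3_enrichment_detected(self, rng):
        trna = [Feature("chrI", 50_000, 50_080, "+", "tRNA", "t1")]
        rows = []
        for r in range(1, 9):
            for i in range(int(rng.integers(8, 14))):  # day-3 junctions at the tRNA
                rows.append((f"d3r{r}", "chrI", 50_000 + int(rng.integers(0, 80)),
                             "chrII", 5_000))
        df, stat = feature_jpmr(_jdf(rows), trna, self._metrics(8))
        d0 = df[df["day"] == 0]["feature_jpmr"]
        d3 = df[df["day"] == 3]["feature_jpmr"]
        assert d3.mean() > d0.mean()
        assert stat is not None and stat.p_value < 0.05

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            feature_jpmr(_jdf([]), [], self._metrics(2))


class TestFeatureCoverage:
    def test_uniform_depth_normalisation(self):
        feats = [Feature("chrI", 100, 200, "+", "gene", "g1"),
                 Feature("chrI", 300, 450, "+", "gene", "g2")]
        depth = {"chrI": np.full(1_000, 6.0)}
        df = normalised_feature_coverage(depth, feats, mapped_reads=300)
        assert np.allclose(df["normalised_coverage"], 6 / 300)

    def test_mean_arithmetic(self):
        feats = [Feature("chrI", 0, 3, "+", "gene", "g1")]
        depth = {"chrI": np.array([2.0, 4.0, 6.0])}
        df = normalised_feature_coverage(depth, feats, mapped_reads=100)
        assert df["normalised_coverage"].iloc[0] == pytest.approx(0.04)

    def test_identical_conditions_t_near_zero(self, rng):
        feats = [Feature("chrI", 100 * i, 100 * i + 50, "+", "gene", f"g{i}")
                 for i in range(1, 20)]
        depth = {"chrI": rng.poisson(30, size=3_000).astype(float)}
        cov = normalised_feature_coverage(depth, feats, mapped_reads=1_000)
        stat = coverage_condition_test(cov, cov)
        assert abs(stat.value) < 1e-12 or np.isnan(stat.value)
        # identical conditions: every per-feature difference is exactly zero

    def test_feature_outside_track_rejected(self):
        feats = [Feature("chrI", 0, 500, "+", "gene", "g1")]
        with pytest.raises(ValueError):
            normalised_feature_coverage({"chrI": np.zeros(100)}, feats, 10)
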