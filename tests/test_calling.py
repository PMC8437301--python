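"""Split-read extraction, the single-read filter, and the calling pipeline."""

import numpy as np
import pytest

from splitjunc import (
    FilterConfig,
    apply_circularity_filter,
    call_sample,
    count_indel_reads,
    extract_split_reads,
    filter_split_read,
    plant_rearrangement,
    synthesize_split_reads,
)
from splitjunc.calling import (
    AlignmentDataError,
    Junction,
    SplitRead,
    scan_stream,
    segment_from_cigar,
)
from splitjunc.simulate import random_events, _as_editable, _rebuild, sam_header


def _sam(genome, body_lines):
    return sam_header(genome) + "".join(l + "\n" for l in body_lines)


def _record(qname, flag, contig, pos1, mapq, cigar, seq="*", tags=()):
    qual = "*" if seq == "*" else "I" * len(seq)
    return "\t".join(
        [qname, str(flag), contig, str(pos1), str(mapq), cigar, "*", "0", "0",
         seq, qual, *tags]
    )


def _split_read(len_a=66, len_b=65, mapq=(60, 60), clips=None):
    """Synthetic SplitRead with given aligned lengths / mapq / clip patterns."""
    L = 126
    sa = segment_from_cigar(f"{len_a}M{L - len_a}S", "chrI", 1_000, "+", mapq[0])
    sb = segment_from_cigar(f"{L - len_b}S{len_b}M", "chrII", 5_000, "+", mapq[1])
    if clips == "double":
        sb = segment_from_cigar(f"10S{len_b}M{L - len_b - 10}S", "chrII", 5_000, "+", mapq[1])
    return SplitRead("r1", sa, sb, L)


class TestCigarParsing:
    def test_read_intervals_forward(self):
        s = segment_from_cigar("60S66M", "chrI", 999, "+", 60)
        assert (s.read_start, s.read_end) == (60, 126)
        assert (s.ref_start, s.ref_end) == (999, 999 + 66)
        assert (s.clip_left, s.clip_right) == (60, 0)
        assert s.junction_proximal == 999

    def test_read_intervals_reverse_strand_flipped(self):
        # reverse record: left clip in record space = tail of the original read
        s = segment_from_cigar("60S66M", "chrI", 999, "-", 60)
        assert (s.read_start, s.read_end) == (0, 66)

    def test_hard_and_soft_clips_equivalent_for_intervals(self):
        a = segment_from_cigar("60S66M", "chrI", 0, "+", 60)
        b = segment_from_cigar("60H66M", "chrI", 0, "+", 60)
        assert (a.read_start, a.read_end) == (b.read_start, b.read_end)

    def test_indel_ops_shift_ref_not_read(self):
        s = segment_from_cigar("30M2D30M6S", "chrI", 100, "+", 60)
        assert s.read_end - s.read_start == 60
        assert s.ref_end - s.ref_start == 62

    def test_malformed_cigar_raises(self):
        with pytest.raises(ValueError):
            segment_from_cigar("66Q", "chrI", 0, "+", 60)


class TestExtraction:
    def test_unclipped_linear_reads_yield_nothing(self, genome, tmp_path):
        lines = [_record(f"r{i}", 0, "chrI", 1_000 + i, 60, "126M", "A" * 126)
                 for i in range(20)]
        p = tmp_path / "lin.sam"
        p.write_text(_sam(genome, lines))
        assert extract_split_reads(p) == []

    def test_split_read_intervals_match_cigar_arithmetic(self, genome, tmp_path):
        lines = [
            _record("sr1", 0, "chrI", 1_001, 60, "60S66M", "A" * 126,
                    ("SA:Z:chrII,5001,+,60M66S,60,0;",)),
            _record("sr1", 2048, "chrII", 5_001, 60, "60M66H", "A" * 60,
                    ("SA:Z:chrI,1001,+,60S66M,60,0;",)),
        ]
        p = tmp_path / "sr.sam"
        p.write_text(_sam(genome, lines))
        (sr,) = extract_split_reads(p)
        prim, supp = sr.segments
        assert (prim.read_start, prim.read_end) == (60, 126)
        assert (supp.read_start, supp.read_end) == (0, 60)

    def test_multi_supplementary_reads_discarded_and_counted(self, genome, tmp_path):
        sa = "SA:Z:chrII,5001,+,60M66S,60,0;chrII,9001,+,100S26M,60,0;"
        lines = [_record("sr1", 0, "chrI", 1_001, 60, "60S66M", "A" * 126, (sa,))]
        p = tmp_path / "multi.sam"
        p.write_text(_sam(genome, lines))
        splits, stats = scan_stream(p)
        assert splits == []
        assert stats.n_multi_supplementary == 1

    def test_malformed_sa_tag_counted_not_fatal(self, genome, tmp_path):
        lines = [_record("bad", 0, "chrI", 1_001, 60, "60S66M", "A" * 126,
                         ("SA:Z:chrII,oops;",))]
        p = tmp_path / "bad.sam"
        p.write_text(_sam(genome, lines))
        splits, stats = scan_stream(p)
        assert splits == [] and stats.n_parse_errors == 1


class TestFilter:
    def test_short_segment_rejected(self):
        j, reason = filter_split_read(_split_read(len_a=39, len_b=80))
        assert j is None and reason == "short_segment"

    def test_submaximal_mapq_rejected(self):
        j, reason = filter_split_read(_split_read(len_a=66, len_b=60, mapq=(60, 59)))
        assert j is None and reason == "low_mapq"

    def test_double_clipped_segment_rejected(self):
        j, reason = filter_split_read(_split_read(len_a=66, len_b=50, clips="double"))
        assert j is None and reason == "double_clipped"

    def test_compliant_read_emits_junction(self):
        j, reason = filter_split_read(_split_read(len_a=66, len_b=65))
        assert reason is None
        assert (j.contig_a, j.contig_b) == ("chrI", "chrII")

    def test_junction_proximal_coordinates(self):
        j, _ = filter_split_read(_split_read(len_a=66, len_b=65))
        # primary 66M60S at 1000 -> clipped right -> last aligned base
        assert j.pos_a == 1_000 + 66 - 1
        # supplementary 61S65M at 5000 -> clipped left -> first aligned base
        assert j.pos_b == 5_000

    def test_tightening_filter_is_monotone(self, genome, tmp_path):
        rng = np.random.default_rng(77)
        seqs = _as_editable(genome)
        events = random_events(genome, 60, rng, seqs=seqs)
        sam, _ = synthesize_split_reads(_rebuild(genome, seqs), events,
                                        n_background_reads=200, rng=rng)
        p = tmp_path / "mono.sam"
        p.write_text(sam)
        splits = extract_split_reads(p)
        counts = []
        for min_len in (20, 40, 60, 70):
            cfg = FilterConfig(min_segment_length=min_len)
            counts.append(
                sum(filter_split_read(s, cfg)[0] is not None for s in splits)
            )
        assert counts == sorted(counts, reverse=True)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(min_segment_length=0)


class TestCircularity:
    def _junction(self, ca, pa, cb, pb):
        return Junction(ca, pa, "+", cb, pb, "+")

    def test_mito_end_spanning_junction_dropped(self, genome):
        mito_len = genome.lengths["mito"]
        j = self._junction("mito", 50, "mito", mito_len - 30)
        assert apply_circularity_filter([j], genome, end_window=500) == []

    def test_inter_contig_mito_junction_kept(self, genome):
        j = self._junction("chrI", 1_000, "mito", 50)
        assert apply_circularity_filter([j], genome, end_window=500) == [j]

    def test_linear_contig_end_junction_kept(self, genome):
        j = self._junction("chrI", 50, "chrI", genome.lengths["chrI"] - 30)
        assert apply_circularity_filter([j], genome, end_window=500) == [j]


class TestIndelCounting:
    def test_counts_indel_reads_once_each(self, genome, tmp_path):
        lines = [
            _record("a", 0, "chrI", 1_001, 60, "126M", "A" * 126),
            _record("b", 0, "chrI", 2_001, 60, "20M1I105M", "A" * 126),
            _record("c", 0, "chrI", 3_001, 60, "25M2D101M", "A" * 126),
            # a split read with an insertion op is NOT an indel read
            _record("d", 0, "chrI", 4_001, 60, "30M1I30M65S", "A" * 126,
                    ("SA:Z:chrII,5001,+,61S65M,60,0;",)),
            # multiple indel ops still count once
            _record("e", 0, "chrI", 5_001, 60, "40M1I40M2D45M", "A" * 126),
        ]
        p = tmp_path / "ind.sam"
        p.write_text(_sam(genome, lines))
        assert count_indel_reads(p) == 3

    def test_all_plain_matches_count_zero(self, genome, tmp_path):
        lines = [_record(f"r{i}", 0, "chrI", 1_001, 60, "50M", "A" * 50)
                 for i in range(5)]
        p = tmp_path / "plain.sam"
        p.write_text(_sam(genome, lines))
        assert count_indel_reads(p) == 0


class TestCallSample:
    def test_recoverable_events_called_at_exact_truth_coordinates(self, genome, tmp_path):
        rng = np.random.default_rng(5)
        seqs = _as_editable(genome)
        events = random_events(genome, 10, rng, seqs=seqs)
        edited = _rebuild(genome, seqs)
        sam, truth = synthesize_split_reads(edited, events, n_background_reads=500,
                                            sample_id="t", rng=rng)
        p = tmp_path / "t.sam"
        p.write_text(sam)
        df, metrics, _ = call_sample(p, edited, sample_meta={"sample_id": "t"})
        truth_df = truth.to_frame()
        recoverable = truth_df[truth_df["recoverable"]]
        assert len(df) == len(recoverable)
        called = {(r.contig_a, r.pos_a, r.contig_b, r.pos_b, r.sig_class, r.sig_length)
                  for r in df.itertuples()}
        for t in recoverable.itertuples():
            key = (t.contig_a, t.pos_a, t.contig_b, t.pos_b, t.sig_class, t.sig_length)
            alt = (t.contig_b, t.pos_b, t.contig_a, t.pos_a, t.sig_class, t.sig_length)
            assert key in called or alt in called

    def test_empty_alignment_file_gives_zero_counts(self, genome, tmp_path):
        p = tmp_path / "empty.sam"
        p.write_text(sam_header(genome))
        df, metrics, _ = call_sample(p, genome)
        assert len(df) == 0 and metrics.junction_count == 0
        assert metrics.indel_read_count == 0

    def test_unrecoverable_only_fixture_yields_no_junctions(self, genome, tmp_path):
        ev, edited = plant_rearrangement(
            genome, "microhomology", 5, ("chrI", 50_000), ("chrII", 40_000),
            read_offset=10,
        )
        sam, truth = synthesize_split_reads(edited, [ev], n_background_reads=100, rng=0)
        p = tmp_path / "ur.sam"
        p.write_text(sam)
        df, _, _ = call_sample(p, edited)
        assert truth.recoverable() == [] and len(df) == 0

    def test_contig_mismatch_is_fatal(self, genome, tmp_path):
        other = type(genome)(
            [c for c in genome.contigs if c.name != "mito"], []
        )
        p = tmp_path / "mm.sam"
        p.write_text(sam_header(genome))
        with pytest.raises(AlignmentDataError):
            call_sample(p, other)

    def test_missing_file_is_fatal(self, genome, tmp_path):
        with pytest.raises(AlignmentDataError):
            call_sample(tmp_path / "nope.sam", genome)


class TestFilterOracle:
    def test_brute_force_reevaluation_agrees(self, genome, tmp_path):
        """Independent re-check of every filter predicate on the raw segments."""
        rng = np.random.default_rng(123)
        seqs = _as_editable(genome)
        events = random_events(genome, 150, rng, seqs=seqs)
        # include marginal events around the 40bp threshold
        sam, _ = synthesize_split_reads(_rebuild(genome, seqs), events,
                                        n_background_reads=1_000, rng=rng)
        p = tmp_path / "oracle.sam"
        p.write_text(sam)
        splits = extract_split_reads(p)
        cfg = FilterConfig()
        mismatches = 0
        for sr in splits:
            verdict = filter_split_read(sr, cfg)[0] is not None
            expect = all(
                (s.read_end - s.read_start) >= 40
                and s.mapq == 60
                and not (s.clip_left > 0 and s.clip_right > 0)
                for s in (sr.segment_primary, sr.segment_supplementary)
            )
            mismatches += verdict != expect
        assert mismatches == 0 and len(splits) == 150
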