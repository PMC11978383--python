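"""Identity/coverage statistics, gap divergence, pseudo-MAF, conservation,
filtering."""

import pytest

from alnkit.core import AlnError, GenomeInterval, PairwiseBlock, Strand, cigar_parse
from alnkit.stats import (
    FilterSpec,
    block_stat,
    block_stats,
    conservation,
    coverage,
    filter_blocks,
    gap_divergence,
    pseudo_maf,
)
from alnkit.synthetic import SimConfig, simulate_pair

from conftest import write_fasta_file


def _block(cigar, t_aln=None, q_aln=None, tstart=0, tsize=None, qsize=None,
           strand="+", tname="t", qname="q"):
    cig = cigar_parse(cigar)
    tsize = tsize or tstart + cig.target_span
    qsize = qsize or cig.query_span
    return PairwiseBlock(
        target_name=tname, target_size=tsize,
        target_start=tstart, target_end=tstart + cig.target_span,
        query_name=qname, query_size=qsize, query_strand=Strand(strand),
        query_start=0, query_end=cig.query_span,
        cigar=cig, target_aln=t_aln, query_aln=q_aln,
    )


class TestBlockStats:
    def test_fixture_counts(self, fixture_block):
        s = block_stat(fixture_block)
        assert (s.columns, s.matches, s.mismatches) == (10, 8, 1)
        assert (s.ins_events, s.ins_bases, s.del_events, s.del_bases) == (1, 1, 0, 0)
        assert s.identity_gap_compressed == pytest.approx(8 / 9)
        assert s.identity_overall == pytest.approx(0.8)

    def test_identity_block(self):
        s = block_stat(_block("6="))
        assert s.identity_gap_compressed == s.identity_overall == 1.0

    def test_deletion_event_counting(self):
        s = block_stat(_block("2=3D2="))
        assert (s.del_events, s.del_bases) == (1, 3)

    def test_partition_identity_on_synthetic(self):
        for seed in (1, 5, 11):
            sim = simulate_pair(SimConfig(length=3000, seed=seed))
            s = block_stat(sim.block)
            assert s.matches + s.mismatches + s.ins_bases + s.del_bases == s.columns

    def test_aggregate_is_length_weighted_sum(self, fixture_block):
        per, agg = block_stats([fixture_block, _block("6=")])
        assert agg.columns == 16
        assert agg.matches == 14
        assert agg.identity_overall == pytest.approx(14 / 16)

    def test_m_without_bases_rejected(self):
        from alnkit.core import FormatError

        with pytest.raises(FormatError, match="M"):
            block_stat(_block("5M"))


class TestCoverage:
    def test_full_cover(self, fixture_block):
        cov = coverage([fixture_block])
        assert cov["t.chr1"] == (9, 9, 1.0)

    def test_union_not_sum(self):
        b1 = _block("5=", tsize=9)
        b2 = _block("6=", tstart=3, tsize=9)
        cov = coverage([b1, b2])
        assert cov["t"][1] == 9  # union of [0,5) and [3,9)

    def test_reorder_and_duplicate_invariant(self):
        b1 = _block("5=", tsize=9)
        b2 = _block("6=", tstart=3, tsize=9)
        assert coverage([b1, b2]) == coverage([b2, b1, b1])

    def test_named_sequence_without_blocks(self):
        cov = coverage([_block("5=", tsize=9)], sizes={"t": 9, "other": 100})
        assert cov["other"] == (100, 0, 0.0)

    def test_query_side(self, fixture_block):
        cov = coverage([fixture_block], by="query")
        assert cov["q.chr1"] == (10, 10, 1.0)


class TestGapDivergence:
    def test_fixture_single_window(self, fixture_block):
        (w,) = gap_divergence([fixture_block], window=1_000_000)
        assert (w.aligned_cols, w.mismatch_cols, w.gap_cols) == (10, 1, 1)
        assert w.gap_divergence == pytest.approx(0.2)
        assert w.mismatch_divergence == pytest.approx(0.1)

    def test_identity_alignment_zero(self):
        (w,) = gap_divergence([_block("8=")], window=100)
        assert w.gap_divergence == 0.0

    def test_window_sums_equal_block_totals(self):
        sim = simulate_pair(SimConfig(length=5000, seed=2))
        s = block_stat(sim.block)
        for window in (100, 999, 1_000_000):
            ws = gap_divergence([sim.block], window=window)
            assert sum(w.aligned_cols for w in ws) == s.columns
            assert sum(w.mismatch_cols for w in ws) == s.mismatches
            assert sum(w.gap_cols for w in ws) == s.ins_bases + s.del_bases

    def test_insertion_anchors_to_previous_window(self):
        # 10= then 5I at target pos 9 (window 0), then 10=
        b = _block("10=5I10=")
        ws = gap_divergence([b], window=10)
        w0 = next(w for w in ws if w.start == 0)
        assert w0.gap_cols == 5
        assert w0.aligned_cols == 15


class TestPseudoMaf:
    @pytest.fixture
    def ref_fasta(self, tmp_path):
        from alnkit.io.fasta import open_fasta

        path = write_fasta_file(tmp_path / "ref.fa", [("t.chr1", "ACGTTGCAT")])
        return open_fasta(str(path))

    def test_single_sample_projection(self, fixture_block, ref_fasta):
        region = GenomeInterval("t.chr1", 0, 9)
        m = pseudo_maf([("s1", [fixture_block])], "t.chr1", region, ref_fasta)
        # insertion G dropped; mismatch A at ref offset 3 retained
        assert m.rows["s1"] == "ACGATGCAT"
        assert m.ref_row == "ACGTTGCAT"

    def test_uncovered_sample_is_stars(self, ref_fasta):
        region = GenomeInterval("t.chr1", 0, 9)
        m = pseudo_maf([("empty", [])], "t.chr1", region, ref_fasta)
        assert m.rows["empty"] == "*********"

    def test_identical_samples_equal_reference(self, ref_fasta):
        ident = _block(
            "9=", t_aln="ACGTTGCAT", q_aln="ACGTTGCAT",
            tname="t.chr1", qname="q",
        )
        region = GenomeInterval("t.chr1", 0, 9)
        m = pseudo_maf(
            [("a", [ident]), ("b", [ident])], "t.chr1", region, ref_fasta
        )
        assert m.rows["a"] == m.rows["b"] == m.ref_row

    def test_deletion_marked_distinctly_from_unaligned(self, ref_fasta):
        b = _block(
            "3=3D3=", t_aln="ACGTTGCAT", q_aln="ACG---CAT",
            tname="t.chr1", qname="q",
        )
        region = GenomeInterval("t.chr1", 0, 9)
        m = pseudo_maf([("s", [b])], "t.chr1", region, ref_fasta)
        assert m.rows["s"] == "ACG---CAT"

    def test_overlap_resolved_most_matches_first(self, ref_fasta):
        good = _block(
            "9=", t_aln="ACGTTGCAT", q_aln="ACGTTGCAT",
            tname="t.chr1", qname="q",
        )
        bad = _block(
            "7X1=1X", t_aln="ACGTTGCAT", q_aln="CAAAAAAAA",
            tname="t.chr1", qname="q",
        )
        region = GenomeInterval("t.chr1", 0, 9)
        m = pseudo_maf([("s", [bad, good])], "t.chr1", region, ref_fasta)
        assert m.rows["s"] == "ACGTTGCAT"  # good block wins despite input order

    def test_row_length_always_region_length(self, fixture_block, ref_fasta):
        region = GenomeInterval("t.chr1", 2, 7)
        m = pseudo_maf([("s1", [fixture_block])], "t.chr1", region, ref_fasta)
        assert len(m.rows["s1"]) == 5

    def test_target_name_mismatch_rejected(self, fixture_block, ref_fasta):
        from alnkit.core import FormatError

        with pytest.raises(FormatError, match="reference"):
            pseudo_maf(
                [("s1", [fixture_block])], "t.chr1",
                GenomeInterval("elsewhere", 0, 9), ref_fasta,
            )


class TestConservation:
    def _matrix(self, fixture_block, tmp_path):
        from alnkit.io.fasta import open_fasta

        path = write_fasta_file(tmp_path / "ref.fa", [("t.chr1", "ACGTTGCAT")])
        ref = open_fasta(str(path))
        return pseudo_maf(
            [("s1", [fixture_block])], "t.chr1",
            GenomeInterval("t.chr1", 0, 9), ref,
        )

    def test_match_and_mismatch_positions(self, fixture_block, tmp_path):
        scores = conservation(self._matrix(fixture_block, tmp_path))
        assert (scores[0].n_aligned, scores[0].n_match, scores[0].score) == (1, 1, 1.0)
        assert (scores[3].n_match, scores[3].score) == (0, 0.0)  # ref T, sample A

    def test_unaligned_counts_against_default_denominator(self, tmp_path):
        from alnkit.io.fasta import open_fasta

        path = write_fasta_file(tmp_path / "ref.fa", [("t.chr1", "ACGTTGCAT")])
        ref = open_fasta(str(path))
        m = pseudo_maf(
            [("covered", []), ("also", [])], "t.chr1",
            GenomeInterval("t.chr1", 0, 3), ref,
        )
        default = conservation(m)
        aligned_only = conservation(m, aligned_only=True)
        assert all(s.score == 0.0 for s in default)
        assert all(s.n_aligned == 0 for s in aligned_only)

    def test_no_samples_rejected(self, fixture_block, tmp_path):
        m = self._matrix(fixture_block, tmp_path)
        m.sample_names = []
        with pytest.raises(AlnError, match="no samples"):
            conservation(m)


class TestFilter:
    def test_threshold_boundary(self, fixture_block):
        kept = list(filter_blocks([fixture_block], FilterSpec(min_block_columns=10)))
        assert kept == [fixture_block]
        kept = list(filter_blocks([fixture_block], FilterSpec(min_block_columns=11)))
        assert kept == []

    def test_empty_spec_keeps_everything(self, fixture_block):
        assert list(filter_blocks([fixture_block], FilterSpec())) == [fixture_block]

    def test_identity_threshold(self, fixture_block):
        spec = FilterSpec(min_identity_gap_compressed=0.95)
        assert list(filter_blocks([fixture_block], spec)) == []  # 8/9 < 0.95

    def test_name_lists(self, fixture_block):
        keep = FilterSpec(allow_names=frozenset({"t.chr1"}))
        drop = FilterSpec(deny_names=frozenset({"q.chr1"}))
        assert list(filter_blocks([fixture_block], keep)) == [fixture_block]
        assert list(filter_blocks([fixture_block], drop)) == []

    def test_order_preserved(self):
        blocks = [_block("5="), _block("7="), _block("3=")]
        spec = FilterSpec(min_block_columns=4)
        assert list(filter_blocks(blocks, spec)) == blocks[:2]
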