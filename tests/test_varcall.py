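"""Variant calling from alignment signatures and VCF left-normalization."""

import pytest

from alnkit.core import GenomeInterval, PairwiseBlock, Strand, cigar_parse
from alnkit.indexing import chunk_maf_block
from alnkit.io.fasta import open_fasta, fasta_fetch
from alnkit.io.maf import maf_block_to_pairwise, pairwise_to_maf_block
from alnkit.synthetic import SimConfig, flip_query_strand, simulate_pair
from alnkit.varcall import (
    CallConfig,
    Variant,
    call_block,
    call_variants,
    normalize_variant,
    normalize_variants,
)

from conftest import write_fasta_file


def _keys(variants):
    return [(v.chrom, v.pos, v.ref, v.alt, v.kind) for v in variants]


class TestCallBlock:
    def test_fixture_snp_and_insertion(self, fixture_block):
        got = call_variants([fixture_block])
        assert _keys(got) == [
            ("t.chr1", 4, "T", "A", "SNP"),
            ("t.chr1", 8, "A", "AG", "INS"),
        ]
        assert got[1].svlen == 1

    def test_deletion_signature(self):
        block = PairwiseBlock(
            target_name="t", target_size=7, target_start=0, target_end=7,
            query_name="q", query_size=4, query_strand=Strand("+"),
            query_start=0, query_end=4, cigar=cigar_parse("2=3D2="),
            target_aln="AAGGGTT", query_aln="AA---TT",
        )
        got = call_variants([block])
        assert _keys(got) == [("t", 2, "AGGG", "A", "DEL")]
        assert got[0].svlen == -3
        assert got[0].end == 5

    def test_identity_yields_nothing(self):
        block = PairwiseBlock(
            target_name="t", target_size=4, target_start=0, target_end=4,
            query_name="q", query_size=4, query_strand=Strand("+"),
            query_start=0, query_end=4, cigar=cigar_parse("4="),
            target_aln="ACGT", query_aln="ACGT",
        )
        assert call_variants([block]) == []

    def test_requires_aligned_strings(self):
        from alnkit.core import FormatError

        block = PairwiseBlock(
            target_name="t", target_size=4, target_start=0, target_end=4,
            query_name="q", query_size=4, query_strand=Strand("+"),
            query_start=0, query_end=4, cigar=cigar_parse("4="),
        )
        with pytest.raises(FormatError, match="aligned base strings"):
            call_block(block)

    def test_leading_deletion_anchors_on_following_base(self, caplog):
        block = PairwiseBlock(
            target_name="t", target_size=5, target_start=0, target_end=5,
            query_name="q", query_size=3, query_strand=Strand("+"),
            query_start=0, query_end=3, cigar=cigar_parse("2D3="),
            target_aln="GGACT", query_aln="--ACT",
        )
        with caplog.at_level("WARNING"):
            (v,) = call_variants([block])
        assert "following base" in caplog.text
        assert (v.pos, v.ref, v.alt) == (1, "GGA", "A")

    def test_minus_strand_called_in_target_coordinates(self, fixture_block):
        flipped = flip_query_strand(fixture_block)
        plus = call_variants([fixture_block])
        minus = call_variants([flipped])
        assert _keys(minus) == _keys(plus)
        # forward-strand query positions reflect through the flip
        for p, m in zip(plus, minus):
            assert m.query_pos == fixture_block.query_size - p.query_pos + 1

    def test_sv_tagging_threshold(self):
        sim = simulate_pair(
            SimConfig(length=4000, snp_rate=0, ins_rate=0, del_rate=0,
                      sv_count=2, sv_len=80, seed=7)
        )
        got = call_variants([sim.block])
        assert len(got) == 2
        assert all(v.is_sv for v in got)
        short = call_variants([sim.block], config=CallConfig(sv_min_len=100))
        assert not any(v.is_sv for v in short)

    def test_kind_selection(self, fixture_block):
        only_snp = call_variants(
            [fixture_block], config=CallConfig(emit=frozenset({"SNP"}))
        )
        assert [v.kind for v in only_snp] == ["SNP"]

    def test_ref_alleles_match_target_fasta(self, tmp_path):
        sim = simulate_pair(SimConfig(length=3000, seed=13))
        path = write_fasta_file(tmp_path / "t.fa", [(sim.target_name, sim.target_seq)])
        tfa = open_fasta(str(path))
        for v in call_variants([sim.block]):
            got = fasta_fetch(
                tfa, GenomeInterval(v.chrom, v.pos - 1, v.pos - 1 + len(v.ref))
            )
            assert got.upper() == v.ref

    def test_invariant_under_chunking(self, fixture_block):
        whole = call_variants([fixture_block])
        chunks = chunk_maf_block(pairwise_to_maf_block(fixture_block), 5)
        rejoined = call_variants([maf_block_to_pairwise(c) for c in chunks])
        assert _keys(rejoined) == _keys(whole)


class TestNormalize:
    @pytest.fixture
    def repeat_fasta(self, tmp_path):
        path = write_fasta_file(tmp_path / "rep.fa", [("c", "CAAAT")])
        return open_fasta(str(path))

    @staticmethod
    def _apply(seq: str, v: Variant) -> str:
        """Oracle: apply a variant to the sequence (1-based pos)."""
        i = v.pos - 1
        assert seq[i:i + len(v.ref)].upper() == v.ref
        return seq[:i] + v.alt + seq[i + len(v.ref):]

    def test_left_shift_in_homopolymer_matches_brute_force(self, repeat_fasta):
        # DEL of one A in CAAAT called at pos 3 -> leftmost equivalent
        # representation (what bcftools norm emits)
        v = Variant(chrom="c", pos=3, ref="AA", alt="A", kind="DEL", svlen=-1,
                    end=4, query_name="q", query_pos=1)
        n = normalize_variant(v, repeat_fasta)
        assert (n.pos, n.ref, n.alt) == (1, "CA", "C")
        # brute force: enumerate every 2-bp deletion representation and keep
        # those producing the same haplotype; pos 1 is the leftmost
        seq = "CAAAT"
        haplo = self._apply(seq, v)
        equivalents = [
            p for p in range(1, 5)
            if self._apply(
                seq, Variant(chrom="c", pos=p, ref=seq[p - 1:p + 1],
                             alt=seq[p - 1], kind="DEL", svlen=-1, end=p + 1,
                             query_name="q", query_pos=1)
            ) == haplo
        ]
        assert n.pos == min(equivalents)

    def test_insertion_shift(self, repeat_fasta):
        v = Variant(chrom="c", pos=4, ref="A", alt="AA", kind="INS", svlen=1,
                    end=4, query_name="q", query_pos=1)
        n = normalize_variant(v, repeat_fasta)
        assert (n.pos, n.ref, n.alt) == (1, "C", "CA")

    def test_non_repeat_indel_fixed_point(self, repeat_fasta):
        v = Variant(chrom="c", pos=1, ref="C", alt="CG", kind="INS", svlen=1,
                    end=1, query_name="q", query_pos=1)
        assert normalize_variant(v, repeat_fasta) == v

    def test_snp_unchanged(self, repeat_fasta):
        v = Variant(chrom="c", pos=3, ref="A", alt="G", kind="SNP", svlen=0,
                    end=3, query_name="q", query_pos=1)
        assert normalize_variant(v, repeat_fasta) == v

    def test_idempotent(self, repeat_fasta):
        v = Variant(chrom="c", pos=3, ref="AA", alt="A", kind="DEL", svlen=-1,
                    end=4, query_name="q", query_pos=1)
        once = normalize_variant(v, repeat_fasta)
        assert normalize_variant(once, repeat_fasta) == once


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_exact_recovery_small_scale(self, tmp_path, seed):
        sim = simulate_pair(
            SimConfig(length=10_000, snp_rate=0.01, ins_rate=0.002,
                      del_rate=0.002, seed=seed)
        )
        path = write_fasta_file(
            tmp_path / "t.fa", [(sim.target_name, sim.target_seq)]
        )
        tfa = open_fasta(str(path))
        calls = normalize_variants(call_variants([sim.block]), tfa)
        truth = normalize_variants(sim.truth, tfa)
        assert _keys(calls) == _keys(truth)
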