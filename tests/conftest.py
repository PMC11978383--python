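"""Shared fixtures: the worked 10-column alignment and file factories.

The canonical hand-checked alignment used throughout::

    target  ACGTTGCA-T   (9 bp)
    query   ACGATGCAGT   (10 bp)

column walk: 3 matches, 1 mismatch (T>A at target offset 3), 4 matches,
1 insertion (G anchored at target offset 7), 1 match — CIGAR 3=1X4=1I1=.
"""

import io
import os

import pytest
from hypothesis import settings

from alnkit.core import PairwiseBlock, Strand, cigar_from_aligned
from alnkit.io.fasta import open_fasta

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

FIX_T = "ACGTTGCAT"
FIX_Q = "ACGATGCAGT"
FIX_T_ALN = "ACGTTGCA-T"
FIX_Q_ALN = "ACGATGCAGT"
FIX_CIGAR = "3=1X4=1I1="

FIX_MAF = (
    "##maf version=1\n"
    "a score=0\n"
    "s t.chr1 0 9 + 9 ACGTTGCA-T\n"
    "s q.chr1 0 10 + 10 ACGATGCAGT\n"
    "\n"
)
FIX_PAF = "q.chr1\t10\t0\t10\t+\tt.chr1\t9\t0\t9\t8\t10\t60\tcg:Z:3=1X4=1I1=\n"
FIX_CHAIN = (
    "chain 8 t.chr1 9 + 0 9 q.chr1 10 + 0 10 1\n"
    "8\t0\t1\n"
    "1\n"
    "\n"
)


@pytest.fixture
def fixture_block() -> PairwiseBlock:
    return PairwiseBlock(
        target_name="t.chr1", target_size=9, target_start=0, target_end=9,
        query_name="q.chr1", query_size=10, query_strand=Strand("+"),
        query_start=0, query_end=10,
        cigar=cigar_from_aligned(FIX_T_ALN, FIX_Q_ALN),
        target_aln=FIX_T_ALN, query_aln=FIX_Q_ALN,
    )


def write_fasta_file(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def fixture_files(tmp_path):
    """Fixture alignment written in all three formats plus both FASTAs."""
    paths = {
        "maf": tmp_path / "fix.maf",
        "paf": tmp_path / "fix.paf",
        "chain": tmp_path / "fix.chain",
        "t_fa": tmp_path / "t.fa",
        "q_fa": tmp_path / "q.fa",
    }
    paths["maf"].write_text(FIX_MAF)
    paths["paf"].write_text(FIX_PAF)
    paths["chain"].write_text(FIX_CHAIN)
    write_fasta_file(paths["t_fa"], [("t.chr1", FIX_T)])
    write_fasta_file(paths["q_fa"], [("q.chr1", FIX_Q)])
    return {k: str(v) for k, v in paths.items()}


@pytest.fixture
def fixture_fastas(fixture_files):
    return (open_fasta(fixture_files["t_fa"]), open_fasta(fixture_files["q_fa"]))
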