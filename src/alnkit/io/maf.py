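"""UCSC MAF (Multiple Alignment Format) reader/writer.

MAF stores blocks introduced by an ``a`` line followed by ``s`` sequence
lines.  An ``s`` line's start is 0-based **strand-relative**: for a ``-``
row it counts from the end of the forward sequence, so the forward-strand
interval is ``[src_size - start - size, src_size - start)``.  This module
converts to the canonical forward frame on the way in and back on the way
out; that conversion is an involution.

Pairwise conversions require exactly two ``s`` rows, the first being the
target/reference.  ``e``/``i``/``q`` annotation lines are skipped with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterator, Optional

from alnkit.core import (
    Cigar,
    FormatError,
    PairwiseBlock,
    Strand,
    cigar_from_aligned,
    revcomp,
)

log = logging.getLogger(__name__)


@dataclass
class MafRow:
    src: str
    start: int  # 0-based, strand-relative
    size: int   # aligned (non-gap) bases
    strand: Strand
    src_size: int
    text: str   # gapped aligned string

    def __post_init__(self) -> None:
        non_gap = len(self.text) - self.text.count("-")
        if non_gap != self.size:
            raise FormatError(
                f"MAF row {self.src}: size {self.size} != {non_gap} non-gap bases"
            )
        if self.start + self.size > self.src_size:
            raise FormatError(
                f"MAF row {self.src}: start+size {self.start + self.size} "
                f"exceeds srcSize {self.src_size}"
            )

    @property
    def forward_start(self) -> int:
        if self.strand.is_forward:
            return self.start
        return self.src_size - self.start - self.size

    @property
    def forward_end(self) -> int:
        return self.forward_start + self.size


@dataclass
class MafBlock:
    rows: list[MafRow]
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise FormatError("MAF block needs at least two 's' rows")
        width = len(self.rows[0].text)
        for row in self.rows[1:]:
            if len(row.text) != width:
                raise FormatError(
                    f"MAF block: row {row.src} text length {len(row.text)} "
                    f"!= {width}"
                )

    @property
    def target(self) -> MafRow:
        return self.rows[0]


def _parse_s_line(fields: list[str]) -> MafRow:
    if len(fields) != 7:
        raise FormatError(f"MAF 's' line has {len(fields)} fields, expected 7")
    _, src, start, size, strand, src_size, text = fields
    return MafRow(
        src=src,
        start=int(start),
        size=int(size),
        strand=Strand(strand),
        src_size=int(src_size),
        text=text,
    )


def read_maf_with_offsets(stream: IO[bytes]) -> Iterator[tuple[int, MafBlock]]:
    """Yield ``(byte_offset_of_a_line, MafBlock)`` in file order."""
    offset = 0
    a_offset: Optional[int] = None
    score: Optional[float] = None
    rows: list[MafRow] = []

    def flush() -> Optional[tuple[int, MafBlock]]:
        nonlocal rows, score, a_offset
        if a_offset is None:
            return None
        if not rows:
            raise FormatError("truncated MAF block: 'a' line with no 's' rows")
        out = (a_offset, MafBlock(rows=rows, score=score))
        rows, score, a_offset = [], None, None
        return out

    for raw in stream:
        line_offset = offset
        offset += len(raw)
        line = raw.decode("ascii").rstrip("\r\n")
        if not line or line.startswith("#"):
            item = flush()
            if item:
                yield item
            continue
        tag = line[0]
        if tag == "a":
            item = flush()
            if item:
                yield item
            a_offset = line_offset
            score = None
            for kv in line.split()[1:]:
                if kv.startswith("score="):
                    try:
                        score = float(kv[6:])
                    except ValueError as exc:
                        raise FormatError(f"bad MAF score: {kv!r}") from exc
        elif tag == "s":
            if a_offset is None:
                raise FormatError("MAF 's' line outside a block")
            rows.append(_parse_s_line(line.split()))
        elif tag in "eiq":
            log.warning("skipping MAF '%s' annotation line", tag)
        else:
            raise FormatError(f"unrecognized MAF line: {line[:40]!r}")
    item = flush()
    if item:
        yield item


def read_maf(stream: IO[bytes]) -> Iterator[MafBlock]:
    """Yield :class:`MafBlock` objects from a binary MAF stream."""
    for _, block in read_maf_with_offsets(stream):
        yield block


def format_maf_block(block: MafBlock) -> str:
    score = block.score if block.score is not None else 0
    if isinstance(score, float) and score.is_integer():
        score = int(score)
    lines = [f"a score={score}"]
    for row in block.rows:
        lines.append(
            f"s {row.src} {row.start} {row.size} {row.strand} "
            f"{row.src_size} {row.text}"
        )
    return "\n".join(lines) + "\n\n"


def write_maf(blocks, stream: IO[str], header: bool = True) -> None:
    if header:
        stream.write("##maf version=1\n")
    for block in blocks:
        stream.write(format_maf_block(block))


# ---------------------------------------------------------------------------
# canonical-model boundary


def maf_block_to_pairwise(block: MafBlock) -> PairwiseBlock:
    """Convert a 2-row MAF block to the canonical forward-target frame.

    Strand-relative starts become forward coordinates; a ``-`` target row
    is normalised by reverse-complementing both texts and flipping the
    query strand (forward intervals are unchanged by that flip).
    """
    if len(block.rows) != 2:
        raise FormatError(
            f"pairwise required: MAF block has {len(block.rows)} rows"
        )
    t, q = block.rows
    t_text, q_text = t.text, q.text
    q_strand = q.strand
    if not t.strand.is_forward:
        t_text, q_text = revcomp(t_text), revcomp(q_text)
        q_strand = q_strand.flipped()
    cigar = cigar_from_aligned(t_text, q_text)
    # MAF scores are aligner-specific and PAF/Chain carry none comparable;
    # dropping it keeps maf2chain identical to paf2chain(maf2paf(.)).
    score = None
    return PairwiseBlock(
        target_name=t.src,
        target_size=t.src_size,
        target_start=t.forward_start,
        target_end=t.forward_end,
        query_name=q.src,
        query_size=q.src_size,
        query_strand=q_strand,
        query_start=q.forward_start,
        query_end=q.forward_end,
        cigar=cigar,
        target_aln=t_text,
        query_aln=q_text,
        score=score,
    )


def pairwise_to_maf_block(block: PairwiseBlock) -> MafBlock:
    """Render a canonical block as a 2-row MAF block (query strand-relative)."""
    if block.target_aln is None:
        raise FormatError(
            "MAF output needs aligned base strings; reconstruct them from "
            "FASTA first (paf2maf/chain2maf)"
        )
    t_row = MafRow(
        src=block.target_name,
        start=block.target_start,
        size=block.target_end - block.target_start,
        strand=Strand("+"),
        src_size=block.target_size,
        text=block.target_aln,
    )
    q_row = MafRow(
        src=block.query_name,
        start=block.query_rel_start,
        size=block.query_end - block.query_start,
        strand=block.query_strand,
        src_size=block.query_size,
        text=block.query_aln,
    )
    return MafBlock(rows=[t_row, q_row], score=block.score)
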