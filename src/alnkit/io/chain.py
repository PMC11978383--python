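"""UCSC Chain reader/writer.

A chain record is a header line::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by ungapped block lines ``size dt dq`` and a final size-only
line, terminated by a blank line.  Coordinates are **strand-relative**:
for a ``-`` strand they are offsets into the reverse-complemented
sequence.  The target strand is always ``+`` by UCSC convention.

Both sum invariants are verified on read — parsing fails rather than
silently repairing a record::

    sum(size) + sum(dt) == tEnd - tStart
    sum(size) + sum(dq) == qEnd - qStart
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterator

from alnkit.core import FormatError, Strand


@dataclass
class ChainRecord:
    score: int
    tname: str
    tsize: int
    tstrand: Strand
    tstart: int
    tend: int
    qname: str
    qsize: int
    qstrand: Strand
    qstart: int  # strand-relative
    qend: int    # strand-relative
    chain_id: int
    blocks: list[tuple[int, int, int]]  # (size, dt, dq); final entry has dt=dq=0

    def __post_init__(self) -> None:
        if not self.tstrand.is_forward:
            raise FormatError(f"chain {self.chain_id}: target strand must be '+'")
        if not self.blocks:
            raise FormatError(f"chain {self.chain_id}: no blocks")
        for size, dt, dq in self.blocks:
            if size < 1:
                raise FormatError(f"chain {self.chain_id}: block size {size} < 1")
            if dt < 0 or dq < 0:
                raise FormatError(f"chain {self.chain_id}: negative gap length")
        last_size, last_dt, last_dq = self.blocks[-1]
        if last_dt or last_dq:
            raise FormatError(
                f"chain {self.chain_id}: final block must be size-only"
            )
        sum_size = sum(b[0] for b in self.blocks)
        sum_dt = sum(b[1] for b in self.blocks)
        sum_dq = sum(b[2] for b in self.blocks)
        if sum_size + sum_dt != self.tend - self.tstart:
            raise FormatError(
                f"chain {self.chain_id}: size+dt sum {sum_size + sum_dt} != "
                f"target span {self.tend - self.tstart}"
            )
        if sum_size + sum_dq != self.qend - self.qstart:
            raise FormatError(
                f"chain {self.chain_id}: size+dq sum {sum_size + sum_dq} != "
                f"query span {self.qend - self.qstart}"
            )

    # forward-strand query interval (canonical frame)
    @property
    def qstart_forward(self) -> int:
        if self.qstrand.is_forward:
            return self.qstart
        return self.qsize - self.qend

    @property
    def qend_forward(self) -> int:
        if self.qstrand.is_forward:
            return self.qend
        return self.qsize - self.qstart


def read_chain(stream: IO[str]) -> Iterator[ChainRecord]:
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def flush() -> ChainRecord | None:
        nonlocal header, blocks
        if header is None:
            return None
        if not blocks:
            raise FormatError(f"chain {header[12]}: header with no blocks")
        rec = ChainRecord(
            score=int(header[1]),
            tname=header[2], tsize=int(header[3]), tstrand=Strand(header[4]),
            tstart=int(header[5]), tend=int(header[6]),
            qname=header[7], qsize=int(header[8]), qstrand=Strand(header[9]),
            qstart=int(header[10]), qend=int(header[11]),
            chain_id=int(header[12]),
            blocks=blocks,
        )
        header, blocks = None, []
        return rec

    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            rec = flush()
            if rec:
                yield rec
            continue
        if line.startswith("chain"):
            rec = flush()
            if rec:
                yield rec
            fields = line.split()
            if len(fields) != 13:
                raise FormatError(
                    f"chain header has {len(fields)} fields, expected 13"
                )
            header = fields
        else:
            if header is None:
                raise FormatError(f"chain block line outside a record: {line!r}")
            parts = line.split()
            try:
                nums = [int(p) for p in parts]
            except ValueError as exc:
                raise FormatError(
                    f"chain {header[12]}: non-integer block line {line!r}"
                ) from exc
            if len(nums) == 3:
                blocks.append((nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                blocks.append((nums[0], 0, 0))
            else:
                raise FormatError(
                    f"chain {header[12]}: block line needs 1 or 3 fields"
                )
    rec = flush()
    if rec:
        yield rec


def format_chain_record(rec: ChainRecord) -> str:
    head = (
        f"chain {rec.score} {rec.tname} {rec.tsize} {rec.tstrand} "
        f"{rec.tstart} {rec.tend} {rec.qname} {rec.qsize} {rec.qstrand} "
        f"{rec.qstart} {rec.qend} {rec.chain_id}"
    )
    lines = [head]
    for size, dt, dq in rec.blocks[:-1]:
        lines.append(f"{size}\t{dt}\t{dq}")
    lines.append(str(rec.blocks[-1][0]))
    return "\n".join(lines) + "\n\n"


def write_chain(records, stream: IO[str]) -> None:
    for rec in records:
        stream.write(format_chain_record(rec))
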