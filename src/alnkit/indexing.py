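"""MAF indexing, region extraction (with sub-block slicing) and chunking.

The index sidecar is a tiny TSV (``<maf>.idx``) with one line per block —
target-row name, forward start/end and the byte offset of the block's
``a`` line — written atomically.  Granularity is per block; sub-block
slicing is computed on demand via column projection, so the sidecar
stays small even for chromosome-scale blocks.

Region strings on the CLI are 1-based inclusive (``name:start-end``,
samtools convention); BED input is 0-based half-open.  Both are
converted to half-open :class:`~alnkit.core.GenomeInterval` internally.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional

from intervaltree import IntervalTree

from alnkit.core import (
    FormatError,
    GenomeInterval,
    PairwiseBlock,
    iter_column_projections,
    slice_rows_columns,
)
from alnkit.io.common import open_binary_read
from alnkit.io.maf import (
    MafBlock,
    MafRow,
    maf_block_to_pairwise,
    pairwise_to_maf_block,
    read_maf_with_offsets,
)

log = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class MafIndexEntry:
    name: str
    target_start: int
    target_end: int
    byte_offset: int


def parse_region(text: str) -> GenomeInterval:
    """Parse a 1-based inclusive ``name:start-end`` region string."""
    m = _REGION_RE.match(text)
    if not m:
        raise FormatError(f"malformed region {text!r}; expected name:start-end")
    name, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or end < start:
        raise FormatError(f"malformed region {text!r}: need 1 <= start <= end")
    return GenomeInterval(name, start - 1, end)


def read_bed_regions(stream: IO[str]) -> Iterator[GenomeInterval]:
    """Yield 0-based half-open intervals from a BED stream (first 3 cols)."""
    for line in stream:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"BED line needs >= 3 columns: {line!r}")
        yield GenomeInterval(fields[0], int(fields[1]), int(fields[2]))


# ---------------------------------------------------------------------------
# index


def build_index(maf_path: str) -> list[MafIndexEntry]:
    entries: list[MafIndexEntry] = []
    with open_binary_read(maf_path) as fh:
        for offset, block in read_maf_with_offsets(fh):
            t = block.target
            entries.append(
                MafIndexEntry(t.src, t.forward_start, t.forward_end, offset)
            )
    return entries


def index_path_for(maf_path: str) -> str:
    return maf_path + ".idx"


def maf_index(maf_path: str, out_path: Optional[str] = None) -> str:
    """Write the index sidecar for *maf_path* atomically; return its path."""
    entries = build_index(maf_path)
    out_path = out_path or index_path_for(maf_path)
    out_dir = os.path.dirname(os.path.abspath(out_path))
    fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".idx.tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            for e in entries:
                fh.write(f"{e.name}\t{e.target_start}\t{e.target_end}\t{e.byte_offset}\n")
        os.replace(tmp, out_path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return out_path


def load_index(idx_path: str) -> list[MafIndexEntry]:
    entries: list[MafIndexEntry] = []
    prev_offset = -1
    with open(idx_path, encoding="ascii") as fh:
        for line in fh:
            if not line.strip():
                continue
            name, start, end, offset = line.rstrip("\n").split("\t")
            entry = MafIndexEntry(name, int(start), int(end), int(offset))
            if entry.byte_offset <= prev_offset:
                raise FormatError("index offsets not strictly increasing")
            prev_offset = entry.byte_offset
            entries.append(entry)
    return entries


# ---------------------------------------------------------------------------
# extraction


def _index_trees(entries: Iterable[MafIndexEntry]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for e in entries:
        trees.setdefault(e.name, IntervalTree()).addi(
            e.target_start, e.target_end, e.byte_offset
        )
    return trees


def _read_block_at(maf_path: str, offset: int) -> MafBlock:
    with open_binary_read(maf_path) as fh:
        fh.seek(offset)
        for _, block in read_maf_with_offsets(fh):
            return block
    raise FormatError(f"no MAF block at byte offset {offset}")


def slice_block_to_region(
    block: PairwiseBlock, region: GenomeInterval
) -> Optional[MafBlock]:
    """Cut a block to the target region via column projection.

    The retained column range covers every column whose projected target
    position lies inside the region; insertion columns anchored at the
    last in-region target base are retained (they sit between or after
    in-region columns, so the range stays contiguous).  Returns ``None``
    if the slice is empty on the target side.
    """
    lo = max(region.start, block.target_start)
    hi = min(region.end, block.target_end)
    if lo >= hi:
        return None
    c0 = c1 = None
    for col, proj in enumerate(iter_column_projections(block)):
        inside = lo <= proj.target_offset < hi and not proj.before_start
        if inside:
            if c0 is None:
                c0 = col
            c1 = col + 1
    if c0 is None:
        return None
    rows = slice_rows_columns(block, c0, c1)
    return pairwise_to_maf_block(rows.to_block(block))


def maf_extract(
    maf_path: str,
    regions: Iterable[GenomeInterval],
    slice_blocks: bool = False,
    index: Optional[list[MafIndexEntry]] = None,
) -> Iterator[MafBlock]:
    """Yield every block overlapping a region, optionally cut to it.

    Uses the ``.idx`` sidecar when present, building the index on the fly
    otherwise.  Each block is emitted once per overlapping region, in
    region order (blocks within a region in file order).
    """
    if index is None:
        idx_path = index_path_for(maf_path)
        if os.path.exists(idx_path):
            index = load_index(idx_path)
        else:
            index = build_index(maf_path)
    trees = _index_trees(index)
    for region in regions:
        tree = trees.get(region.name)
        if tree is None:
            log.warning("region on absent sequence %r: no blocks", region.name)
            continue
        hits = sorted(tree.overlap(region.start, region.end), key=lambda iv: iv.data)
        for iv in hits:
            block = _read_block_at(maf_path, iv.data)
            if not slice_blocks:
                yield block
                continue
            sliced = slice_block_to_region(maf_block_to_pairwise(block), region)
            if sliced is not None:
                yield sliced


# ---------------------------------------------------------------------------
# chunking


def chunk_maf_block(block: MafBlock, max_columns: int) -> Iterator[MafBlock]:
    """Split one MAF block at column boundaries into <= max_columns pieces.

    Row starts/sizes are recomputed per piece; concatenating the piece
    row texts reproduces the originals exactly.  A piece in which one row
    is entirely gapped (a long deletion/insertion window) keeps that row
    with size 0 for coordinate continuity.
    """
    if max_columns < 1:
        raise ValueError("max_columns must be >= 1")
    width = len(block.target.text)
    if width <= max_columns:
        yield block
        return
    # per-row running strand-relative offsets
    offsets = [row.start for row in block.rows]
    for c0 in range(0, width, max_columns):
        c1 = min(c0 + max_columns, width)
        rows = []
        for i, row in enumerate(block.rows):
            piece = row.text[c0:c1]
            size = len(piece) - piece.count("-")
            rows.append(
                MafRow(
                    src=row.src,
                    start=offsets[i],
                    size=size,
                    strand=row.strand,
                    src_size=row.src_size,
                    text=piece,
                )
            )
            offsets[i] += size
        # a size-0 row (window fully deleted in that sample) is legal MAF
        # and kept for coordinate continuity
        yield MafBlock(rows=rows, score=block.score)


def maf_chunk(blocks: Iterable[MafBlock], max_columns: int) -> Iterator[MafBlock]:
    for block in blocks:
        yield from chunk_maf_block(block, max_columns)
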