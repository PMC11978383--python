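"""Alignment statistics, filtering, pseudo-MAF and conservation scores.

Definitions used throughout (see also the methods note):

* **gap-compressed identity** — matches / (matches + mismatches); indel
  columns are ignored.
* **overall identity** — matches / total alignment columns.
* **gap divergence** — per target window, (mismatch columns + indel
  columns) / all columns assigned to the window; a window with no
  assigned columns is reported as missing.  Insertion columns are
  anchored to the last consumed target base, so every column lands in
  exactly one window and window sums equal whole-alignment totals for
  any window size.
* **pseudo-MAF** — a reference-projected base matrix: one character per
  reference position per sample (aligned query base, ``-`` where the
  reference base is deleted in that sample, ``*`` where unaligned);
  insertions relative to the reference are dropped.
* **conservation score** — per reference position, the fraction of
  non-reference samples whose base matches the reference
  (case-insensitive).  By default unaligned samples count against
  conservation; ``aligned_only`` switches the denominator to the number
  of aligned samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from pyfaidx import Fasta

from alnkit.core import (
    AlnError,
    FormatError,
    GenomeInterval,
    PairwiseBlock,
    bases_match,
)
from alnkit.io.fasta import fasta_fetch


# ---------------------------------------------------------------------------
# per-block statistics


@dataclass
class BlockStat:
    target_name: str
    target_start: int
    target_end: int
    query_name: str
    query_start: int
    query_end: int
    strand: str
    columns: int
    matches: int
    mismatches: int
    ins_events: int
    ins_bases: int
    del_events: int
    del_bases: int

    @property
    def identity_gap_compressed(self) -> float:
        return self.matches / (self.matches + self.mismatches)

    @property
    def identity_overall(self) -> float:
        return self.matches / self.columns


def block_stat(block: PairwiseBlock) -> BlockStat:
    """Per-block counts; raises for an opaque M CIGAR with no bases."""
    cig = block.exact_cigar()
    matches = mismatches = 0
    ins_events = ins_bases = del_events = del_bases = 0
    for op in cig.ops:
        if op.kind == "=":
            matches += op.length
        elif op.kind == "X":
            mismatches += op.length
        elif op.kind == "I":
            ins_events += 1
            ins_bases += op.length
        elif op.kind == "D":
            del_events += 1
            del_bases += op.length
    return BlockStat(
        target_name=block.target_name,
        target_start=block.target_start,
        target_end=block.target_end,
        query_name=block.query_name,
        query_start=block.query_start,
        query_end=block.query_end,
        strand=str(block.query_strand),
        columns=cig.columns,
        matches=matches,
        mismatches=mismatches,
        ins_events=ins_events,
        ins_bases=ins_bases,
        del_events=del_events,
        del_bases=del_bases,
    )


def block_stats(blocks: Iterable[PairwiseBlock]) -> tuple[list[BlockStat], Optional[BlockStat]]:
    """Per-block stats plus a summed aggregate (None for empty input).

    Aggregate identities are length-weighted by construction: they are
    recomputed from the summed counts.
    """
    stats = [block_stat(b) for b in blocks]
    if not stats:
        return [], None
    agg = BlockStat(
        target_name="*", target_start=0, target_end=0,
        query_name="*", query_start=0, query_end=0, strand="+",
        columns=sum(s.columns for s in stats),
        matches=sum(s.matches for s in stats),
        mismatches=sum(s.mismatches for s in stats),
        ins_events=sum(s.ins_events for s in stats),
        ins_bases=sum(s.ins_bases for s in stats),
        del_events=sum(s.del_events for s in stats),
        del_bases=sum(s.del_bases for s in stats),
    )
    return stats, agg


# ---------------------------------------------------------------------------
# coverage


def coverage(
    blocks: Iterable[PairwiseBlock],
    by: str = "target",
    sizes: Optional[dict[str, int]] = None,
) -> dict[str, tuple[int, int, float]]:
    """Union-merged covered bases per sequence on the chosen side.

    Returns ``{name: (size, covered, fraction)}`` plus a ``*`` aggregate
    (total over sequences).  Invariant under block reordering and
    duplication.  Pass *sizes* to also report sequences no block touches
    (covered 0, fraction 0.0).
    """
    if by not in ("target", "query"):
        raise ValueError("by must be 'target' or 'query'")
    intervals: dict[str, list[tuple[int, int]]] = {}
    sizes = dict(sizes) if sizes else {}
    for name in sizes:
        intervals.setdefault(name, [])
    for b in blocks:
        if by == "target":
            name, size, lo, hi = b.target_name, b.target_size, b.target_start, b.target_end
        else:
            name, size, lo, hi = b.query_name, b.query_size, b.query_start, b.query_end
        sizes[name] = size
        intervals.setdefault(name, []).append((lo, hi))
    out: dict[str, tuple[int, int, float]] = {}
    total_size = total_cov = 0
    for name in sorted(intervals):
        merged_cov = 0
        cur_lo = cur_hi = None
        for lo, hi in sorted(intervals[name]):
            if cur_hi is None or lo > cur_hi:
                if cur_hi is not None:
                    merged_cov += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        if cur_hi is not None:
            merged_cov += cur_hi - cur_lo
        size = sizes[name]
        out[name] = (size, merged_cov, merged_cov / size)
        total_size += size
        total_cov += merged_cov
    if out:
        out["*"] = (total_size, total_cov, total_cov / total_size)
    return out


# ---------------------------------------------------------------------------
# windowed gap divergence

DEFAULT_WINDOW = 1_000_000  # 1 Mb segments


@dataclass
class WindowStat:
    target_name: str
    start: int
    end: int
    aligned_cols: int = 0
    mismatch_cols: int = 0
    gap_cols: int = 0

    @property
    def gap_divergence(self) -> Optional[float]:
        if self.aligned_cols == 0:
            return None
        return (self.mismatch_cols + self.gap_cols) / self.aligned_cols

    @property
    def mismatch_divergence(self) -> Optional[float]:
        """Mismatch-only divergence (indel columns excluded from numerator)."""
        if self.aligned_cols == 0:
            return None
        return self.mismatch_cols / self.aligned_cols


def gap_divergence(
    blocks: Iterable[PairwiseBlock], window: int = DEFAULT_WINDOW
) -> list[WindowStat]:
    """Windowed divergence on the target axis.

    Every alignment column is assigned to the window containing its
    projected target position; insertion columns anchor to the preceding
    consumed target base (a leading insertion anchors to the block's
    first target base).  Runs are split at window boundaries, so the
    walk is per-op, not per-column.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    acc: dict[tuple[str, int], WindowStat] = {}

    def bump(name: str, tpos: int, n: int, mismatch: bool, gap: bool) -> None:
        w = tpos // window
        stat = acc.get((name, w))
        if stat is None:
            stat = WindowStat(name, w * window, (w + 1) * window)
            acc[(name, w)] = stat
        stat.aligned_cols += n
        if mismatch:
            stat.mismatch_cols += n
        if gap:
            stat.gap_cols += n

    for block in blocks:
        cig = block.exact_cigar()
        name = block.target_name
        tpos = block.target_start
        for op in cig.ops:
            if op.kind == "I":
                anchor = tpos - 1 if tpos > block.target_start else block.target_start
                bump(name, anchor, op.length, mismatch=False, gap=True)
                continue
            # target-consuming run: split at window boundaries
            remaining = op.length
            while remaining:
                w_end = (tpos // window + 1) * window
                n = min(remaining, w_end - tpos)
                bump(
                    name, tpos, n,
                    mismatch=(op.kind == "X"),
                    gap=(op.kind == "D"),
                )
                tpos += n
                remaining -= n
    return sorted(acc.values(), key=lambda s: (s.target_name, s.start))


# ---------------------------------------------------------------------------
# pseudo-MAF and conservation

UNALIGNED_CHAR = "*"
DELETED_CHAR = "-"


@dataclass
class PseudoMafMatrix:
    ref_name: str
    start: int
    end: int
    ref_row: str
    sample_names: list[str]
    rows: dict[str, str]

    @property
    def length(self) -> int:
        return self.end - self.start


def _fill_sample_row(
    blocks: Sequence[PairwiseBlock], region: GenomeInterval
) -> str:
    """Project one sample's blocks onto the reference interval.

    Overlaps are resolved most-matches-wins (matches counted inside the
    region), ties broken by input order: blocks are visited best-first
    and only write positions no earlier block has claimed.
    """
    L = region.length
    row = [UNALIGNED_CHAR] * L
    claimed = [False] * L

    def region_matches(block: PairwiseBlock) -> int:
        n = 0
        tpos = block.target_start
        cols = zip(block.target_aln, block.query_aln)
        for t, q in cols:
            if t == "-":
                continue
            if region.start <= tpos < region.end and q != "-" and bases_match(t, q):
                n += 1
            tpos += 1
        return n

    order = sorted(
        range(len(blocks)),
        key=lambda i: (-region_matches(blocks[i]), i),
    )
    for i in order:
        block = blocks[i]
        if block.target_aln is None:
            raise FormatError(
                "pseudo-MAF needs aligned base strings; supply FASTAs for "
                "PAF/Chain input"
            )
        tpos = block.target_start
        for t, q in zip(block.target_aln, block.query_aln):
            if t == "-":  # insertion relative to the reference: dropped
                continue
            if region.start <= tpos < region.end:
                k = tpos - region.start
                if not claimed[k]:
                    claimed[k] = True
                    row[k] = DELETED_CHAR if q == "-" else q
            tpos += 1
    return "".join(row)


def pseudo_maf(
    samples: Sequence[tuple[str, Sequence[PairwiseBlock]]],
    ref_name: str,
    region: GenomeInterval,
    ref_fasta: Fasta,
) -> PseudoMafMatrix:
    """Build the reference-projected multi-sample base matrix."""
    if region.name != ref_name:
        raise FormatError(
            f"region sequence {region.name!r} != reference {ref_name!r}"
        )
    ref_row = fasta_fetch(ref_fasta, region)
    rows: dict[str, str] = {}
    names: list[str] = []
    for sample_name, blocks in samples:
        for b in blocks:
            if b.target_name != ref_name:
                raise FormatError(
                    f"sample {sample_name!r}: block target {b.target_name!r} "
                    f"!= reference {ref_name!r}"
                )
        names.append(sample_name)
        rows[sample_name] = _fill_sample_row(
            [b for b in blocks if b.target_name == ref_name], region
        )
    return PseudoMafMatrix(
        ref_name=ref_name, start=region.start, end=region.end,
        ref_row=ref_row, sample_names=names, rows=rows,
    )


@dataclass(frozen=True)
class ConservationScore:
    position: int  # absolute 0-based reference coordinate
    n_aligned: int
    n_match: int
    score: float


def conservation(
    matrix: PseudoMafMatrix, aligned_only: bool = False
) -> list[ConservationScore]:
    """Per-base conservation over the non-reference samples.

    ``*`` (unaligned) and ``-`` (deleted) count as non-matching; ``*`` is
    additionally excluded from ``n_aligned``.  With ``aligned_only`` the
    denominator is ``n_aligned`` instead of the sample count (a position
    aligned in no sample scores 0).
    """
    n_samples = len(matrix.sample_names)
    if n_samples == 0:
        raise AlnError("no samples: conservation needs >= 1 non-reference sample")
    out: list[ConservationScore] = []
    rows = [matrix.rows[name] for name in matrix.sample_names]
    for k in range(matrix.length):
        ref_base = matrix.ref_row[k]
        n_aligned = n_match = 0
        for row in rows:
            c = row[k]
            if c == UNALIGNED_CHAR:
                continue
            n_aligned += 1
            if c != DELETED_CHAR and bases_match(c, ref_base):
                n_match += 1
        denom = n_aligned if aligned_only else n_samples
        score = n_match / denom if denom else 0.0
        out.append(
            ConservationScore(matrix.start + k, n_aligned, n_match, score)
        )
    return out


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterSpec:
    min_block_columns: int = 0
    min_target_span: int = 0
    min_query_span: int = 0
    min_identity_gap_compressed: float = 0.0
    allow_names: Optional[frozenset[str]] = None
    deny_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if min(self.min_block_columns, self.min_target_span, self.min_query_span) < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0.0 <= self.min_identity_gap_compressed <= 1.0):
            raise ValueError("identity threshold must be in [0, 1]")


def filter_blocks(
    blocks: Iterable[PairwiseBlock], spec: FilterSpec
) -> Iterator[PairwiseBlock]:
    """Keep blocks satisfying ALL supplied predicates, order preserved.

    Name lists apply to both target and query names.  Contradictory
    thresholds are not detected — an impossible combination simply keeps
    nothing.
    """
    for b in blocks:
        if b.columns < spec.min_block_columns:
            continue
        if b.target_end - b.target_start < spec.min_target_span:
            continue
        if b.query_end - b.query_start < spec.min_query_span:
            continue
        if spec.allow_names is not None and not (
            b.target_name in spec.allow_names or b.query_name in spec.allow_names
        ):
            continue
        if b.target_name in spec.deny_names or b.query_name in spec.deny_names:
            continue
        if spec.min_identity_gap_compressed > 0.0:
            st = block_stat(b)
            if st.matches + st.mismatches == 0:
                continue
            if st.identity_gap_compressed < spec.min_identity_gap_compressed:
                continue
        yield b
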