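"""Canonical coordinate model and CIGAR arithmetic.

Every alignment format handled by this package is converted into a single
in-memory representation, :class:`PairwiseBlock`, before anything else
happens to it.  The canonical frame is:

* all coordinates are 0-based half-open on the **forward** strand;
* the target is always on the ``+`` strand (a record whose target is on
  ``-`` is normalised by reverse-complementing both rows and flipping the
  query strand);
* the query keeps its strand flag, but ``query_start``/``query_end`` are
  forward-strand coordinates.  Strand-relative offsets exist only at the
  format boundaries (MAF rows and Chain headers).

Alignment columns are described by a run-length CIGAR over the closed
operation set ``{=, X, I, D, M}``: ``=`` match, ``X`` mismatch, ``I``
query-only (insertion), ``D`` target-only (deletion), ``M`` opaque
match-or-mismatch.  ``M`` is kept as-is until base strings are available
to split it; operations that need the distinction without bases raise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

CIGAR_OPS = frozenset("=XIDM")
#: ops that consume a target base
TARGET_OPS = frozenset("=XDM")
#: ops that consume a query base
QUERY_OPS = frozenset("=XIM")

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn-*",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn-*")


class AlnError(Exception):
    """Base class for all package errors."""


class CigarError(AlnError):
    """Malformed CIGAR text or inconsistent CIGAR arithmetic."""


class FormatError(AlnError):
    """Malformed input record in one of the supported formats."""


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC codes, gap-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Strand:
    value: str

    def __post_init__(self) -> None:
        if self.value not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.value!r}")

    def __str__(self) -> str:
        return self.value

    @property
    def is_forward(self) -> bool:
        return self.value == "+"

    def flipped(self) -> "Strand":
        return Strand("-" if self.value == "+" else "+")


FORWARD = Strand("+")
REVERSE = Strand("-")


@dataclass(frozen=True)
class CigarOp:
    kind: str
    length: int

    def __post_init__(self) -> None:
        if self.kind not in CIGAR_OPS:
            raise CigarError(f"unknown CIGAR op {self.kind!r}")
        if self.length < 1:
            raise CigarError(f"CIGAR op length must be >= 1, got {self.length}")


_CIGAR_TOKEN = re.compile(r"(\d+)(\D)")


@dataclass(frozen=True)
class Cigar:
    """Normalised run-length CIGAR: no two consecutive ops share a kind."""

    ops: tuple[CigarOp, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.ops, self.ops[1:]):
            if a.kind == b.kind:
                raise CigarError("cigar not normalized: adjacent ops share kind")

    @classmethod
    def from_ops(cls, ops: Iterable[tuple[str, int]]) -> "Cigar":
        """Build a Cigar, merging adjacent same-kind runs."""
        merged: list[list] = []
        for kind, length in ops:
            if length == 0:
                continue
            if merged and merged[-1][0] == kind:
                merged[-1][1] += length
            else:
                merged.append([kind, length])
        return cls(tuple(CigarOp(k, n) for k, n in merged))

    @property
    def target_span(self) -> int:
        return sum(op.length for op in self.ops if op.kind in TARGET_OPS)

    @property
    def query_span(self) -> int:
        return sum(op.length for op in self.ops if op.kind in QUERY_OPS)

    @property
    def columns(self) -> int:
        return sum(op.length for op in self.ops)

    def render(self) -> str:
        return "".join(f"{op.length}{op.kind}" for op in self.ops)

    def __str__(self) -> str:
        return self.render()

    def reversed(self) -> "Cigar":
        return Cigar(tuple(reversed(self.ops)))

    def has_m(self) -> bool:
        return any(op.kind == "M" for op in self.ops)


def cigar_parse(text: str) -> Cigar:
    """Parse CIGAR text into a normalised :class:`Cigar`.

    Raises :class:`CigarError` naming the byte offset of the first
    offending token for empty input, zero-length runs and unknown op
    letters.
    """
    if not text:
        raise CigarError("empty CIGAR at byte 0")
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR at byte {pos}")
        length = int(m.group(1))
        kind = m.group(2)
        if kind not in CIGAR_OPS:
            raise CigarError(f"unknown CIGAR op {kind!r} at byte {m.start(2)}")
        if length == 0:
            raise CigarError(f"zero-length CIGAR run at byte {m.start(1)}")
        ops.append((kind, length))
        pos = m.end()
    if pos != len(text):
        raise CigarError(f"malformed CIGAR at byte {pos}")
    return Cigar.from_ops(ops)


def bases_match(a: str, b: str) -> bool:
    """Case-insensitive base equality; 'N' never matches anything."""
    au, bu = a.upper(), b.upper()
    return au == bu and au != "N"


def cigar_from_aligned(target_aln: str, query_aln: str) -> Cigar:
    """Derive a =/X/I/D CIGAR from a pair of gapped aligned strings.

    Per column: ``=`` if the bases match (case-insensitive, N never
    matches), ``X`` if both columns hold bases that differ, ``I`` if the
    target is gapped, ``D`` if the query is gapped.
    """
    if len(target_aln) != len(query_aln):
        raise FormatError(
            f"aligned string length mismatch: {len(target_aln)} vs {len(query_aln)}"
        )
    ops: list[tuple[str, int]] = []
    for i, (t, q) in enumerate(zip(target_aln, query_aln)):
        if t == "-" and q == "-":
            raise FormatError(f"doubly-gapped column at index {i}")
        if t == "-":
            kind = "I"
        elif q == "-":
            kind = "D"
        elif bases_match(t, q):
            kind = "="
        else:
            kind = "X"
        ops.append((kind, 1))
    return Cigar.from_ops(ops)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open forward-strand interval on a named sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PairwiseBlock:
    """Canonical pairwise alignment block (see module docstring)."""

    target_name: str
    target_size: int
    target_start: int
    target_end: int
    query_name: str
    query_size: int
    query_strand: Strand
    query_start: int
    query_end: int
    cigar: Optional[Cigar] = None
    target_aln: Optional[str] = None
    query_aln: Optional[str] = None
    score: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 <= self.target_start < self.target_end <= self.target_size):
            raise FormatError(
                f"target interval [{self.target_start},{self.target_end}) "
                f"invalid for size {self.target_size}"
            )
        if not (0 <= self.query_start < self.query_end <= self.query_size):
            raise FormatError(
                f"query interval [{self.query_start},{self.query_end}) "
                f"invalid for size {self.query_size}"
            )
        if self.cigar is not None:
            if self.cigar.target_span != self.target_end - self.target_start:
                raise FormatError(
                    f"cigar target span {self.cigar.target_span} != "
                    f"{self.target_end - self.target_start}"
                )
            if self.cigar.query_span != self.query_end - self.query_start:
                raise FormatError(
                    f"cigar query span {self.cigar.query_span} != "
                    f"{self.query_end - self.query_start}"
                )
        if (self.target_aln is None) != (self.query_aln is None):
            raise FormatError("aligned strings must be given for both rows or neither")
        if self.target_aln is not None:
            if len(self.target_aln) != len(self.query_aln):
                raise FormatError("aligned strings differ in length")
            t_bases = len(self.target_aln) - self.target_aln.count("-")
            q_bases = len(self.query_aln) - self.query_aln.count("-")
            if t_bases != self.target_end - self.target_start:
                raise FormatError(
                    f"target aligned string holds {t_bases} bases, "
                    f"expected {self.target_end - self.target_start}"
                )
            if q_bases != self.query_end - self.query_start:
                raise FormatError(
                    f"query aligned string holds {q_bases} bases, "
                    f"expected {self.query_end - self.query_start}"
                )
            if self.cigar is not None:
                derived = cigar_from_aligned(self.target_aln, self.query_aln)
                if self.cigar.has_m():
                    ok = coarsen_to_m(derived) == coarsen_to_m(self.cigar)
                else:
                    ok = derived == self.cigar
                if not ok:
                    raise FormatError("aligned strings inconsistent with cigar")

    # -- derived views ------------------------------------------------

    @property
    def columns(self) -> int:
        if self.cigar is not None:
            return self.cigar.columns
        return len(self.target_aln)  # type: ignore[arg-type]

    def effective_cigar(self) -> Cigar:
        """The block's CIGAR, deriving it from aligned strings if absent."""
        if self.cigar is not None:
            return self.cigar
        if self.target_aln is None:
            raise FormatError("block carries neither cigar nor aligned strings")
        return cigar_from_aligned(self.target_aln, self.query_aln)

    def exact_cigar(self) -> Cigar:
        """A =/X/I/D CIGAR; splits M from aligned strings, errors without them."""
        cig = self.effective_cigar()
        if not cig.has_m():
            return cig
        if self.target_aln is None:
            raise FormatError(
                "CIGAR contains 'M' and no aligned bases are available to "
                "split it into =/X"
            )
        return cigar_from_aligned(self.target_aln, self.query_aln)

    def with_aligned(self, target_aln: str, query_aln: str) -> "PairwiseBlock":
        """Attach aligned strings, re-splitting any M ops from the bases."""
        cig = cigar_from_aligned(target_aln, query_aln)
        return replace(
            self, target_aln=target_aln, query_aln=query_aln, cigar=cig
        )

    # strand-relative query coordinates (used by MAF rows, Chain headers)
    @property
    def query_rel_start(self) -> int:
        if self.query_strand.is_forward:
            return self.query_start
        return self.query_size - self.query_end

    @property
    def query_rel_end(self) -> int:
        if self.query_strand.is_forward:
            return self.query_end
        return self.query_size - self.query_start


@dataclass(frozen=True)
class ColumnProjection:
    """Result of projecting one alignment column onto the target.

    ``target_offset`` is an absolute 0-based forward target coordinate.
    For insertion (``I``) columns it is the coordinate of the last target
    base consumed before the column (``insertion=True``); a leading
    insertion with no consumed base yet reports ``before_start=True`` and
    ``target_offset`` equal to ``target_start``.
    """

    target_offset: int
    insertion: bool = False
    before_start: bool = False


def iter_column_projections(block: PairwiseBlock) -> Iterator[ColumnProjection]:
    """Project every alignment column of *block* onto the target, in order."""
    cig = block.effective_cigar()
    tpos = block.target_start  # next target base to consume
    for op in cig.ops:
        if op.kind in TARGET_OPS:
            for _ in range(op.length):
                yield ColumnProjection(tpos)
                tpos += 1
        else:  # I
            if tpos == block.target_start:
                proj = ColumnProjection(block.target_start, insertion=True,
                                        before_start=True)
            else:
                proj = ColumnProjection(tpos - 1, insertion=True)
            for _ in range(op.length):
                yield proj


def project_column_to_target(block: PairwiseBlock, column: int) -> ColumnProjection:
    """Project a single 0-based column index onto the target coordinate axis."""
    if column < 0 or column >= block.columns:
        raise IndexError(
            f"column {column} out of range [0, {block.columns})"
        )
    for i, proj in enumerate(iter_column_projections(block)):
        if i == column:
            return proj
    raise AssertionError("unreachable")


def split_m(cigar: Cigar, target_aln: str, query_aln: str) -> Cigar:
    """Split M ops of *cigar* into =/X using the aligned base columns."""
    if not cigar.has_m():
        return cigar
    return cigar_from_aligned(target_aln, query_aln)


def coarsen_to_m(cigar: Cigar) -> Cigar:
    """Collapse =/X into M (the Chain-compatible view of a CIGAR)."""
    return Cigar.from_ops(
        ("M" if op.kind in "=X" else op.kind, op.length) for op in cigar.ops
    )


def slice_block_columns(block: PairwiseBlock, c0: int, c1: int) -> PairwiseBlock:
    """Cut *block* to the column range ``[c0, c1)``, recomputing coordinates.

    Works in column space so it serves both chunking and region slicing.
    The sliced query interval is computed in strand-relative offsets and
    converted back to the canonical forward frame, so minus-strand blocks
    slice correctly.  Requires aligned strings or a cigar; a slice whose
    query side is empty (pure deletion window) keeps forward==rel frames
    consistent by pinning a zero-length interval at the boundary, which
    PairwiseBlock forbids — callers that must represent empty rows (MAF
    chunking) use :func:`slice_rows_columns` instead.
    """
    rows = slice_rows_columns(block, c0, c1)
    return rows.to_block(block)


@dataclass
class SlicedRows:
    """Column-slice of a block, tolerant of empty (size-0) rows."""

    target_start: int
    target_len: int
    query_rel_start: int
    query_len: int
    target_aln: Optional[str]
    query_aln: Optional[str]
    cigar: Cigar

    def to_block(self, parent: PairwiseBlock) -> PairwiseBlock:
        if self.target_len == 0 or self.query_len == 0:
            raise FormatError("slice has an empty row; not representable as a block")
        if parent.query_strand.is_forward:
            qs = self.query_rel_start
        else:
            qs = parent.query_size - (self.query_rel_start + self.query_len)
        return PairwiseBlock(
            target_name=parent.target_name,
            target_size=parent.target_size,
            target_start=self.target_start,
            target_end=self.target_start + self.target_len,
            query_name=parent.query_name,
            query_size=parent.query_size,
            query_strand=parent.query_strand,
            query_start=qs,
            query_end=qs + self.query_len,
            cigar=self.cigar,
            target_aln=self.target_aln,
            query_aln=self.query_aln,
            score=parent.score,
        )


def slice_rows_columns(block: PairwiseBlock, c0: int, c1: int) -> SlicedRows:
    """Column-slice returning raw row data (tolerates size-0 rows)."""
    total = block.columns
    if not (0 <= c0 <= c1 <= total):
        raise IndexError(f"column slice [{c0},{c1}) out of range [0,{total}]")
    cig = block.effective_cigar()
    # walk ops counting consumed target/query before c0 and inside [c0,c1)
    col = 0
    t_before = q_before = 0
    ops_inside: list[tuple[str, int]] = []
    t_inside = q_inside = 0
    for op in cig.ops:
        lo, hi = col, col + op.length
        col = hi
        take_lo, take_hi = max(lo, c0), min(hi, c1)
        before = min(hi, c0) - lo
        if before > 0:
            if op.kind in TARGET_OPS:
                t_before += before
            if op.kind in QUERY_OPS:
                q_before += before
        if take_hi > take_lo:
            n = take_hi - take_lo
            ops_inside.append((op.kind, n))
            if op.kind in TARGET_OPS:
                t_inside += n
            if op.kind in QUERY_OPS:
                q_inside += n
        if lo >= c1:
            break
    t_aln = q_aln = None
    if block.target_aln is not None:
        t_aln = block.target_aln[c0:c1]
        q_aln = block.query_aln[c0:c1]
    return SlicedRows(
        target_start=block.target_start + t_before,
        target_len=t_inside,
        query_rel_start=block.query_rel_start + q_before,
        query_len=q_inside,
        target_aln=t_aln,
        query_aln=q_aln,
        cigar=Cigar.from_ops(ops_inside),
    )
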