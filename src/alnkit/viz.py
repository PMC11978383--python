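"""Dotplot export: segment tables (TSV) and deterministic static SVG.

A dotplot draws the target on the x axis and the query on the y axis;
collinear aligned runs appear as diagonal segments (ascending for ``+``
query strand, descending for ``-``).  Interactivity is left to
downstream viewers — the exports here are plain geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence
from xml.sax.saxutils import escape

from alnkit.core import PairwiseBlock


@dataclass(frozen=True)
class DotSegment:
    tname: str
    tstart: int
    tend: int
    qname: str
    qstart: int  # forward strand
    qend: int
    strand: str
    identity: float


def dot_segments(
    blocks: Iterable[PairwiseBlock], break_at_indel_ge: int = 1
) -> Iterator[DotSegment]:
    """Cut each block into diagonal segments at indels >= the threshold.

    A maximal run of ``{=, X, M}`` columns uninterrupted by a breaking
    indel becomes one segment.  Indels below the threshold are absorbed
    (the segment then spans unequal target/query lengths).  Segment
    identity is match columns / aligned columns, counting opaque ``M``
    as matching (an upper bound when bases are unavailable).
    """
    if break_at_indel_ge < 1:
        raise ValueError("break_at_indel_ge must be >= 1")
    for block in blocks:
        cig = block.effective_cigar()
        fwd = block.query_strand.is_forward
        tpos = block.target_start
        # walk in strand-relative query offsets; convert per segment
        qrel = block.query_rel_start
        seg_t0 = seg_q0 = None
        match = aligned = 0

        def flush() -> Iterator[DotSegment]:
            nonlocal seg_t0, seg_q0, match, aligned
            if seg_t0 is None or aligned == 0:
                seg_t0 = seg_q0 = None
                match = aligned = 0
                return
            if fwd:
                q0, q1 = seg_q0, qrel
            else:
                q0, q1 = block.query_size - qrel, block.query_size - seg_q0
            yield DotSegment(
                tname=block.target_name,
                tstart=seg_t0,
                tend=tpos,
                qname=block.query_name,
                qstart=q0,
                qend=q1,
                strand=str(block.query_strand),
                identity=match / aligned,
            )
            seg_t0 = seg_q0 = None
            match = aligned = 0

        for op in cig.ops:
            if op.kind in "=XM":
                if seg_t0 is None:
                    seg_t0, seg_q0 = tpos, qrel
                aligned += op.length
                if op.kind in "=M":
                    match += op.length
                tpos += op.length
                qrel += op.length
            elif op.kind == "D":
                if op.length >= break_at_indel_ge:
                    yield from flush()
                tpos += op.length
            else:  # I
                if op.length >= break_at_indel_ge:
                    yield from flush()
                qrel += op.length
        yield from flush()


def segments_to_tsv(segments: Iterable[DotSegment], stream: IO[str]) -> None:
    stream.write(
        "tname\ttstart\ttend\tqname\tqstart\tqend\tstrand\tidentity\n"
    )
    for s in segments:
        stream.write(
            f"{s.tname}\t{s.tstart}\t{s.tend}\t{s.qname}\t{s.qstart}\t"
            f"{s.qend}\t{s.strand}\t{s.identity:.6f}\n"
        )


FORWARD_COLOR = "#1f77b4"
REVERSE_COLOR = "#d62728"


def render_svg(
    segments: Sequence[DotSegment],
    target_size: int | None = None,
    query_size: int | None = None,
    width: int = 800,
    height: int = 800,
    margin: int = 60,
) -> str:
    """Render segments as a deterministic standalone SVG document.

    One ``<line>`` element per segment; axes scaled to the sequence
    sizes (or to the segment extent when sizes are not given).  ``-``
    strand segments are drawn in a second colour with descending query
    geometry.  Identical input and options give byte-identical output.
    """
    t_max = target_size or max((s.tend for s in segments), default=1)
    q_max = query_size or max((max(s.qstart, s.qend) for s in segments), default=1)
    plot_w = width - 2 * margin
    plot_h = height - 2 * margin

    def sx(t: float) -> float:
        return margin + plot_w * t / t_max

    def sy(q: float) -> float:
        return height - margin - plot_h * q / q_max  # y grows downward in SVG

    tname = segments[0].tname if segments else "target"
    qname = segments[0].qname if segments else "query"
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect x="{margin}" y="{margin}" width="{plot_w}" height="{plot_h}" '
        'fill="none" stroke="#333" stroke-width="1"/>',
        f'<text x="{width // 2}" y="{height - margin // 3}" '
        f'text-anchor="middle" font-size="14">{escape(tname)}</text>',
        f'<text x="{margin // 3}" y="{height // 2}" text-anchor="middle" '
        f'font-size="14" transform="rotate(-90 {margin // 3} {height // 2})">'
        f"{escape(qname)}</text>",
    ]
    for s in segments:
        color = FORWARD_COLOR if s.strand == "+" else REVERSE_COLOR
        if s.strand == "+":
            y1, y2 = sy(s.qstart), sy(s.qend)
        else:  # descending query geometry
            y1, y2 = sy(s.qend), sy(s.qstart)
        parts.append(
            f'<line x1="{sx(s.tstart):.2f}" y1="{y1:.2f}" '
            f'x2="{sx(s.tend):.2f}" y2="{y2:.2f}" '
            f'stroke="{color}" stroke-width="1.5"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
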