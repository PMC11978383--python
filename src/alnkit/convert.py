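"""Pairwise format conversions: MAF <-> PAF <-> Chain <-> MAF.

All six conversions are single passes through the canonical
:class:`~alnkit.core.PairwiseBlock`; no intermediate text is produced.
The only lossy edge is Chain: it cannot represent mismatch positions, so
``=``/``X`` coarsen to ``M`` on the way in and are recovered from FASTA
bases on the way out (``chain2maf``).  Chains must also start and end
with an ungapped block, so a CIGAR beginning or ending with ``I``/``D``
has those boundary indels trimmed into the coordinates, with a warning.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional

from pyfaidx import Fasta

from alnkit.core import (
    Cigar,
    FormatError,
    GenomeInterval,
    PairwiseBlock,
    Strand,
    coarsen_to_m,
)
from alnkit.io.chain import ChainRecord
from alnkit.io.fasta import fasta_fetch
from alnkit.io.maf import MafBlock, maf_block_to_pairwise, pairwise_to_maf_block
from alnkit.io.paf import PafRecord

log = logging.getLogger(__name__)

DEFAULT_MAPQ = 60


# ---------------------------------------------------------------------------
# record <-> canonical block


def block_to_paf(block: PairwiseBlock, mapq: int = DEFAULT_MAPQ) -> PafRecord:
    """Render a canonical block as a PAF record with a ``cg:Z:`` tag.

    ``nmatch`` counts ``=`` columns when the CIGAR distinguishes matches;
    for an opaque ``M`` CIGAR (chain provenance) it counts all ``M``
    columns, the convention chain-derived PAF uses.
    """
    cig = block.effective_cigar()
    if cig.has_m():
        nmatch = sum(op.length for op in cig.ops if op.kind in "=M")
    else:
        nmatch = sum(op.length for op in cig.ops if op.kind == "=")
    return PafRecord(
        qname=block.query_name,
        qlen=block.query_size,
        qstart=block.query_start,
        qend=block.query_end,
        strand=block.query_strand,
        tname=block.target_name,
        tlen=block.target_size,
        tstart=block.target_start,
        tend=block.target_end,
        nmatch=nmatch,
        block_len=cig.columns,
        mapq=mapq,
        tags={"cg": ("Z", cig.render())},
    )


def paf_to_block(rec: PafRecord) -> PairwiseBlock:
    cig = rec.cigar
    if cig is None:
        raise FormatError(f"PAF record {rec.qname}: CIGAR required (cg tag missing)")
    return PairwiseBlock(
        target_name=rec.tname,
        target_size=rec.tlen,
        target_start=rec.tstart,
        target_end=rec.tend,
        query_name=rec.qname,
        query_size=rec.qlen,
        query_strand=rec.strand,
        query_start=rec.qstart,
        query_end=rec.qend,
        cigar=cig,
    )


def block_to_chain(block: PairwiseBlock, chain_id: int) -> ChainRecord:
    """Render a canonical block as a UCSC chain record.

    ``=``/``X`` runs coarsen to ungapped blocks; ``D`` contributes ``dt``
    and ``I`` contributes ``dq``; an adjacent ``I``+``D`` run becomes one
    triple with both gaps set.  Boundary indels are trimmed into the
    coordinates (chains require ungapped blocks at both ends).
    """
    ops = list(coarsen_to_m(block.effective_cigar()).ops)
    tstart, tend = block.target_start, block.target_end
    qrel_start, qrel_end = block.query_rel_start, block.query_rel_end
    trimmed = False
    while ops and ops[0].kind != "M":
        op = ops.pop(0)
        trimmed = True
        if op.kind == "D":
            tstart += op.length
        else:
            qrel_start += op.length
    while ops and ops[-1].kind != "M":
        op = ops.pop()
        trimmed = True
        if op.kind == "D":
            tend -= op.length
        else:
            qrel_end -= op.length
    if trimmed:
        log.warning(
            "chain %d: boundary indel trimmed into coordinates "
            "(chains require ungapped end blocks)", chain_id
        )
    if not ops:
        raise FormatError(
            f"chain {chain_id}: alignment has no match block after trimming"
        )
    triples: list[tuple[int, int, int]] = []
    size: Optional[int] = None
    dt = dq = 0
    for op in ops:
        if op.kind == "M":
            if size is not None:
                triples.append((size, dt, dq))
            size, dt, dq = op.length, 0, 0
        elif op.kind == "D":
            dt += op.length
        else:  # I
            dq += op.length
    triples.append((size, 0, 0))
    if block.score is not None:
        score = block.score
    else:
        # no score carried: use the match-column count (exact CIGARs count
        # '=' only, opaque ones count all M columns)
        exact = block.effective_cigar()
        score = sum(op.length for op in exact.ops if op.kind in ("=" , "M"))
    return ChainRecord(
        score=score,
        tname=block.target_name, tsize=block.target_size,
        tstrand=Strand("+"), tstart=tstart, tend=tend,
        qname=block.query_name, qsize=block.query_size,
        qstrand=block.query_strand, qstart=qrel_start, qend=qrel_end,
        chain_id=chain_id,
        blocks=triples,
    )


def chain_to_block(rec: ChainRecord) -> PairwiseBlock:
    """Lift a chain record into the canonical frame (CIGAR uses ``M``)."""
    ops: list[tuple[str, int]] = []
    for i, (size, dt, dq) in enumerate(rec.blocks):
        ops.append(("M", size))
        if dt:
            ops.append(("D", dt))
        if dq:
            ops.append(("I", dq))
    return PairwiseBlock(
        target_name=rec.tname,
        target_size=rec.tsize,
        target_start=rec.tstart,
        target_end=rec.tend,
        query_name=rec.qname,
        query_size=rec.qsize,
        query_strand=rec.qstrand,
        query_start=rec.qstart_forward,
        query_end=rec.qend_forward,
        cigar=Cigar.from_ops(ops),
        score=rec.score,
    )


def attach_bases(
    block: PairwiseBlock, target_fasta: Fasta, query_fasta: Fasta
) -> PairwiseBlock:
    """Reconstruct gapped aligned strings by walking the CIGAR over FASTA.

    ``M`` ops are re-split into ``=``/``X`` from the fetched bases.  A
    mismatch between fetched ungapped lengths and the CIGAR spans raises
    a corrupt-input :class:`FormatError`.
    """
    cig = block.effective_cigar()
    tseq = fasta_fetch(
        target_fasta,
        GenomeInterval(block.target_name, block.target_start, block.target_end),
    )
    qseq = fasta_fetch(
        query_fasta,
        GenomeInterval(block.query_name, block.query_start, block.query_end),
        block.query_strand,
    )
    if len(tseq) != cig.target_span or len(qseq) != cig.query_span:
        raise FormatError(
            f"corrupt input: fetched lengths ({len(tseq)}, {len(qseq)}) "
            f"disagree with CIGAR spans ({cig.target_span}, {cig.query_span})"
        )
    t_parts: list[str] = []
    q_parts: list[str] = []
    ti = qi = 0
    for op in cig.ops:
        n = op.length
        if op.kind in "=XM":
            t_parts.append(tseq[ti:ti + n]); ti += n
            q_parts.append(qseq[qi:qi + n]); qi += n
        elif op.kind == "D":
            t_parts.append(tseq[ti:ti + n]); ti += n
            q_parts.append("-" * n)
        else:  # I
            t_parts.append("-" * n)
            q_parts.append(qseq[qi:qi + n]); qi += n
    return block.with_aligned("".join(t_parts), "".join(q_parts))


# ---------------------------------------------------------------------------
# the six file-level conversions


def maf_to_paf(blocks: Iterable[MafBlock]) -> Iterator[PafRecord]:
    for mb in blocks:
        yield block_to_paf(maf_block_to_pairwise(mb))


def paf_to_maf(
    records: Iterable[PafRecord], target_fasta: Fasta, query_fasta: Fasta
) -> Iterator[MafBlock]:
    for rec in records:
        block = attach_bases(paf_to_block(rec), target_fasta, query_fasta)
        yield pairwise_to_maf_block(block)


def paf_to_chain(records: Iterable[PafRecord]) -> Iterator[ChainRecord]:
    for i, rec in enumerate(records, start=1):
        yield block_to_chain(paf_to_block(rec), chain_id=i)


def chain_to_paf(records: Iterable[ChainRecord]) -> Iterator[PafRecord]:
    """Chain to PAF; ``cg`` uses ``M`` (chain carries no base detail).

    ``nmatch`` is recovered from the chain score when it is a plausible
    match count (our chain writer stores exactly that), i.e. when
    ``0 < score <= aligned columns``; otherwise it falls back to the sum
    of block sizes.  This makes PAF -> Chain -> PAF preserve all twelve
    mandatory columns for chains this package wrote.
    """
    for rec in records:
        paf = block_to_paf(chain_to_block(rec))
        aligned = sum(b[0] for b in rec.blocks)
        if not (0 < rec.score <= aligned):
            paf = replace_nmatch(paf, aligned)
        else:
            paf = replace_nmatch(paf, rec.score)
        yield paf


def replace_nmatch(rec: PafRecord, nmatch: int) -> PafRecord:
    from dataclasses import replace

    return replace(rec, nmatch=nmatch)


def maf_to_chain(blocks: Iterable[MafBlock]) -> Iterator[ChainRecord]:
    for i, mb in enumerate(blocks, start=1):
        yield block_to_chain(maf_block_to_pairwise(mb), chain_id=i)


def chain_to_maf(
    records: Iterable[ChainRecord], target_fasta: Fasta, query_fasta: Fasta
) -> Iterator[MafBlock]:
    for rec in records:
        block = attach_bases(chain_to_block(rec), target_fasta, query_fasta)
        yield pairwise_to_maf_block(block)
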