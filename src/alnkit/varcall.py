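"""Variant identification from pairwise alignment signatures.

The caller walks alignment columns left to right.  A mismatch column
becomes a SNP at the consumed target base.  A maximal run of insertion
columns becomes an INS anchored at the last consumed target base
(REF = anchor base, ALT = anchor + inserted query bases); a maximal run
of deletion columns becomes a DEL anchored at the base before the run
(REF = anchor + deleted bases, ALT = anchor).  These are the standard
VCF representations of alignment-derived indels.  Indels at or above
``sv_min_len`` (50 bp by default, the community convention) are
additionally tagged as structural variants with SVTYPE/SVLEN/END.

Minus-strand query blocks are called in target coordinates; the aligned
query string in the canonical frame is already reverse-complemented, so
ALT bases read straight off it.  A leading indel with no left anchor
falls back to anchoring on the following target base (the VCF
convention for position-1 events), with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from pyfaidx import Fasta

from alnkit.core import FormatError, GenomeInterval, PairwiseBlock, bases_match
from alnkit.io.fasta import fasta_fetch

log = logging.getLogger(__name__)

SV_MIN_LEN_DEFAULT = 50


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based target position of REF[0]
    ref: str
    alt: str
    kind: str  # SNP | INS | DEL
    svlen: int  # +ins / -del / 0 for SNP
    end: int  # 1-based inclusive target end of REF
    query_name: str
    query_pos: int  # 1-based, query forward strand
    is_sv: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position {self.pos} < 1")
        if self.kind == "SNP":
            ok = len(self.ref) == len(self.alt) == 1 and self.ref != self.alt
        elif self.kind == "INS":
            # anchor base leads; for a position-1 event it trails (VCF fallback)
            ok = len(self.alt) > len(self.ref) == 1 and (
                self.alt[0] == self.ref or self.alt[-1] == self.ref
            )
        elif self.kind == "DEL":
            ok = len(self.ref) > len(self.alt) == 1 and (
                self.ref[0] == self.alt or self.ref[-1] == self.alt
            )
        else:
            ok = False
        if not ok:
            raise FormatError(
                f"invalid {self.kind} REF/ALT: {self.ref!r}>{self.alt!r}"
            )

    @property
    def sort_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CallConfig:
    sv_min_len: int = SV_MIN_LEN_DEFAULT
    emit: frozenset[str] = frozenset({"SNP", "INS", "DEL"})
    min_block_columns: int = 0
    sample: str = "query"

    def __post_init__(self) -> None:
        if self.sv_min_len < 1:
            raise FormatError("sv_min_len must be >= 1")


def _query_forward_pos(block: PairwiseBlock, q_consumed: int) -> int:
    """1-based forward-strand query position of the base at strand-relative
    offset *q_consumed* within the block."""
    rel = block.query_rel_start + q_consumed
    if block.query_strand.is_forward:
        return rel + 1
    return block.query_size - rel  # = (qsize - 1 - rel) + 1


def _next_target_base(t_aln: str, j: int) -> str:
    for ch in t_aln[j:]:
        if ch != "-":
            return ch.upper()
    raise FormatError("indel run has no following target base to anchor on")


def call_block(
    block: PairwiseBlock,
    target_fasta: Optional[Fasta] = None,
    config: CallConfig = CallConfig(),
) -> list[Variant]:
    """Call variants from one block (in column order, unsorted).

    Blocks carrying only a CIGAR are given aligned strings via the
    target/query FASTAs upstream (``convert.attach_bases``); here we
    require the strings, or an exact CIGAR plus a target FASTA is of no
    help because the query bases are still unknown.
    """
    if block.target_aln is None:
        raise FormatError(
            "variant calling needs aligned base strings; reconstruct them "
            "from FASTA first (convert.attach_bases)"
        )
    t_aln, q_aln = block.target_aln, block.query_aln
    variants: list[Variant] = []
    tpos = block.target_start  # next target base (0-based forward)
    q_consumed = 0
    last_t_base: Optional[str] = None  # last consumed target base
    i = 0
    n = len(t_aln)
    while i < n:
        t, q = t_aln[i], q_aln[i]
        if t != "-" and q != "-":
            if not bases_match(t, q) and t.upper() != "N" and q.upper() != "N":
                variants.append(
                    Variant(
                        chrom=block.target_name,
                        pos=tpos + 1,
                        ref=t.upper(),
                        alt=q.upper(),
                        kind="SNP",
                        svlen=0,
                        end=tpos + 1,
                        query_name=block.query_name,
                        query_pos=_query_forward_pos(block, q_consumed),
                    )
                )
            last_t_base = t.upper()
            tpos += 1
            q_consumed += 1
            i += 1
            continue
        # maximal indel run
        j = i
        if t == "-":  # insertion (query-only columns)
            while j < n and t_aln[j] == "-":
                j += 1
            inserted = q_aln[i:j].upper()
            run = j - i
            if last_t_base is not None:
                anchor0 = tpos - 1
                ref, alt = last_t_base, last_t_base + inserted
            else:
                log.warning(
                    "leading insertion at %s:%d anchored on following base",
                    block.target_name, tpos + 1,
                )
                anchor0 = tpos
                follow = _next_target_base(t_aln, j)
                ref, alt = follow, inserted + follow
            variants.append(
                Variant(
                    chrom=block.target_name,
                    pos=anchor0 + 1,
                    ref=ref,
                    alt=alt,
                    kind="INS",
                    svlen=run,
                    end=anchor0 + 1,
                    query_name=block.query_name,
                    query_pos=_query_forward_pos(block, q_consumed),
                    is_sv=run >= config.sv_min_len,
                )
            )
            q_consumed += run
        else:  # deletion (target-only columns)
            while j < n and q_aln[j] == "-":
                j += 1
            deleted = t_aln[i:j].upper()
            run = j - i
            if last_t_base is not None:
                pos0 = tpos - 1
                ref, alt = last_t_base + deleted, last_t_base
            else:
                log.warning(
                    "leading deletion at %s:%d anchored on following base",
                    block.target_name, tpos + 1,
                )
                pos0 = tpos
                follow = _next_target_base(t_aln, j)
                ref, alt = deleted + follow, follow
            variants.append(
                Variant(
                    chrom=block.target_name,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    kind="DEL",
                    svlen=-run,
                    end=pos0 + len(ref),
                    query_name=block.query_name,
                    query_pos=_query_forward_pos(block, max(q_consumed - 1, 0)),
                    is_sv=run >= config.sv_min_len,
                )
            )
            last_t_base = deleted[-1]
            tpos += run
        i = j
    return variants


def call_variants(
    blocks: Iterable[PairwiseBlock],
    target_fasta: Optional[Fasta] = None,
    config: CallConfig = CallConfig(),
) -> list[Variant]:
    """Call variants across blocks, filtered per *config*, sorted by
    (chrom, pos, ref, alt)."""
    out: list[Variant] = []
    for block in blocks:
        if block.columns < config.min_block_columns:
            continue
        out.extend(call_block(block, target_fasta, config))
    kinds = config.emit
    out = [v for v in out if v.kind in kinds or (v.is_sv and "SV" in kinds)]
    out.sort(key=lambda v: v.sort_key)
    return out


# ---------------------------------------------------------------------------
# left-normalization


def normalize_variant(v: Variant, target_fasta: Fasta) -> Variant:
    """Left-align an indel to its leftmost equivalent position.

    Standard VCF normalisation: while the base preceding POS equals the
    last base of the varied sequence, rotate the event one base left.
    SNPs and position-1 fallback representations are returned unchanged;
    the operation is idempotent.
    """
    if v.kind == "SNP":
        return v
    if v.kind == "INS" and v.alt[0] != v.ref:
        return v  # position-1 fallback form, nothing to the left
    if v.kind == "DEL" and v.ref[0] != v.alt:
        return v
    seq = v.alt[1:] if v.kind == "INS" else v.ref[1:]
    pos0 = v.pos - 1  # 0-based anchor position
    # rotate the event left while the anchor base equals the last varied
    # base (the invariant bcftools norm / vt normalize use)
    while pos0 > 0:
        anchor_base = fasta_fetch(
            target_fasta, GenomeInterval(v.chrom, pos0, pos0 + 1)
        ).upper()
        if anchor_base != seq[-1]:
            break
        seq = anchor_base + seq[:-1]
        pos0 -= 1
    if pos0 == v.pos - 1:
        return v
    anchor = fasta_fetch(
        target_fasta, GenomeInterval(v.chrom, pos0, pos0 + 1)
    ).upper()
    if v.kind == "INS":
        ref, alt = anchor, anchor + seq
        end = pos0 + 1
    else:
        ref, alt = anchor + seq, anchor
        end = pos0 + len(ref)
    return replace(v, pos=pos0 + 1, ref=ref, alt=alt, end=end)


def normalize_variants(
    variants: Iterable[Variant], target_fasta: Fasta
) -> list[Variant]:
    out = [normalize_variant(v, target_fasta) for v in variants]
    out.sort(key=lambda v: v.sort_key)
    return out
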