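"""Minimal VCF 4.2 writer for alignment-derived variant calls.

Calls are haploid assembly-vs-assembly comparisons, so the single sample
is written as ``GT`` ``1/1``.  The emitter is deliberately a small text
writer: the header is fixed, records are pre-sorted, and byte-for-byte
deterministic output matters for round-trip tests.
"""

from __future__ import annotations

from typing import IO, Iterable, Mapping

from alnkit.core import FormatError

_HEADER_LINES = [
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant class: SNP, INS or DEL">',
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length difference of ALT vs REF">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end position on the target">',
    '##INFO=<ID=QNAME,Number=1,Type=String,Description="Query sequence name">',
    '##INFO=<ID=QPOS,Number=1,Type=Integer,Description="1-based query position (forward strand)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(
    variants: Iterable,
    contig_lengths: Mapping[str, int],
    sample: str,
    stream: IO[str],
) -> None:
    """Write *variants* (sorted by chrom, pos) as a VCF 4.2 stream.

    Each variant must expose ``chrom, pos, ref, alt, kind, svlen, end,
    query_name, query_pos`` and ``is_sv`` (see ``alnkit.varcall.Variant``).
    Unsorted input raises :class:`FormatError`.
    """
    stream.write("##fileformat=VCFv4.2\n")
    stream.write("##source=alnkit\n")
    for name, length in contig_lengths.items():
        stream.write(f"##contig=<ID={name},length={length}>\n")
    for line in _HEADER_LINES:
        stream.write(line + "\n")
    stream.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{sample}\n"
    )
    prev = None
    for v in variants:
        key = (v.chrom, v.pos)
        if prev is not None and key < prev:
            raise FormatError(
                f"variants not sorted: {key} after {prev}"
            )
        prev = key
        info = [f"TYPE={v.kind}"]
        if v.is_sv:
            info.append(f"SVTYPE={v.kind}")
            info.append(f"SVLEN={v.svlen}")
            info.append(f"END={v.end}")
        info.append(f"QNAME={v.query_name}")
        info.append(f"QPOS={v.query_pos}")
        stream.write(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"{';'.join(info)}\tGT\t1/1\n"
        )
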