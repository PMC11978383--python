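"""PAF (minimap2 dialect) reader/writer.

Twelve mandatory tab-separated columns, then typed ``TAG:TYPE:VALUE``
optional fields.  Query coordinates are always on the forward strand;
the ``cg:Z:`` tag carries a CIGAR over ``=,X,I,D,M``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterator, Optional

from alnkit.core import Cigar, FormatError, Strand, cigar_parse

_TAG_PARSERS = {"i": int, "f": float, "A": str, "Z": str, "H": str, "B": str}


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: Strand
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    block_len: int
    mapq: int
    tags: dict[str, tuple[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise FormatError(
                f"PAF {self.qname}: query interval [{self.qstart},{self.qend}) "
                f"invalid for length {self.qlen}"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise FormatError(
                f"PAF {self.qname}: target interval [{self.tstart},{self.tend}) "
                f"invalid for length {self.tlen}"
            )
        if self.nmatch > self.block_len:
            raise FormatError(
                f"PAF {self.qname}: nmatch {self.nmatch} > block_len {self.block_len}"
            )
        cig = self.cigar
        if cig is not None:
            if cig.target_span != self.tend - self.tstart:
                raise FormatError(
                    f"PAF {self.qname}: cg target span {cig.target_span} != "
                    f"{self.tend - self.tstart}"
                )
            if cig.query_span != self.qend - self.qstart:
                raise FormatError(
                    f"PAF {self.qname}: cg query span {cig.query_span} != "
                    f"{self.qend - self.qstart}"
                )

    @property
    def cigar(self) -> Optional[Cigar]:
        entry = self.tags.get("cg")
        if entry is None:
            return None
        return cigar_parse(str(entry[1]))


def _parse_tag(token: str) -> tuple[str, str, object]:
    parts = token.split(":", 2)
    if len(parts) != 3 or len(parts[0]) != 2 or parts[1] not in _TAG_PARSERS:
        raise FormatError(f"malformed PAF tag {token!r}")
    tag, typ, raw = parts
    try:
        value = _TAG_PARSERS[typ](raw)
    except ValueError as exc:
        raise FormatError(f"malformed PAF tag value {token!r}") from exc
    return tag, typ, value


def parse_paf_line(line: str) -> PafRecord:
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) < 12:
        raise FormatError(f"PAF line has {len(fields)} columns, expected >= 12")
    try:
        rec = PafRecord(
            qname=fields[0],
            qlen=int(fields[1]),
            qstart=int(fields[2]),
            qend=int(fields[3]),
            strand=Strand(fields[4]),
            tname=fields[5],
            tlen=int(fields[6]),
            tstart=int(fields[7]),
            tend=int(fields[8]),
            nmatch=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
            tags={},
        )
    except ValueError as exc:
        raise FormatError(f"non-integer PAF coordinate in: {line[:60]!r}") from exc
    for token in fields[12:]:
        tag, typ, value = _parse_tag(token)
        rec.tags[tag] = (typ, value)
    rec.__post_init__()  # re-validate now that cg is attached
    return rec


def read_paf(stream: IO[str]) -> Iterator[PafRecord]:
    for line in stream:
        if not line.strip() or line.startswith("#"):
            continue
        yield parse_paf_line(line)


def format_paf_record(rec: PafRecord) -> str:
    cols = [
        rec.qname, rec.qlen, rec.qstart, rec.qend, rec.strand,
        rec.tname, rec.tlen, rec.tstart, rec.tend,
        rec.nmatch, rec.block_len, rec.mapq,
    ]
    tags = [f"{tag}:{typ}:{value}" for tag, (typ, value) in rec.tags.items()]
    return "\t".join(str(c) for c in cols + tags) + "\n"


def write_paf(records, stream: IO[str]) -> None:
    for rec in records:
        stream.write(format_paf_record(rec))
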