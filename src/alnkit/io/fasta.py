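"""Indexed FASTA access (pyfaidx-backed, .fai sidecar)."""

from __future__ import annotations

from pyfaidx import Fasta

from alnkit.core import AlnError, GenomeInterval, Strand, revcomp


def open_fasta(path: str) -> Fasta:
    """Open an indexed FASTA; the .fai sidecar is built on first use."""
    return Fasta(path, sequence_always_upper=False, as_raw=True)


def fasta_fetch(fasta: Fasta, interval: GenomeInterval, strand: Strand = Strand("+")) -> str:
    """Fetch a forward-strand substring, reverse-complemented for '-'.

    Raises :class:`AlnError` for a missing sequence or an out-of-bounds
    interval.
    """
    if interval.name not in fasta:
        raise AlnError(f"sequence {interval.name!r} not in FASTA")
    seq_len = len(fasta[interval.name])
    if interval.end > seq_len:
        raise AlnError(
            f"interval [{interval.start},{interval.end}) exceeds length "
            f"{seq_len} of {interval.name!r}"
        )
    seq = str(fasta[interval.name][interval.start:interval.end])
    return seq if strand.is_forward else revcomp(seq)
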