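"""Shared stream helpers: gzip/BGZF auto-detection and '-' for stdio."""

from __future__ import annotations

import gzip
import io
import sys
from contextlib import contextmanager
from typing import IO, Iterator

GZIP_MAGIC = b"\x1f\x8b"  # plain gzip and BGZF share the magic


def _is_gzipped(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


@contextmanager
def open_binary_read(path: str) -> Iterator[IO[bytes]]:
    """Open *path* for binary reading, transparently decompressing gzip/BGZF.

    ``-`` reads stdin (no seek, no decompression detection on pipes beyond
    the magic in the buffered stream).
    """
    if path == "-":
        data = sys.stdin.buffer.read()
        if data[:2] == GZIP_MAGIC:
            data = gzip.decompress(data)
        yield io.BytesIO(data)
        return
    if _is_gzipped(path):
        with gzip.open(path, "rb") as fh:
            yield fh
    else:
        with open(path, "rb") as fh:
            yield fh


@contextmanager
def open_text(path: str, mode: str = "r") -> Iterator[IO[str]]:
    """Open text for reading (gzip auto-detected) or writing ('-' = stdio)."""
    if "r" in mode:
        with open_binary_read(path) as fh:
            yield io.TextIOWrapper(fh, encoding="ascii")
        return
    if path == "-":
        yield sys.stdout
        return
    with open(path, mode, encoding="ascii") as fh:
        yield fh
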