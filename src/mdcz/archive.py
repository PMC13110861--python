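"""Random-access container: named streams of parts, one u64 aux value per part.

The archive is a flat file of appended part payloads followed by a directory
and a fixed-size footer, so any part can be fetched with one directory lookup
plus one contiguous read.  New stream names may be appended at any time before
finalization; the file contains no timestamps or machine identifiers, so its
bytes are a deterministic function of the append sequence.

On-disk layout (little-endian, documented bit-exactly in docs/format.md):

* header: ``b"MDC1"`` + format version (u32)
* part payloads, back to back, in append order
* directory: u32 stream count; per stream: u16 name length, UTF-8 name,
  u32 part count, then per part (offset u64, length u64, aux u64, crc32 u32)
* footer: directory offset (u64), format version (u32), magic ``b"MDC1"``
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import Dict, List, Tuple

__all__ = ["ArchiveWriter", "ArchiveReader", "ArchiveError", "ArchiveFormatError"]

MAGIC = b"MDC1"
VERSION = 1

_HEADER = struct.Struct("<4sI")
_FOOTER = struct.Struct("<QI4s")
_PART = struct.Struct("<QQQI")


class ArchiveError(RuntimeError):
    """Archive misuse (e.g. appending after finalize)."""


class ArchiveFormatError(ValueError):
    """Corrupt or truncated archive file."""


@dataclass
class _Part:
    offset: int
    length: int
    aux: int
    crc: int


class ArchiveWriter:
    """Append-only archive writer; call :meth:`finalize` exactly once."""

    def __init__(self, path):
        self.path = str(path)
        try:
            self._fh = open(self.path, "wb")
        except OSError as exc:
            raise ArchiveError(f"cannot create archive at {self.path}: {exc}") from exc
        self._fh.write(_HEADER.pack(MAGIC, VERSION))
        self._streams: Dict[str, List[_Part]] = {}
        self._order: List[str] = []
        self._finalized = False

    def append_part(self, stream: str, payload: bytes, aux: int = 0) -> int:
        """Append one part to ``stream``; returns the part index within it."""
        if self._finalized:
            raise ArchiveError("append_part called after finalize")
        if stream not in self._streams:
            self._streams[stream] = []
            self._order.append(stream)
        offset = self._fh.tell()
        self._fh.write(payload)
        parts = self._streams[stream]
        parts.append(_Part(offset, len(payload), int(aux), zlib.crc32(payload)))
        return len(parts) - 1

    def finalize(self) -> None:
        if self._finalized:
            raise ArchiveError("finalize called twice")
        dir_offset = self._fh.tell()
        out = [struct.pack("<I", len(self._order))]
        for name in self._order:
            enc = name.encode("utf-8")
            out.append(struct.pack("<H", len(enc)))
            out.append(enc)
            parts = self._streams[name]
            out.append(struct.pack("<I", len(parts)))
            for p in parts:
                out.append(_PART.pack(p.offset, p.length, p.aux, p.crc))
        self._fh.write(b"".join(out))
        self._fh.write(_FOOTER.pack(dir_offset, VERSION, MAGIC))
        self._fh.close()
        self._finalized = True

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None and not self._finalized:
            self.finalize()
        elif not self._finalized:
            self._fh.close()
        return False


class ArchiveReader:
    """Random-access reader; counts per-stream part reads for instrumentation."""

    def __init__(self, path):
        self.path = str(path)
        self._fh = open(self.path, "rb")
        self._fh.seek(0, 2)
        size = self._fh.tell()
        if size < _HEADER.size + _FOOTER.size:
            raise ArchiveFormatError(f"{self.path}: too short to be an archive")
        self._fh.seek(0)
        magic, version = _HEADER.unpack(self._fh.read(_HEADER.size))
        if magic != MAGIC:
            raise ArchiveFormatError(f"{self.path}: bad header magic")
        self._fh.seek(size - _FOOTER.size)
        dir_offset, fversion, fmagic = _FOOTER.unpack(self._fh.read(_FOOTER.size))
        if fmagic != MAGIC or fversion != VERSION or version != VERSION:
            raise ArchiveFormatError(f"{self.path}: bad footer or version")
        if not _HEADER.size <= dir_offset <= size - _FOOTER.size:
            raise ArchiveFormatError(f"{self.path}: directory offset out of range")
        self._fh.seek(dir_offset)
        blob = self._fh.read(size - _FOOTER.size - dir_offset)
        self._streams: Dict[str, List[_Part]] = {}
        self._order: List[str] = []
        try:
            (nstreams,) = struct.unpack_from("<I", blob, 0)
            off = 4
            for _ in range(nstreams):
                (nlen,) = struct.unpack_from("<H", blob, off)
                off += 2
                name = blob[off : off + nlen].decode("utf-8")
                off += nlen
                (nparts,) = struct.unpack_from("<I", blob, off)
                off += 4
                parts = []
                for _ in range(nparts):
                    o, ln, aux, crc = _PART.unpack_from(blob, off)
                    off += _PART.size
                    parts.append(_Part(o, ln, aux, crc))
                self._streams[name] = parts
                self._order.append(name)
        except (struct.error, UnicodeDecodeError) as exc:
            raise ArchiveFormatError(f"{self.path}: corrupt directory") from exc
        #: stream name -> number of read_part calls (instrumentation hook)
        self.read_counts: Dict[str, int] = {}

    def list_streams(self) -> List[str]:
        return list(self._order)

    def n_parts(self, stream: str) -> int:
        return len(self._parts(stream))

    def _parts(self, stream: str) -> List[_Part]:
        try:
            return self._streams[stream]
        except KeyError:
            raise KeyError(f"archive has no stream {stream!r}") from None

    def part_aux(self, stream: str, idx: int) -> int:
        return self._part(stream, idx).aux

    def part_sizes(self, stream: str) -> List[int]:
        return [p.length for p in self._parts(stream)]

    def _part(self, stream: str, idx: int) -> _Part:
        parts = self._parts(stream)
        if not 0 <= idx < len(parts):
            raise IndexError(f"stream {stream!r} has no part {idx}")
        return parts[idx]

    def read_part(self, stream: str, idx: int) -> Tuple[bytes, int]:
        """One directory lookup + one contiguous read; verifies the part CRC."""
        p = self._part(stream, idx)
        self._fh.seek(p.offset)
        payload = self._fh.read(p.length)
        if len(payload) != p.length:
            raise ArchiveFormatError(
                f"{self.path}: truncated part {stream!r}[{idx}]"
            )
        if zlib.crc32(payload) != p.crc:
            raise ArchiveFormatError(
                f"{self.path}: checksum mismatch in part {stream!r}[{idx}]"
            )
        self.read_counts[stream] = self.read_counts.get(stream, 0) + 1
        return payload, p.aux

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        self.close()
        return False
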