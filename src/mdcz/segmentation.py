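"""Partition the atom list into MOL / WAT / OTH segments and subsegments.

Segments tile the atom list in file order:

* ``MOL`` — every molecule with at least six atoms gets its own segment;
* ``WAT`` — a maximal run of consecutive 3-point water molecules (residue name
  in the water whitelist, atoms strictly ordered O, H, H) forms one segment;
* ``OTH`` — a maximal run of consecutive non-water molecules with fewer than
  six atoms (ions included) forms one segment.

Segments are further split into fixed-size *subsegments*, the independent
coding units of the format: no prediction reference ever crosses a subsegment
boundary, which is what makes per-atom random access possible.  Water
subsegment sizes are rounded down to whole molecules so no water straddles a
boundary.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field

__all__ = [
    "MOL",
    "WAT",
    "OTH",
    "OFF",
    "WATER_RESNAMES",
    "Segment",
    "classify_segments",
    "split_subsegments",
    "describe_segments",
    "parse_segments",
    "SegmentFormatError",
]

MOL = "MOL"
WAT = "WAT"
OTH = "OTH"

#: Sentinel disabling subsegment splitting (one subsegment per segment).
OFF = None

WATER_RESNAMES = frozenset({"SOL", "WAT", "HOH", "TIP3", "H2O"})

_KIND_CODE = {MOL: 0, WAT: 1, OTH: 2}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}

MIN_SUBSEG = 6  # the MOL predictor needs three predecessors plus headroom


class SegmentFormatError(ValueError):
    """Raised when a serialized segment description cannot be parsed."""


@dataclass
class Segment:
    kind: str
    atom_start: int
    atom_count: int
    subsegments: list = field(default_factory=list)  # [(start, count)] absolute

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODE:
            raise ValueError(f"unknown segment kind {self.kind!r}")


def _molecules(topo):
    """Yield (first_atom_index, n_atoms, is_water) per molecule, in order."""
    out = []
    start = 0
    n = topo.n_atoms
    for i in range(1, n + 1):
        if i == n or topo.atoms[i].molecule != topo.atoms[start].molecule:
            out.append((start, i - start))
            start = i
    return out


def _is_water(topo, start, count) -> bool:
    if count != 3:
        return False
    atoms = topo.atoms[start : start + 3]
    if any(a.resname.upper() not in WATER_RESNAMES for a in atoms):
        return False
    elements = [a.element.upper() for a in atoms]
    return elements[0] == "O" and elements[1] == "H" and elements[2] == "H"


def classify_segments(topo) -> list:
    """Classify a topology's molecules into an ordered MOL/WAT/OTH tiling."""
    segments: list[Segment] = []

    def flush(kind, start, count):
        if count > 0:
            segments.append(Segment(kind, start, count))

    run_kind = None
    run_start = 0
    run_count = 0
    for start, count in _molecules(topo):
        if count >= 6:
            flush(run_kind, run_start, run_count)
            run_kind, run_count = None, 0
            segments.append(Segment(MOL, start, count))
            continue
        kind = WAT if _is_water(topo, start, count) else OTH
        if kind == run_kind:
            run_count += count
        else:
            flush(run_kind, run_start, run_count)
            run_kind, run_start, run_count = kind, start, count
    flush(run_kind, run_start, run_count)
    return segments


def split_subsegments(seg: Segment, subseg_size=OFF) -> Segment:
    """Fill ``seg.subsegments`` with contiguous coding units.

    MOL/OTH subsegments hold exactly ``subseg_size`` atoms except the last;
    WAT subsegments hold ``3 * (subseg_size // 3)`` atoms so molecules never
    straddle.  ``subseg_size=OFF`` yields a single subsegment.
    """
    if subseg_size is OFF:
        seg.subsegments = [(seg.atom_start, seg.atom_count)]
        return seg
    if subseg_size < MIN_SUBSEG:
        raise ValueError(f"subsegment size must be >= {MIN_SUBSEG} or OFF")
    step = 3 * (subseg_size // 3) if seg.kind == WAT else subseg_size
    subs = []
    pos = seg.atom_start
    end = seg.atom_start + seg.atom_count
    while pos < end:
        n = min(step, end - pos)
        subs.append((pos, n))
        pos += n
    seg.subsegments = subs
    return seg


_HEADER = struct.Struct("<4sI")
_SEG = struct.Struct("<BQQI")
_SUB = struct.Struct("<QQ")
_MAGIC = b"SEGD"


def describe_segments(segments) -> bytes:
    """Self-delimiting binary encoding of a segment list (CRC-protected)."""
    parts = [_HEADER.pack(_MAGIC, len(segments))]
    for seg in segments:
        parts.append(
            _SEG.pack(
                _KIND_CODE[seg.kind], seg.atom_start, seg.atom_count,
                len(seg.subsegments),
            )
        )
        for start, count in seg.subsegments:
            parts.append(_SUB.pack(start, count))
    body = b"".join(parts)
    return body + struct.pack("<I", zlib.crc32(body))


def parse_segments(data: bytes) -> list:
    """Inverse of :func:`describe_segments`."""
    if len(data) < _HEADER.size + 4:
        raise SegmentFormatError("segment description truncated")
    body, crc = data[:-4], struct.unpack("<I", data[-4:])[0]
    if zlib.crc32(body) != crc:
        raise SegmentFormatError("segment description checksum mismatch")
    magic, nseg = _HEADER.unpack_from(body, 0)
    if magic != _MAGIC:
        raise SegmentFormatError("bad segment description magic")
    off = _HEADER.size
    segments = []
    try:
        for _ in range(nseg):
            code, start, count, nsub = _SEG.unpack_from(body, off)
            off += _SEG.size
            subs = []
            for _ in range(nsub):
                s, c = _SUB.unpack_from(body, off)
                off += _SUB.size
                subs.append((s, c))
            segments.append(Segment(_CODE_KIND[code], start, count, subs))
    except struct.error as exc:
        raise SegmentFormatError("segment description truncated") from exc
    if off != len(body):
        raise SegmentFormatError("trailing bytes in segment description")
    return segments
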