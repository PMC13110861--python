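"""Compression pipeline: batches x subsegments, presets, queries, summaries.

A trajectory is processed in *batches* of consecutive frames; each batch
starts with an anchor frame followed by delta frames.  Every (batch,
subsegment) pair is an independently coded block stored as one archive part,
which is what gives the format its two random-access axes: frame subsets
decode only the batches they touch, per-atom trajectories decode only the
subsegments containing the requested atoms.

Work units may be encoded by several workers, but outputs are always gathered
in canonical (batch, segment, subsegment) order before writing, so archive
bytes are independent of the worker count.
"""

from __future__ import annotations

import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import _kernels
from .archive import ArchiveFormatError, ArchiveReader, ArchiveWriter
from .model_builder import (
    ModelParams,
    WatModel,
    build_mol_model,
    build_wat_model,
    parse_model,
    serialize_model,
)
from .residual_codec import FormatError, QuantSpec, dequantize, quantize
from .segmentation import (
    MOL,
    OFF,
    OTH,
    WAT,
    classify_segments,
    describe_segments,
    parse_segments,
    split_subsegments,
)
from .trajectory_io import (
    Atom,
    RawFrame,
    TopologyLite,
    read_structure,
    read_trajectory,
    write_trajectory,
)

__all__ = [
    "CompressionParams",
    "PRESETS",
    "resolve_preset",
    "compress",
    "compress_frames",
    "decompress_all",
    "query_frames",
    "query_atoms",
    "info",
    "TRR_BASELINE_BITS",
]

#: Uncompressed TRR stores 3 x 32-bit floats per atom per frame.
TRR_BASELINE_BITS = 96

_KIND_CODE = {MOL: 0, WAT: 1, OTH: 2}


@dataclass(frozen=True)
class CompressionParams:
    level: int = 2
    batch_size: int = 20
    subsegment_size: Optional[int] = 100  # None = OFF
    model_frames: int = 100
    precision_pm: int = 1
    workers: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 5:
            raise ValueError("level must be in 1..5")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.model_frames < 1:
            raise ValueError("model_frames must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        QuantSpec(self.precision_pm)  # validates the precision set


#: name -> (batch_size, subsegment_size)
PRESETS = {
    "default": (20, 100),
    "archive": (100, 1000),
    "trajectory": (100, 100),
    "frames": (10, 1000),
}


def resolve_preset(name: str, **overrides) -> CompressionParams:
    """Preset lookup; explicit keyword flags override preset values."""
    try:
        batch, subseg = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        ) from None
    base = {"batch_size": batch, "subsegment_size": subseg}
    base.update({k: v for k, v in overrides.items() if v is not None})
    return CompressionParams(**base)


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------


def _kernel_model(kind: str, n: int, model):
    """Model in the flat array form the block kernels consume."""
    refs = np.full((n, 3), -1, dtype=np.int64)
    rdist = np.zeros((n, 3), dtype=np.int64)
    plane = np.zeros(n, dtype=np.uint8)
    doh = dhh = 0
    if kind == MOL and model:
        for idx, e in enumerate(model):
            i = idx + 3
            refs[i] = (e.p, e.q, e.r)
            rdist[i] = (e.d_p, e.d_q, e.d_r)
            plane[i] = 1 if e.plane_side == "above" else 0
    elif kind == WAT:
        doh, dhh = model.dOH, model.dHH
    return refs, rdist, plane, doh, dhh


def _encode_block(kind, block, level, kmodel):
    refs, rdist, plane, doh, dhh = kmodel
    buf = np.empty(block.size * 48 + 4096, dtype=np.uint8)
    if kind == MOL:
        nb = _kernels.encode_block_mol(block, level, refs, rdist, plane, buf)
    elif kind == WAT:
        nb = _kernels.encode_block_wat(block, level, doh, dhh, buf)
    else:
        nb = _kernels.encode_block_oth(block, buf)
    return bytes(buf[:nb])


def _decode_block(kind, data, T, n, level, kmodel):
    refs, rdist, plane, doh, dhh = kmodel
    arr = np.frombuffer(data, dtype=np.uint8)
    out = np.empty((T, n, 3), dtype=np.int64)
    if kind == MOL:
        overrun = _kernels.decode_block_mol(arr, T, n, level, refs, rdist, plane, out)
    elif kind == WAT:
        overrun = _kernels.decode_block_wat(arr, T, n, level, doh, dhh, out)
    else:
        overrun = _kernels.decode_block_oth(arr, T, n, out)
    if overrun:
        raise FormatError("coordinate block truncated (decoder overrun)")
    return out


def _anchors(n_frames: int, batch_size: int) -> List[int]:
    return list(range(0, n_frames, batch_size))


def _serialize_topology(topo: TopologyLite) -> bytes:
    return json.dumps(
        [[a.element, a.name, a.resname, a.resid, a.molecule] for a in topo.atoms],
        separators=(",", ":"),
    ).encode()


def _parse_topology(data: bytes) -> TopologyLite:
    return TopologyLite([Atom(*rec) for rec in json.loads(data.decode())])


def _serialize_meta(frames: Sequence[RawFrame]) -> bytes:
    times = np.array([f.time for f in frames], dtype="<f8")
    steps = np.array([f.step for f in frames], dtype="<i8")
    boxes = np.stack([f.box for f in frames]).astype("<f8")
    return times.tobytes() + steps.tobytes() + boxes.tobytes()


def _parse_meta(data: bytes, T: int):
    times = np.frombuffer(data, "<f8", T, 0)
    steps = np.frombuffer(data, "<i8", T, 8 * T)
    boxes = np.frombuffer(data, "<f8", 9 * T, 16 * T).reshape(T, 3, 3)
    return times, steps, boxes


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------


def compress_frames(
    topo: TopologyLite,
    frames: Sequence[RawFrame],
    out_path,
    params: CompressionParams = CompressionParams(),
    store_topology: bool = True,
) -> Dict:
    """Compress in-memory frames; returns a summary with bits/atom by kind."""
    frames = list(frames)
    if not frames:
        raise ValueError("empty trajectory")
    if frames[0].n_atoms != topo.n_atoms:
        raise ValueError(
            f"trajectory has {frames[0].n_atoms} atoms, structure has {topo.n_atoms}"
        )
    T, N = len(frames), topo.n_atoms
    spec = QuantSpec(params.precision_pm)
    qcoords = np.empty((T, N, 3), dtype=np.int64)
    for t, f in enumerate(frames):
        qcoords[t] = quantize(f.coords, spec)

    segments = [
        split_subsegments(seg, params.subsegment_size)
        for seg in classify_segments(topo)
    ]
    mf = min(params.model_frames, T)
    mp = ModelParams(m=mf)
    models = []  # [(seg_idx, ss_idx, kind, (start, count), model, kmodel)]
    for si, seg in enumerate(segments):
        for ssi, (start, count) in enumerate(seg.subsegments):
            if seg.kind == MOL:
                model = build_mol_model(qcoords[:mf], (start, count), mp)
            elif seg.kind == WAT:
                model = build_wat_model(qcoords[:mf], (start, count))
            else:
                model = None
            models.append(
                (si, ssi, seg.kind, (start, count),
                 model, _kernel_model(seg.kind, count, model))
            )

    anchors = _anchors(T, params.batch_size)
    jobs = []  # canonical (batch, segment, subsegment) order
    for a in anchors:
        bt = min(params.batch_size, T - a)
        for si, ssi, kind, (start, count), _, kmodel in models:
            jobs.append((a, si, ssi, kind,
                         qcoords[a : a + bt, start : start + count], kmodel))

    level = params.level
    if params.workers > 1:
        with ThreadPoolExecutor(max_workers=params.workers) as pool:
            payloads = list(
                pool.map(lambda j: _encode_block(j[3], j[4], level, j[5]), jobs)
            )
    else:
        payloads = [_encode_block(j[3], j[4], level, j[5]) for j in jobs]

    meta = {
        "level": level,
        "batch_size": params.batch_size,
        "subsegment_size": params.subsegment_size,
        "model_frames": mf,
        "precision_pm": params.precision_pm,
        "n_frames": T,
        "n_atoms": N,
    }
    with ArchiveWriter(out_path) as writer:
        writer.append_part("params", json.dumps(meta, sort_keys=True).encode())
        writer.append_part("segment_desc", describe_segments(segments))
        writer.append_part(
            "frame_ids", np.arange(T, dtype="<u8").tobytes()
        )
        writer.append_part(
            "anchor_ids", np.array(anchors, dtype="<u8").tobytes()
        )
        writer.append_part("frame_meta", _serialize_meta(frames))
        if store_topology:
            writer.append_part("topology", _serialize_topology(topo))
        for si, ssi, kind, _, model, _k in models:
            writer.append_part(f"model/{si}/{ssi}", serialize_model(model))
        for (a, si, ssi, _kind, _block, _kmodel), payload in zip(jobs, payloads):
            writer.append_part(f"coords/{si}/{ssi}", payload, aux=a)

    # summary: bits per atom per segment kind
    kind_bytes: Dict[str, int] = {}
    kind_atoms: Dict[str, int] = {}
    for (a, si, ssi, kind, block, _kmodel), payload in zip(jobs, payloads):
        kind_bytes[kind] = kind_bytes.get(kind, 0) + len(payload)
    for seg in segments:
        kind_atoms[seg.kind] = kind_atoms.get(seg.kind, 0) + seg.atom_count
    bits = {
        k: 8.0 * kind_bytes[k] / (kind_atoms[k] * T) for k in kind_bytes
    }
    total_bytes = sum(kind_bytes.values())
    return {
        "n_frames": T,
        "n_atoms": N,
        "coords_payload_bytes": total_bytes,
        "bits_per_atom": {k: bits[k] for k in bits},
        "bits_per_atom_overall": 8.0 * total_bytes / (N * T),
        "n_batches": len(anchors),
        "n_subsegments": len(models),
    }


def compress(
    structure_path,
    trajectory_path,
    out_path,
    params: CompressionParams = CompressionParams(),
) -> Dict:
    """Compress a (GRO structure, trajectory file) pair into an archive."""
    topo = read_structure(structure_path)
    frames = read_trajectory(trajectory_path)
    return compress_frames(topo, frames, out_path, params)


# ---------------------------------------------------------------------------
# Decompression and queries
# ---------------------------------------------------------------------------


class _Opened:
    """Load everything needed to decode blocks from an archive."""

    def __init__(self, reader: ArchiveReader):
        self.reader = reader
        try:
            self.meta = json.loads(reader.read_part("params", 0)[0].decode())
            self.segments = parse_segments(reader.read_part("segment_desc", 0)[0])
            self.anchors = np.frombuffer(
                reader.read_part("anchor_ids", 0)[0], "<u8"
            ).astype(int)
        except (KeyError, IndexError) as exc:
            raise ArchiveFormatError(f"not an mdcz archive: {exc}") from exc
        self.T = self.meta["n_frames"]
        self.N = self.meta["n_atoms"]
        self.level = self.meta["level"]
        self.spec = QuantSpec(self.meta["precision_pm"])
        self._kmodels = {}

    def kmodel(self, si: int, ssi: int):
        key = (si, ssi)
        if key not in self._kmodels:
            seg = self.segments[si]
            start, count = seg.subsegments[ssi]
            model = parse_model(self.reader.read_part(f"model/{si}/{ssi}", 0)[0])
            self._kmodels[key] = _kernel_model(seg.kind, count, model)
        return self._kmodels[key]

    def batch_span(self, bi: int):
        a = int(self.anchors[bi])
        end = int(self.anchors[bi + 1]) if bi + 1 < len(self.anchors) else self.T
        return a, end - a

    def frames_from(self, coords_q: np.ndarray, frame_idx=None) -> List[RawFrame]:
        times, steps, boxes = _parse_meta(
            self.reader.read_part("frame_meta", 0)[0], self.T
        )
        idx = range(self.T) if frame_idx is None else frame_idx
        return [
            RawFrame(
                dequantize(coords_q[t], self.spec),
                boxes[t],
                float(times[t]),
                int(steps[t]),
            )
            for t in idx
        ]

    def topology(self):
        if "topology" in self.reader.list_streams():
            return _parse_topology(self.reader.read_part("topology", 0)[0])
        return None


def _decode_batches(op: _Opened, batch_indices, subseg_filter=None):
    """Decode selected batches (optionally only some subsegments) into a
    (T, N, 3) quantized array; untouched entries stay zero."""
    coords = np.zeros((op.T, op.N, 3), dtype=np.int64)
    for bi in batch_indices:
        a, bt = op.batch_span(bi)
        for si, seg in enumerate(op.segments):
            for ssi, (start, count) in enumerate(seg.subsegments):
                if subseg_filter is not None and (si, ssi) not in subseg_filter:
                    continue
                data, aux = op.reader.read_part(f"coords/{si}/{ssi}", bi)
                if aux != a:
                    raise ArchiveFormatError(
                        f"batch anchor mismatch in coords/{si}/{ssi}[{bi}]"
                    )
                coords[a : a + bt, start : start + count] = _decode_block(
                    seg.kind, data, bt, count, op.level, op.kmodel(si, ssi)
                )
    return coords


def decompress_all(archive_path, out_path=None, fmt: str = "trr") -> List[RawFrame]:
    """Reconstruct every frame; optionally write a TRR/GRO trajectory."""
    with ArchiveReader(archive_path) as reader:
        op = _Opened(reader)
        coords = _decode_batches(op, range(len(op.anchors)))
        frames = op.frames_from(coords)
        topo = op.topology()
    if out_path is not None:
        write_trajectory(out_path, fmt, frames, topo)
    return frames


def query_frames(archive_path, frame_indices) -> List[RawFrame]:
    """Decode only the batches containing the requested frames."""
    frame_indices = list(frame_indices)
    with ArchiveReader(archive_path) as reader:
        op = _Opened(reader)
        for t in frame_indices:
            if not 0 <= t < op.T:
                raise IndexError(f"frame index {t} out of range [0, {op.T})")
        batch_of = np.searchsorted(op.anchors, frame_indices, side="right") - 1
        coords = _decode_batches(op, sorted(set(int(b) for b in batch_of)))
        return op.frames_from(coords, frame_indices)


def query_atoms(archive_path, atom_indices):
    """Per-atom coordinate series over all frames.

    Returns ``(coords_nm (T, len(atom_indices), 3), times)``; only parts of
    subsegments containing requested atoms are read.
    """
    atom_indices = list(atom_indices)
    with ArchiveReader(archive_path) as reader:
        op = _Opened(reader)
        for i in atom_indices:
            if not 0 <= i < op.N:
                raise IndexError(f"atom index {i} out of range [0, {op.N})")
        wanted = set()
        for si, seg in enumerate(op.segments):
            for ssi, (start, count) in enumerate(seg.subsegments):
                if any(start <= i < start + count for i in atom_indices):
                    wanted.add((si, ssi))
        coords = _decode_batches(op, range(len(op.anchors)), subseg_filter=wanted)
        times, _, _ = _parse_meta(reader.read_part("frame_meta", 0)[0], op.T)
        out = dequantize(coords[:, atom_indices, :], op.spec)
    return out, np.asarray(times, dtype=np.float64)


def info(archive_path) -> Dict:
    """Archive report: segments, batches, stream sizes, bits/atom by kind."""
    with ArchiveReader(archive_path) as reader:
        op = _Opened(reader)
        stream_sizes = {
            name: sum(reader.part_sizes(name)) for name in reader.list_streams()
        }
        kind_bytes: Dict[str, int] = {}
        kind_atoms: Dict[str, int] = {}
        for si, seg in enumerate(op.segments):
            kind_atoms[seg.kind] = kind_atoms.get(seg.kind, 0) + seg.atom_count
            for ssi in range(len(seg.subsegments)):
                kind_bytes[seg.kind] = kind_bytes.get(seg.kind, 0) + sum(
                    reader.part_sizes(f"coords/{si}/{ssi}")
                )
        bits = {
            k: 8.0 * kind_bytes[k] / (kind_atoms[k] * op.T) for k in kind_bytes
        }
        coords_bytes = sum(kind_bytes.values())
        overall = 8.0 * coords_bytes / (op.N * op.T)
        return {
            "n_frames": op.T,
            "n_atoms": op.N,
            "level": op.level,
            "precision_pm": op.meta["precision_pm"],
            "batch_size": op.meta["batch_size"],
            "n_batches": len(op.anchors),
            "segments": [
                {"kind": s.kind, "atom_start": s.atom_start,
                 "atom_count": s.atom_count, "n_subsegments": len(s.subsegments)}
                for s in op.segments
            ],
            "stream_sizes": stream_sizes,
            "coords_payload_bytes": coords_bytes,
            "bits_per_atom": bits,
            "bits_per_atom_overall": overall,
            "baseline_trr_bits_per_atom": TRR_BASELINE_BITS,
            "ratio_vs_trr": (TRR_BASELINE_BITS / overall) if overall else float("inf"),
        }
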