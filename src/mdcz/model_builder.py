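"""Per-subsegment prediction models built from the initial trajectory frames.

For MOL subsegments, each atom with local index >= 3 gets three *reference*
atoms: the predecessors (within a window of ``b`` atoms, never crossing the
subsegment boundary) with the smallest mean distance to the atom over the
first ``m`` frames, ordered by increasing mean distance (ties broken by the
smaller index).  The model stores the per-reference *median* distance (in
quantization units, rounded half-to-even) and whether the atom sits above the
plane of its references (majority vote over the model frames; ties count as
above).  For WAT subsegments the model is just the median O-H and H-H
distances over all molecules and model frames.  OTH subsegments carry no
model.

All distances are computed on quantized integer coordinates in double
precision, so compressor and decompressor share identical inputs.  Medians of
even-length samples take the lower middle value.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = [
    "ModelParams",
    "MolModelEntry",
    "WatModel",
    "ModelFormatError",
    "build_mol_model",
    "build_wat_model",
    "serialize_model",
    "parse_model",
]


class ModelFormatError(ValueError):
    """Raised when a serialized model cannot be parsed."""


@dataclass(frozen=True)
class ModelParams:
    m: int = 100  # number of initial frames used to fit the model
    b: int = 100  # predecessor window for reference-atom candidates

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.b < 3:
            raise ValueError("b must be >= 3 (three references are needed)")


@dataclass(frozen=True)
class MolModelEntry:
    p: int
    q: int
    r: int
    d_p: int
    d_q: int
    d_r: int
    plane_side: str  # "above" | "below"


@dataclass(frozen=True)
class WatModel:
    dOH: int
    dHH: int

    def __post_init__(self) -> None:
        if self.dOH <= 0 or self.dHH <= 0:
            raise ValueError("water model distances must be positive")


def _lower_median(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values).ravel())
    return float(v[(v.shape[0] - 1) // 2])


def _round_unit(x: float) -> int:
    return int(np.rint(x))


def _local(frames, subseg):
    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("frames must be (n_frames, n_atoms, 3)")
    if subseg is not None:
        start, count = subseg
        arr = arr[:, start : start + count, :]
    return arr


def build_mol_model(frames, subseg=None, params: ModelParams = ModelParams()):
    """Reference triples + median distances + plane flags for a MOL subsegment.

    ``frames`` holds the quantized model frames ``(n_frames, n_atoms, 3)``;
    ``subseg=(start, count)`` selects the subsegment (``None`` = all atoms).
    Returns one :class:`MolModelEntry` per local atom index >= 3.
    """
    arr = _local(frames, subseg)
    F, n = arr.shape[0], arr.shape[1]
    entries: List[MolModelEntry] = []
    if n < 4:
        return entries
    # mean pairwise distances over the model frames, accumulated per frame to
    # bound memory for large subsegments
    mean_d = np.zeros((n, n))
    for f in range(F):
        diff = arr[f, :, None, :] - arr[f, None, :, :]
        mean_d += np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    mean_d /= F
    b = params.b
    for i in range(3, n):
        lo = min(max(0, i - b), i - 3)  # widen backward if the window is thin
        cand = np.arange(lo, i)
        order = np.lexsort((cand, mean_d[i, cand]))  # mean distance, then index
        refs = cand[order[:3]]
        dists = []
        for ref in refs:
            diff = arr[:, i, :] - arr[:, ref, :]
            per_frame = np.sqrt(np.einsum("fk,fk->f", diff, diff))
            dists.append(_round_unit(_lower_median(per_frame)))
        p, q, r = (int(v) for v in refs)
        # plane side: majority over model frames, ties -> above
        u = arr[:, q, :] - arr[:, p, :]
        w = arr[:, r, :] - arr[:, p, :]
        x = arr[:, i, :] - arr[:, p, :]
        s = np.einsum("fk,fk->f", np.cross(u, w), x)
        above = int(np.count_nonzero(s >= 0))
        entries.append(
            MolModelEntry(
                p, q, r, dists[0], dists[1], dists[2],
                "above" if 2 * above >= F else "below",
            )
        )
    return entries


def build_wat_model(frames, subseg=None) -> WatModel:
    """Median dOH / dHH over every molecule of a WAT subsegment and every
    model frame (both O-H distances contribute to dOH)."""
    arr = _local(frames, subseg)
    n = arr.shape[1]
    if n < 3 or n % 3:
        raise ValueError("WAT subsegment must hold whole O,H,H molecules")
    O = arr[:, 0::3, :]
    H1 = arr[:, 1::3, :]
    H2 = arr[:, 2::3, :]
    doh = np.concatenate(
        [
            np.linalg.norm(H1 - O, axis=2).ravel(),
            np.linalg.norm(H2 - O, axis=2).ravel(),
        ]
    )
    dhh = np.linalg.norm(H2 - H1, axis=2).ravel()
    return WatModel(_round_unit(_lower_median(doh)), _round_unit(_lower_median(dhh)))


# ---------------------------------------------------------------------------
# Serialization (one archive part per subsegment).
# ---------------------------------------------------------------------------

_MOL_ENTRY = struct.Struct("<IIIIIIB")
_WAT_BODY = struct.Struct("<II")
_SIDE_CODE = {"above": 1, "below": 0}
_CODE_SIDE = {v: k for k, v in _SIDE_CODE.items()}


def serialize_model(model) -> bytes:
    """Lossless byte encoding of a subsegment model (MOL entry list, WatModel,
    or ``None`` for OTH)."""
    if model is None:
        return b"O"
    if isinstance(model, WatModel):
        return b"W" + _WAT_BODY.pack(model.dOH, model.dHH)
    parts = [b"M", struct.pack("<I", len(model))]
    for e in model:
        parts.append(
            _MOL_ENTRY.pack(e.p, e.q, e.r, e.d_p, e.d_q, e.d_r,
                            _SIDE_CODE[e.plane_side])
        )
    return b"".join(parts)


def parse_model(data: bytes):
    """Inverse of :func:`serialize_model`."""
    if not data:
        raise ModelFormatError("empty model payload")
    tag = data[:1]
    if tag == b"O":
        if len(data) != 1:
            raise ModelFormatError("trailing bytes in OTH model")
        return None
    if tag == b"W":
        if len(data) != 1 + _WAT_BODY.size:
            raise ModelFormatError("bad WAT model length")
        doh, dhh = _WAT_BODY.unpack(data[1:])
        return WatModel(doh, dhh)
    if tag != b"M":
        raise ModelFormatError(f"unknown model tag {tag!r}")
    if len(data) < 5:
        raise ModelFormatError("truncated MOL model header")
    (count,) = struct.unpack_from("<I", data, 1)
    expected = 5 + count * _MOL_ENTRY.size
    if len(data) != expected:
        raise ModelFormatError("truncated MOL model payload")
    entries = []
    off = 5
    for _ in range(count):
        p, q, r, dp, dq, dr, side = _MOL_ENTRY.unpack_from(data, off)
        off += _MOL_ENTRY.size
        entries.append(MolModelEntry(p, q, r, dp, dq, dr, _CODE_SIDE[side]))
    return entries
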