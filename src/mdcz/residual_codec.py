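"""Coordinate quantization and entropy coding of prediction residuals.

Coordinates in nanometers are quantized to a user-chosen precision (1, 3, 10,
30, or 100 pm); compression is then lossless with respect to the quantized
integer coordinates.  Residuals (true minus predicted coordinate, in
quantization units) are coded with an adaptive binary range coder: each
residual is zigzag-mapped to an unsigned value ``u``, the bit length ``k`` of
``u`` is coded as an adaptive unary sequence in a context determined by
(frame kind, axis, magnitude class of the previous residual on that axis), and
the ``k - 1`` low-order bits of ``u`` follow as near-uniform bypass bits (the
most significant bit is implicit).  Choice bits selecting between geometric
candidate positions are interleaved at their emission points and coded under
their own adaptive models.

Model states are reset at every (subsegment, batch) block boundary so blocks
are independently decodable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import (
    KMAX,
    N_CHOICE,
    N_KMODELS,
    PROB_INIT,
)

__all__ = [
    "ALLOWED_PRECISIONS_PM",
    "QuantSpec",
    "FormatError",
    "quantize",
    "dequantize",
    "rc_encode_bits",
    "rc_decode_bits",
    "encode_residual_block",
    "decode_residual_block",
]

ALLOWED_PRECISIONS_PM = (1, 3, 10, 30, 100)

#: Quantized coordinates must fit a signed 32-bit integer.
_QMAX = 2**31


class FormatError(ValueError):
    """Raised when a compressed byte stream cannot be decoded."""


@dataclass(frozen=True)
class QuantSpec:
    """Coordinate quantization: ``step_nm = precision_pm / 1000``."""

    precision_pm: int = 1

    def __post_init__(self) -> None:
        if self.precision_pm not in ALLOWED_PRECISIONS_PM:
            raise ValueError(
                f"precision_pm must be one of {ALLOWED_PRECISIONS_PM}, "
                f"got {self.precision_pm}"
            )

    @property
    def step_nm(self) -> float:
        return self.precision_pm / 1000.0


def quantize(coords_nm, spec: QuantSpec):
    """Round coordinates (nm) half-to-even to integer quantization units."""
    q = np.rint(np.asarray(coords_nm, dtype=np.float64) / spec.step_nm)
    if np.any(np.abs(q) >= _QMAX):
        raise OverflowError(
            f"coordinate exceeds 2^31 quantization units at {spec.precision_pm} pm"
        )
    return q.astype(np.int64)


def dequantize(q, spec: QuantSpec):
    """Map integer quantization units back to nanometers."""
    return np.asarray(q, dtype=np.float64) * spec.step_nm


# ---------------------------------------------------------------------------
# Raw adaptive-bit interface (exposes the range coder itself).
# ---------------------------------------------------------------------------


def rc_encode_bits(bits, model_ids=None, n_models: int = 1) -> bytes:
    """Range-encode a bit sequence; ``model_ids[i]`` selects the adaptive
    probability model for bit ``i`` (all models start at p = 1/2)."""
    bits = np.ascontiguousarray(bits, dtype=np.uint8)
    if model_ids is None:
        model_ids = np.zeros(bits.shape[0], dtype=np.int64)
    else:
        model_ids = np.ascontiguousarray(model_ids, dtype=np.int64)
        if model_ids.shape != bits.shape:
            raise ValueError("model_ids must parallel bits")
        n_models = max(n_models, int(model_ids.max(initial=0)) + 1)
    # a mispredicted adaptive bit costs at most ~7.05 coded bits (< 1 byte)
    buf = np.empty(bits.shape[0] + 64, dtype=np.uint8)
    nb = _kernels.rc_encode_bits_kernel(bits, model_ids, n_models, buf)
    return bytes(buf[:nb])


def rc_decode_bits(data: bytes, n_bits: int, model_ids=None, n_models: int = 1):
    """Inverse of :func:`rc_encode_bits`; raises :class:`FormatError` if the
    byte stream is too short for ``n_bits`` symbols."""
    if model_ids is None:
        model_ids = np.zeros(n_bits, dtype=np.int64)
    else:
        model_ids = np.ascontiguousarray(model_ids, dtype=np.int64)
        if model_ids.shape[0] != n_bits:
            raise ValueError("model_ids must have n_bits entries")
        n_models = max(n_models, int(model_ids.max(initial=0)) + 1)
    arr = np.frombuffer(data, dtype=np.uint8)
    out = np.empty(n_bits, dtype=np.uint8)
    overrun = _kernels.rc_decode_bits_kernel(arr, model_ids, n_models, out)
    if overrun:
        raise FormatError("range-coded stream truncated (decoder overrun)")
    return out


# ---------------------------------------------------------------------------
# Residual blocks.
# ---------------------------------------------------------------------------


def _block_arrays(n, frame_kinds, axes):
    if frame_kinds is None:
        fk = np.zeros(n, dtype=np.int64)
    else:
        fk = np.ascontiguousarray(frame_kinds, dtype=np.int64)
    if axes is None:
        axes = np.arange(n, dtype=np.int64) % 3
    else:
        axes = np.ascontiguousarray(axes, dtype=np.int64)
    if fk.shape[0] != n or axes.shape[0] != n:
        raise ValueError("frame_kinds and axes must parallel the residuals")
    return fk, axes


def _choice_arrays(choice_bits, choice_pos, choice_models):
    if choice_bits is None:
        z = np.zeros(0, dtype=np.int64)
        return np.zeros(0, dtype=np.uint8), z, z.copy()
    cb = np.ascontiguousarray(choice_bits, dtype=np.uint8)
    cp = np.ascontiguousarray(choice_pos, dtype=np.int64)
    if choice_models is None:
        cm = np.zeros(cb.shape[0], dtype=np.int64)
    else:
        cm = np.ascontiguousarray(choice_models, dtype=np.int64)
    if cp.shape != cb.shape or cm.shape != cb.shape:
        raise ValueError("choice arrays must be parallel")
    if np.any(np.diff(cp) < 0):
        raise ValueError("choice_pos must be non-decreasing")
    if np.any(cm < 0) or np.any(cm >= N_CHOICE):
        raise ValueError(f"choice model ids must be in [0, {N_CHOICE})")
    return cb, cp, cm


def encode_residual_block(
    residuals,
    frame_kinds=None,
    axes=None,
    choice_bits=None,
    choice_pos=None,
    choice_models=None,
) -> bytes:
    """Encode one block of per-coordinate integer residuals (plus optional
    interleaved choice bits) with freshly initialized adaptive models."""
    res = np.ascontiguousarray(residuals, dtype=np.int64)
    fk, axes = _block_arrays(res.shape[0], frame_kinds, axes)
    cb, cp, cm = _choice_arrays(choice_bits, choice_pos, choice_models)
    # worst case ~48 bytes per residual (36 mispredicted unary bits + mantissa)
    buf = np.empty(res.shape[0] * 48 + cb.shape[0] + 4096, dtype=np.uint8)
    nb = _kernels.encode_residual_block_kernel(res, fk, axes, cb, cp, cm, buf)
    return bytes(buf[:nb])


def decode_residual_block(
    data: bytes,
    n_residuals: int,
    frame_kinds=None,
    axes=None,
    choice_pos=None,
    choice_models=None,
):
    """Inverse of :func:`encode_residual_block`.

    Returns ``(residuals, choice_bits)``; raises :class:`FormatError` on a
    truncated byte stream.
    """
    fk, axes = _block_arrays(n_residuals, frame_kinds, axes)
    if choice_pos is None:
        cp = np.zeros(0, dtype=np.int64)
        cm = np.zeros(0, dtype=np.int64)
    else:
        cp = np.ascontiguousarray(choice_pos, dtype=np.int64)
        cm = (
            np.zeros(cp.shape[0], dtype=np.int64)
            if choice_models is None
            else np.ascontiguousarray(choice_models, dtype=np.int64)
        )
    arr = np.frombuffer(data, dtype=np.uint8)
    out = np.empty(n_residuals, dtype=np.int64)
    cbits = np.empty(cp.shape[0], dtype=np.uint8)
    overrun = _kernels.decode_residual_block_kernel(arr, fk, axes, cp, cm, out, cbits)
    if overrun:
        raise FormatError("residual block truncated (decoder overrun)")
    return out, cbits
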