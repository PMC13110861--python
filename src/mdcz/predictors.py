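"""Geometric coordinate predictors for anchor and delta frames.

All functions operate on integer coordinates in quantization units and do
their geometry in double precision with one final round-half-to-even per
coordinate.  Every prediction is a function only of values the decompressor
already knows (previously decoded coordinates, the per-subsegment model, the
compression level, and the frame kind), which is what makes the residual
streams replayable on the decoder side.

Candidate-pair conventions (normative for the format):

* :func:`sphere_line_z` returns ``(z_low, z_high)``;
* :func:`trilaterate` returns the "above" candidate first (on the side of the
  plane normal ``(P2 - P1) x (P3 - P1)``);
* :func:`water_h2_y` returns the two circle-intersection y values in a fixed
  orientation of the in-plane perpendicular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "CandidatePair",
    "LocalFrame",
    "DEGENERATE",
    "predict_oth",
    "sphere_line_z",
    "water_h2_x",
    "water_h2_y",
    "trilaterate",
    "plane_side",
    "build_local_frame",
    "predict_mol_anchor",
    "predict_mol_delta",
    "predict_water",
]

DEGENERATE = "degenerate"
OK = "ok"

_V0 = (0, 0, 0)


@dataclass(frozen=True)
class CandidatePair:
    """Up to two geometric candidates; ``status`` is ``"ok"`` or
    ``"degenerate"`` (candidates unset when degenerate)."""

    status: str
    first: object = None
    second: object = None

    @property
    def ok(self) -> bool:
        return self.status == OK


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal coordinate system anchored at a reference atom."""

    origin: tuple
    basis: np.ndarray  # rows e1, e2, e3


def _v(x):
    a = np.asarray(x, dtype=np.int64)
    if a.shape != (3,):
        raise ValueError("expected a 3-vector")
    return a


def predict_oth(prev_atom_same_frame, same_atom_prev_frame, frame_kind: str):
    """Predictor for small-molecule/ion (OTH) segments.

    Anchor frames copy the preceding atom of the same frame (origin for the
    first atom of a subsegment); delta frames copy the atom's previous-frame
    position.
    """
    if frame_kind == "anchor":
        if prev_atom_same_frame is None:
            return np.zeros(3, dtype=np.int64)
        return _v(prev_atom_same_frame)
    if same_atom_prev_frame is None:
        raise ValueError("delta frames require the previous-frame position")
    return _v(same_atom_prev_frame)


def sphere_line_z(O, x: int, y: int, dOH: int) -> CandidatePair:
    """Intersect the vertical line through (x, y) with sphere(O, dOH)."""
    if dOH <= 0:
        raise ValueError("dOH must be positive")
    o = _v(O)
    ok, zlo, zhi = _kernels.sphere_line_z_kernel(
        o[0], o[1], o[2], int(x), int(y), float(dOH)
    )
    if not ok:
        return CandidatePair(DEGENERATE)
    return CandidatePair(OK, int(zlo), int(zhi))


def water_h2_x(O, H1, dOH: int, dHH: int):
    """x of the centre of the circle sphere(O,dOH) ∩ sphere(H1,dHH), or the
    degenerate pair when the spheres are disjoint or contained."""
    if dOH <= 0 or dHH <= 0:
        raise ValueError("distances must be positive")
    o, h = _v(O), _v(H1)
    ok, x = _kernels.water_h2_x_kernel(
        o[0], o[1], o[2], h[0], h[1], h[2], float(dOH), float(dHH)
    )
    if not ok:
        return CandidatePair(DEGENERATE)
    return CandidatePair(OK, int(x), int(x))


def water_h2_y(O, H1, x: int, dOH: int, dHH: int) -> CandidatePair:
    """y-coordinates of the intersection points of the two circles obtained by
    cutting sphere(O,dOH) and sphere(H1,dHH) with the plane x = const."""
    if dOH <= 0 or dHH <= 0:
        raise ValueError("distances must be positive")
    o, h = _v(O), _v(H1)
    ok, y1, y2 = _kernels.water_h2_y_kernel(
        o[0], o[1], o[2], h[0], h[1], h[2], int(x), float(dOH), float(dHH)
    )
    if not ok:
        return CandidatePair(DEGENERATE)
    return CandidatePair(OK, int(y1), int(y2))


def trilaterate(P1, P2, P3, d1: int, d2: int, d3: int) -> CandidatePair:
    """The two mirror-image points at distances (d1, d2, d3) from (P1, P2, P3)."""
    if d1 <= 0 or d2 <= 0 or d3 <= 0:
        raise ValueError("distances must be positive")
    a, b, c = _v(P1), _v(P2), _v(P3)
    ok, x1, y1, z1, x2, y2, z2 = _kernels.trilaterate_kernel(
        a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2],
        float(d1), float(d2), float(d3),
    )
    if not ok:
        return CandidatePair(DEGENERATE)
    return CandidatePair(
        OK,
        np.array([x1, y1, z1], dtype=np.int64),
        np.array([x2, y2, z2], dtype=np.int64),
    )


def plane_side(P1, P2, P3, X) -> str:
    """``"above"`` or ``"below"`` w.r.t. the plane through P1, P2, P3 with
    normal (P2-P1) x (P3-P1); in-plane points count as above."""
    a, b, c, x = _v(P1), _v(P2), _v(P3), _v(X)
    ok, side = _kernels.plane_side_kernel(
        a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2], x[0], x[1], x[2]
    )
    if not ok:
        raise ValueError("reference points are colinear")
    return "above" if side else "below"


def build_local_frame(P, Q, R):
    """Orthonormal frame with origin P, e1 along Q-P, e3 along e1 x (R-P)."""
    p, q, r = _v(P), _v(Q), _v(R)
    out = _kernels.build_local_frame_kernel(
        p[0], p[1], p[2], q[0], q[1], q[2], r[0], r[1], r[2]
    )
    if not out[0]:
        return CandidatePair(DEGENERATE)
    basis = np.array(out[1:], dtype=np.float64).reshape(3, 3)
    return LocalFrame(origin=tuple(int(v) for v in p), basis=basis)


def predict_mol_anchor(level: int, i_local: int, truth_prior, model=None):
    """Anchor-frame prediction for atom ``i_local`` of a MOL subsegment.

    ``truth_prior`` holds the already-coded true positions of local atoms
    ``0..i_local-1`` in this frame.  Returns ``(prediction, needs_choice_bit,
    chosen_candidates_or_None)``: levels 1-3 copy reference p; level 4
    trilaterates and signals a choice bit; level 5 trilaterates and resolves
    the ambiguity with the stored plane-side flag.
    """
    if i_local == 0:
        return np.zeros(3, dtype=np.int64), False, None
    if i_local < 3 or model is None:
        return _v(truth_prior[i_local - 1]), False, None
    p, q, r = model.p, model.q, model.r
    copy_p = _v(truth_prior[p])
    if level <= 3:
        return copy_p, False, None
    cand = trilaterate(
        truth_prior[p], truth_prior[q], truth_prior[r],
        model.d_p, model.d_q, model.d_r,
    )
    if not cand.ok:
        return copy_p, False, None
    if level == 4:
        return cand, True, cand
    chosen = cand.first if model.plane_side == "above" else cand.second
    return np.asarray(chosen, dtype=np.int64), False, cand


def predict_mol_delta(level: int, prev_pos, refs_prev, refs_cur):
    """Delta-frame prediction for a modeled MOL atom.

    Levels 1-3 translate the previous position by the movement of reference p;
    levels 4-5 carry the previous position through the local coordinate
    systems defined by the references at t-1 and t (falling back to the
    movement vector when either frame is degenerate).
    """
    prev = _v(prev_pos)
    p0 = _v(refs_prev[0])
    p1 = _v(refs_cur[0])
    move = prev + (p1 - p0)
    if level <= 3:
        return move
    f0 = build_local_frame(*refs_prev)
    f1 = build_local_frame(*refs_cur)
    if isinstance(f0, CandidatePair) or isinstance(f1, CandidatePair):
        return move
    d = (prev - p0).astype(np.float64)
    local = f0.basis @ d
    out = np.asarray(p1, dtype=np.float64) + f1.basis.T @ local
    return np.rint(out).astype(np.int64)


def predict_water(
    level: int,
    molecule_truth,
    prev_molecule_O=None,
    prev_frame_O=None,
    frame_kind: str = "anchor",
    wat_model=None,
):
    """Per-atom predictions for one water molecule (atoms ordered O, H1, H2).

    ``molecule_truth`` is the (3, 3) array of the molecule's true quantized
    coordinates: hydrogens are predicted from coordinates of the same molecule
    that have already been coded (the compressor and decompressor both know
    them by the time each later coordinate is predicted).  Returns
    ``(predictions (3, 3), choice_flags (3, 3))`` where a flag marks a
    coordinate whose candidate pair consumes one choice bit.
    """
    truth = np.asarray(molecule_truth, dtype=np.int64)
    if truth.shape != (3, 3):
        raise ValueError("molecule_truth must be (3, 3): O, H1, H2 rows")
    dOH, dHH = int(wat_model.dOH), int(wat_model.dHH)
    pred = np.zeros((3, 3), dtype=np.int64)
    flags = np.zeros((3, 3), dtype=bool)
    if frame_kind == "anchor":
        if prev_molecule_O is not None:
            pred[0] = _v(prev_molecule_O)
    else:
        pred[0] = _v(prev_frame_O)
    O = truth[0]
    # H1: x, y copied from the oxygen; z from the dOH sphere.
    pred[1, 0] = O[0]
    pred[1, 1] = O[1]
    c = sphere_line_z(O, truth[1, 0], truth[1, 1], dOH)
    if c.ok:
        flags[1, 2] = True
        pred[1, 2] = min((c.first, c.second), key=lambda z: abs(int(truth[1, 2]) - z))
    else:
        pred[1, 2] = O[2]
    H1 = truth[1]
    # H2 x: oxygen copy below level 5, sphere-intersection centre at level 5.
    pred[2, 0] = O[0]
    if level >= 5:
        cx = water_h2_x(O, H1, dOH, dHH)
        if cx.ok:
            pred[2, 0] = cx.first
    # H2 y: oxygen copy at levels 1-2, two-circle intersection above.
    pred[2, 1] = O[1]
    if level >= 3:
        cy = water_h2_y(O, H1, truth[2, 0], dOH, dHH)
        if cy.ok:
            flags[2, 1] = True
            pred[2, 1] = min(
                (cy.first, cy.second), key=lambda y: abs(int(truth[2, 1]) - y)
            )
    # H2 z: dOH sphere through the true (x, y); dHH sphere as fallback.
    cz = sphere_line_z(O, truth[2, 0], truth[2, 1], dOH)
    if not cz.ok:
        cz = sphere_line_z(H1, truth[2, 0], truth[2, 1], dHH)
    if cz.ok:
        flags[2, 2] = True
        pred[2, 2] = min((cz.first, cz.second), key=lambda z: abs(int(truth[2, 2]) - z))
    else:
        pred[2, 2] = O[2]
    return pred, flags
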