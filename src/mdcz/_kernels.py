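"""Numba-compiled inner loops: range coder, geometric predictors, block codecs.

Everything in this module operates on plain integer/float scalars and numpy
arrays so it can be compiled with ``numba.njit``.  The functions here are the
single source of truth for the on-disk bit layout: the public wrappers in
:mod:`mdcz.residual_codec` and :mod:`mdcz.predictors` and the batch codecs used
by :mod:`mdcz.pipeline` all call into the same compiled code, so compressor and
decompressor can never disagree on rounding or coder state.

Coordinate convention: all positions are signed integers in quantization units
(default 1 unit = 1 pm).  All intermediate geometry uses float64 with a single
final round-half-to-even per coordinate; that rounding is normative for the
format.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Binary range coder (32-bit range, 64-bit low with carry, byte renorm).
#
# Probabilities are 12-bit (state in (0, 4096), initialised to 2048) and adapt
# with shift-5 updates; the natural fixed points of the update keep the state
# inside [31, 4065] so it can never hit 0 or 4096.
# ---------------------------------------------------------------------------

RC_TOP = 1 << 24
PROB_BITS = 12
PROB_INIT = 1 << (PROB_BITS - 1)
ADAPT_SHIFT = 5

# encoder state layout: [low, range, cache, cache_size, pos]
# decoder state layout: [code, range, pos, overrun]

KMAX = 36  # max unary positions for the bit-length class of a residual


@njit(cache=True, nogil=True, inline="always")
def _shift_low(st, buf):
    low = st[0]
    if low < 0xFF000000 or low > 0xFFFFFFFF:
        carry = low >> 32
        temp = st[2]
        while True:
            buf[st[4]] = (temp + carry) & 0xFF
            st[4] += 1
            temp = 0xFF
            st[3] -= 1
            if st[3] == 0:
                break
        st[2] = (low >> 24) & 0xFF
    st[3] += 1
    st[0] = (low << 8) & 0xFFFFFFFF


@njit(cache=True, nogil=True, inline="always")
def _enc_init(st):
    st[0] = 0
    st[1] = 0xFFFFFFFF
    st[2] = 0
    st[3] = 1
    st[4] = 0


@njit(cache=True, nogil=True, inline="always")
def _enc_bit(st, buf, models, k, bit):
    p = models[k]
    bound = (st[1] >> PROB_BITS) * p
    if bit:
        st[1] = bound
        models[k] = p + ((4096 - p) >> ADAPT_SHIFT)
    else:
        st[0] += bound
        st[1] -= bound
        models[k] = p - (p >> ADAPT_SHIFT)
    if st[1] < RC_TOP:
        st[1] = (st[1] << 8) & 0xFFFFFFFF
        _shift_low(st, buf)


@njit(cache=True, nogil=True, inline="always")
def _enc_bypass(st, buf, bit):
    bound = st[1] >> 1
    if bit:
        st[1] = bound
    else:
        st[0] += bound
        st[1] -= bound
    if st[1] < RC_TOP:
        st[1] = (st[1] << 8) & 0xFFFFFFFF
        _shift_low(st, buf)


@njit(cache=True, nogil=True, inline="always")
def _enc_flush(st, buf):
    for _ in range(5):
        _shift_low(st, buf)
    return st[4]


@njit(cache=True, nogil=True, inline="always")
def _dec_byte(st, buf, n):
    if st[2] < n:
        b = buf[st[2]]
        st[2] += 1
        return np.int64(b)
    st[3] = 1
    return np.int64(0)


@njit(cache=True, nogil=True, inline="always")
def _dec_init(st, buf, n):
    st[0] = 0
    st[1] = 0xFFFFFFFF
    st[2] = 0
    st[3] = 0
    for _ in range(5):
        st[0] = ((st[0] << 8) | _dec_byte(st, buf, n)) & 0xFFFFFFFF


@njit(cache=True, nogil=True, inline="always")
def _dec_bit(st, buf, n, models, k):
    p = models[k]
    bound = (st[1] >> PROB_BITS) * p
    if st[0] < bound:
        bit = 1
        st[1] = bound
        models[k] = p + ((4096 - p) >> ADAPT_SHIFT)
    else:
        bit = 0
        st[0] -= bound
        st[1] -= bound
        models[k] = p - (p >> ADAPT_SHIFT)
    if st[1] < RC_TOP:
        st[1] = (st[1] << 8) & 0xFFFFFFFF
        st[0] = ((st[0] << 8) | _dec_byte(st, buf, n)) & 0xFFFFFFFF
    return bit


@njit(cache=True, nogil=True, inline="always")
def _dec_bypass(st, buf, n):
    bound = st[1] >> 1
    if st[0] < bound:
        bit = 1
        st[1] = bound
    else:
        bit = 0
        st[0] -= bound
        st[1] -= bound
    if st[1] < RC_TOP:
        st[1] = (st[1] << 8) & 0xFFFFFFFF
        st[0] = ((st[0] << 8) | _dec_byte(st, buf, n)) & 0xFFFFFFFF
    return bit


@njit(cache=True, nogil=True)
def rc_encode_bits_kernel(bits, model_ids, n_models, buf):
    """Encode a sequence of bits, each under its own adaptive model id."""
    st = np.zeros(5, dtype=np.int64)
    _enc_init(st)
    models = np.full(n_models, PROB_INIT, dtype=np.int64)
    for i in range(bits.shape[0]):
        _enc_bit(st, buf, models, model_ids[i], bits[i])
    return _enc_flush(st, buf)


@njit(cache=True, nogil=True)
def rc_decode_bits_kernel(data, model_ids, n_models, out):
    st = np.zeros(5, dtype=np.int64)
    _dec_init(st, data, data.shape[0])
    models = np.full(n_models, PROB_INIT, dtype=np.int64)
    for i in range(out.shape[0]):
        out[i] = _dec_bit(st, data, data.shape[0], models, model_ids[i])
    return st[3]


# ---------------------------------------------------------------------------
# Residual coding: zigzag + adaptive unary bit-length class + bypass mantissa.
# Context: (frame kind, axis, magnitude class of previous residual on the axis)
# ---------------------------------------------------------------------------


@njit(cache=True, nogil=True, inline="always")
def _enc_residual(st, buf, kmod, ctxbase, r):
    u = (r << 1) ^ (r >> 63)  # zigzag to unsigned
    k = 0
    while (u >> k) != 0:
        k += 1
    j = 0
    while j < k:
        _enc_bit(st, buf, kmod, ctxbase + j, 1)
        j += 1
    if k < KMAX:
        _enc_bit(st, buf, kmod, ctxbase + k, 0)
    if k >= 2:  # MSB of the mantissa is implicit
        for b in range(k - 2, -1, -1):
            _enc_bypass(st, buf, (u >> b) & 1)
    return k


@njit(cache=True, nogil=True, inline="always")
def _dec_residual(st, buf, n, kmod, ctxbase):
    k = 0
    while k < KMAX:
        if _dec_bit(st, buf, n, kmod, ctxbase + k) == 0:
            break
        k += 1
    if k == 0:
        u = np.int64(0)
    else:
        u = np.int64(1)
        for _ in range(k - 1):
            u = (u << 1) | _dec_bypass(st, buf, n)
    r = (u >> 1) ^ -(u & 1)  # inverse zigzag
    return r, k


@njit(cache=True, nogil=True, inline="always")
def _ctxbase(fk, axis, prevclass):
    return (((fk * 3) + axis) * 8 + prevclass) * KMAX


@njit(cache=True, nogil=True, inline="always")
def _magclass(k):
    if k > 7:
        return 7
    return k


N_KMODELS = 2 * 3 * 8 * KMAX
N_CHOICE = 4  # mol trilateration, wat H1 z, wat H2 y, wat H2 z


@njit(cache=True, nogil=True)
def encode_residual_block_kernel(residuals, fk, axes, cbits, cpos, cmodel, buf):
    """Generic residual block encoder: residuals with choice bits interleaved
    at their emission points (choice bit j is emitted just before residual
    ``cpos[j]``, under adaptive model ``cmodel[j]``)."""
    st = np.zeros(5, dtype=np.int64)
    _enc_init(st)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    cmod = np.full(N_CHOICE, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    cj = 0
    ncb = cbits.shape[0]
    for i in range(residuals.shape[0]):
        while cj < ncb and cpos[cj] == i:
            _enc_bit(st, buf, cmod, cmodel[cj], cbits[cj])
            cj += 1
        a = axes[i]
        k = _enc_residual(st, buf, kmod, _ctxbase(fk[i], a, pc[a]), residuals[i])
        pc[a] = _magclass(k)
    while cj < ncb:
        _enc_bit(st, buf, cmod, cmodel[cj], cbits[cj])
        cj += 1
    return _enc_flush(st, buf)


@njit(cache=True, nogil=True)
def decode_residual_block_kernel(data, fk, axes, cpos, cmodel, out, cbits_out):
    st = np.zeros(5, dtype=np.int64)
    n = data.shape[0]
    _dec_init(st, data, n)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    cmod = np.full(N_CHOICE, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    cj = 0
    ncb = cpos.shape[0]
    for i in range(out.shape[0]):
        while cj < ncb and cpos[cj] == i:
            cbits_out[cj] = _dec_bit(st, data, n, cmod, cmodel[cj])
            cj += 1
        a = axes[i]
        r, k = _dec_residual(st, data, n, kmod, _ctxbase(fk[i], a, pc[a]))
        out[i] = r
        pc[a] = _magclass(k)
    while cj < ncb:
        cbits_out[cj] = _dec_bit(st, data, n, cmod, cmodel[cj])
        cj += 1
    return st[3]


# ---------------------------------------------------------------------------
# Geometry primitives (all return rounded integer candidates).
# ---------------------------------------------------------------------------

DEGEN_TOL = 1e-6


@njit(cache=True, nogil=True, inline="always")
def _rint(x):
    return np.int64(np.rint(x))


@njit(cache=True, nogil=True)
def sphere_line_z_kernel(ox, oy, oz, x, y, d):
    """Intersect the vertical line (x, y, *) with the sphere centred at O of
    radius d.  Returns (ok, z_low, z_high)."""
    disc = float(d) * float(d) - (float(x) - ox) ** 2 - (float(y) - oy) ** 2
    if disc < 0.0:
        return False, np.int64(0), np.int64(0)
    s = np.sqrt(disc)
    return True, _rint(oz - s), _rint(oz + s)


@njit(cache=True, nogil=True)
def water_h2_x_kernel(ox, oy, oz, hx, hy, hz, doh, dhh):
    """x-coordinate of the centre of the circle sphere(O,dOH) ∩ sphere(H1,dHH)."""
    dx = float(hx) - ox
    dy = float(hy) - oy
    dz = float(hz) - oz
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    r1 = float(doh)
    r2 = float(dhh)
    if d <= 0.0 or d > r1 + r2 or d < abs(r1 - r2):
        return False, np.int64(0)
    a = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    return True, _rint(ox + a * dx / d)


@njit(cache=True, nogil=True)
def water_h2_y_kernel(ox, oy, oz, hx, hy, hz, x, doh, dhh):
    """Intersect sphere(O,dOH) and sphere(H1,dHH) with the plane x = const;
    the two circles in that plane meet in up to two points whose y-coordinates
    are returned as (ok, y_first, y_second)."""
    r1sq = float(doh) * doh - (float(x) - ox) ** 2
    r2sq = float(dhh) * dhh - (float(x) - hx) ** 2
    if r1sq < 0.0 or r2sq < 0.0:
        return False, np.int64(0), np.int64(0)
    r1 = np.sqrt(r1sq)
    r2 = np.sqrt(r2sq)
    cy = float(hy) - oy
    cz = float(hz) - oz
    d = np.sqrt(cy * cy + cz * cz)
    if d <= 0.0 or d > r1 + r2 or d < abs(r1 - r2):
        return False, np.int64(0), np.int64(0)
    a = (d * d + r1sq - r2sq) / (2.0 * d)
    hsq = r1sq - a * a
    if hsq < 0.0:
        hsq = 0.0
    h = np.sqrt(hsq)
    uy = cy / d
    uz = cz / d
    # in-plane perpendicular of (uy, uz) is (-uz, uy)
    y1 = oy + a * uy + h * (-uz)
    y2 = oy + a * uy - h * (-uz)
    return True, _rint(y1), _rint(y2)


@njit(cache=True, nogil=True)
def trilaterate_kernel(p1x, p1y, p1z, p2x, p2y, p2z, p3x, p3y, p3z, d1, d2, d3):
    """Both points at distances (d1, d2, d3) from (P1, P2, P3).

    Returns (ok, x1, y1, z1, x2, y2, z2); the first candidate lies on the
    'above' side of the plane (normal along (P2-P1) x (P3-P1))."""
    exx = float(p2x) - p1x
    exy = float(p2y) - p1y
    exz = float(p2z) - p1z
    d = np.sqrt(exx * exx + exy * exy + exz * exz)
    if d < DEGEN_TOL:
        return False, np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0)
    exx /= d
    exy /= d
    exz /= d
    tx = float(p3x) - p1x
    ty = float(p3y) - p1y
    tz = float(p3z) - p1z
    tn = np.sqrt(tx * tx + ty * ty + tz * tz)
    i = exx * tx + exy * ty + exz * tz
    eyx = tx - i * exx
    eyy = ty - i * exy
    eyz = tz - i * exz
    j = np.sqrt(eyx * eyx + eyy * eyy + eyz * eyz)
    if tn < DEGEN_TOL or j < DEGEN_TOL * tn:
        return False, np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0)
    eyx /= j
    eyy /= j
    eyz /= j
    f1 = float(d1)
    f2 = float(d2)
    f3 = float(d3)
    x = (f1 * f1 - f2 * f2 + d * d) / (2.0 * d)
    y = (f1 * f1 - f3 * f3 + i * i + j * j - 2.0 * i * x) / (2.0 * j)
    hsq = f1 * f1 - x * x - y * y
    if hsq < 0.0:
        if hsq > -DEGEN_TOL * (f1 * f1 + 1.0):
            hsq = 0.0
        else:
            return False, np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0), np.int64(0)
    h = np.sqrt(hsq)
    ezx = exy * eyz - exz * eyy
    ezy = exz * eyx - exx * eyz
    ezz = exx * eyy - exy * eyx
    bx = p1x + x * exx + y * eyx
    by = p1y + x * exy + y * eyy
    bz = p1z + x * exz + y * eyz
    return (
        True,
        _rint(bx + h * ezx),
        _rint(by + h * ezy),
        _rint(bz + h * ezz),
        _rint(bx - h * ezx),
        _rint(by - h * ezy),
        _rint(bz - h * ezz),
    )


@njit(cache=True, nogil=True)
def plane_side_kernel(p1x, p1y, p1z, p2x, p2y, p2z, p3x, p3y, p3z, xx, xy, xz):
    """1 if X is on/above the plane through P1,P2,P3 (normal (P2-P1)x(P3-P1)),
    else 0.  Returns (ok, side); ok is False for colinear reference points."""
    ux = float(p2x) - p1x
    uy = float(p2y) - p1y
    uz = float(p2z) - p1z
    wx = float(p3x) - p1x
    wy = float(p3y) - p1y
    wz = float(p3z) - p1z
    nx = uy * wz - uz * wy
    ny = uz * wx - ux * wz
    nz = ux * wy - uy * wx
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    wn = np.sqrt(wx * wx + wy * wy + wz * wz)
    if nn < DEGEN_TOL * max(un * wn, 1.0):
        return False, 1
    s = nx * (float(xx) - p1x) + ny * (float(xy) - p1y) + nz * (float(xz) - p1z)
    if s >= 0.0:
        return True, 1
    return True, 0


@njit(cache=True, nogil=True)
def build_local_frame_kernel(px, py, pz, qx, qy, qz, rx, ry, rz):
    """Right-handed orthonormal frame anchored at P: e1 along Q-P, e3 along
    e1 x (R-P), e2 = e3 x e1.  Returns (ok, e1..., e2..., e3...)."""
    ux = float(qx) - px
    uy = float(qy) - py
    uz = float(qz) - pz
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    z = 0.0
    if un < DEGEN_TOL:
        return False, z, z, z, z, z, z, z, z, z
    e1x = ux / un
    e1y = uy / un
    e1z = uz / un
    wx = float(rx) - px
    wy = float(ry) - py
    wz = float(rz) - pz
    wn = np.sqrt(wx * wx + wy * wy + wz * wz)
    cx = e1y * wz - e1z * wy
    cy = e1z * wx - e1x * wz
    cz = e1x * wy - e1y * wx
    cn = np.sqrt(cx * cx + cy * cy + cz * cz)
    if wn < DEGEN_TOL or cn < DEGEN_TOL * wn:
        return False, z, z, z, z, z, z, z, z, z
    e3x = cx / cn
    e3y = cy / cn
    e3z = cz / cn
    e2x = e3y * e1z - e3z * e1y
    e2y = e3z * e1x - e3x * e1z
    e2z = e3x * e1y - e3y * e1x
    return True, e1x, e1y, e1z, e2x, e2y, e2z, e3x, e3y, e3z


# ---------------------------------------------------------------------------
# Block codecs: one (subsegment x batch) pair per call.  coords is
# (n_frames, n_atoms, 3) int64; frame 0 of the batch is the anchor.
# ---------------------------------------------------------------------------


@njit(cache=True, nogil=True, inline="always")
def _enc_coord(st, buf, kmod, pc, fk, axis, truth, pred):
    k = _enc_residual(st, buf, kmod, _ctxbase(fk, axis, pc[axis]), truth - pred)
    pc[axis] = _magclass(k)


@njit(cache=True, nogil=True, inline="always")
def _dec_coord(st, buf, n, kmod, pc, fk, axis, pred):
    r, k = _dec_residual(st, buf, n, kmod, _ctxbase(fk, axis, pc[axis]))
    pc[axis] = _magclass(k)
    return pred + r


@njit(cache=True, nogil=True)
def _mol_delta_pred(coords, t, i, p, q, r, level):
    """Prediction of atom i in delta frame t of a MOL subsegment."""
    prevx = coords[t - 1, i, 0]
    prevy = coords[t - 1, i, 1]
    prevz = coords[t - 1, i, 2]
    p0x = coords[t - 1, p, 0]
    p0y = coords[t - 1, p, 1]
    p0z = coords[t - 1, p, 2]
    p1x = coords[t, p, 0]
    p1y = coords[t, p, 1]
    p1z = coords[t, p, 2]
    if level <= 3:
        return prevx + (p1x - p0x), prevy + (p1y - p0y), prevz + (p1z - p0z)
    q0x = coords[t - 1, q, 0]
    q0y = coords[t - 1, q, 1]
    q0z = coords[t - 1, q, 2]
    r0x = coords[t - 1, r, 0]
    r0y = coords[t - 1, r, 1]
    r0z = coords[t - 1, r, 2]
    q1x = coords[t, q, 0]
    q1y = coords[t, q, 1]
    q1z = coords[t, q, 2]
    r1x = coords[t, r, 0]
    r1y = coords[t, r, 1]
    r1z = coords[t, r, 2]
    ok0, a1x, a1y, a1z, a2x, a2y, a2z, a3x, a3y, a3z = build_local_frame_kernel(
        p0x, p0y, p0z, q0x, q0y, q0z, r0x, r0y, r0z
    )
    ok1, b1x, b1y, b1z, b2x, b2y, b2z, b3x, b3y, b3z = build_local_frame_kernel(
        p1x, p1y, p1z, q1x, q1y, q1z, r1x, r1y, r1z
    )
    if not (ok0 and ok1):
        # colinear references: fall back to the movement vector of p(i)
        return prevx + (p1x - p0x), prevy + (p1y - p0y), prevz + (p1z - p0z)
    dx = float(prevx) - p0x
    dy = float(prevy) - p0y
    dz = float(prevz) - p0z
    c1 = dx * a1x + dy * a1y + dz * a1z
    c2 = dx * a2x + dy * a2y + dz * a2z
    c3 = dx * a3x + dy * a3y + dz * a3z
    fx = p1x + c1 * b1x + c2 * b2x + c3 * b3x
    fy = p1y + c1 * b1y + c2 * b2y + c3 * b3y
    fz = p1z + c1 * b1z + c2 * b2z + c3 * b3z
    return _rint(fx), _rint(fy), _rint(fz)


@njit(cache=True, nogil=True)
def encode_block_mol(coords, level, refs, rdist, plane, buf):
    T, n = coords.shape[0], coords.shape[1]
    st = np.zeros(5, dtype=np.int64)
    _enc_init(st)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    cmod = np.full(N_CHOICE, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    for t in range(T):
        fk = 0 if t == 0 else 1
        for i in range(n):
            if t == 0:
                if i == 0:
                    px = np.int64(0)
                    py = np.int64(0)
                    pz = np.int64(0)
                elif i < 3:
                    px = coords[0, i - 1, 0]
                    py = coords[0, i - 1, 1]
                    pz = coords[0, i - 1, 2]
                else:
                    p = refs[i, 0]
                    px = coords[0, p, 0]
                    py = coords[0, p, 1]
                    pz = coords[0, p, 2]
                    if level >= 4:
                        q = refs[i, 1]
                        r = refs[i, 2]
                        ok, x1, y1, z1, x2, y2, z2 = trilaterate_kernel(
                            coords[0, p, 0], coords[0, p, 1], coords[0, p, 2],
                            coords[0, q, 0], coords[0, q, 1], coords[0, q, 2],
                            coords[0, r, 0], coords[0, r, 1], coords[0, r, 2],
                            rdist[i, 0], rdist[i, 1], rdist[i, 2],
                        )
                        if ok:
                            if level == 4:
                                tx = coords[0, i, 0]
                                ty = coords[0, i, 1]
                                tz = coords[0, i, 2]
                                e1 = (tx - x1) ** 2 + (ty - y1) ** 2 + (tz - z1) ** 2
                                e2 = (tx - x2) ** 2 + (ty - y2) ** 2 + (tz - z2) ** 2
                                bit = 1 if e2 < e1 else 0
                                _enc_bit(st, buf, cmod, 0, bit)
                                if bit:
                                    px, py, pz = x2, y2, z2
                                else:
                                    px, py, pz = x1, y1, z1
                            else:  # level 5: side stored in the model picks it
                                if plane[i] == 1:
                                    px, py, pz = x1, y1, z1
                                else:
                                    px, py, pz = x2, y2, z2
            else:
                if i < 3 or n < 4:
                    px = coords[t - 1, i, 0]
                    py = coords[t - 1, i, 1]
                    pz = coords[t - 1, i, 2]
                else:
                    px, py, pz = _mol_delta_pred(
                        coords, t, i, refs[i, 0], refs[i, 1], refs[i, 2], level
                    )
            _enc_coord(st, buf, kmod, pc, fk, 0, coords[t, i, 0], px)
            _enc_coord(st, buf, kmod, pc, fk, 1, coords[t, i, 1], py)
            _enc_coord(st, buf, kmod, pc, fk, 2, coords[t, i, 2], pz)
    return _enc_flush(st, buf)


@njit(cache=True, nogil=True)
def decode_block_mol(data, T, n, level, refs, rdist, plane, coords):
    st = np.zeros(5, dtype=np.int64)
    nb = data.shape[0]
    _dec_init(st, data, nb)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    cmod = np.full(N_CHOICE, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    for t in range(T):
        fk = 0 if t == 0 else 1
        for i in range(n):
            if t == 0:
                if i == 0:
                    px = np.int64(0)
                    py = np.int64(0)
                    pz = np.int64(0)
                elif i < 3:
                    px = coords[0, i - 1, 0]
                    py = coords[0, i - 1, 1]
                    pz = coords[0, i - 1, 2]
                else:
                    p = refs[i, 0]
                    px = coords[0, p, 0]
                    py = coords[0, p, 1]
                    pz = coords[0, p, 2]
                    if level >= 4:
                        q = refs[i, 1]
                        r = refs[i, 2]
                        ok, x1, y1, z1, x2, y2, z2 = trilaterate_kernel(
                            coords[0, p, 0], coords[0, p, 1], coords[0, p, 2],
                            coords[0, q, 0], coords[0, q, 1], coords[0, q, 2],
                            coords[0, r, 0], coords[0, r, 1], coords[0, r, 2],
                            rdist[i, 0], rdist[i, 1], rdist[i, 2],
                        )
                        if ok:
                            if level == 4:
                                bit = _dec_bit(st, data, nb, cmod, 0)
                                if bit:
                                    px, py, pz = x2, y2, z2
                                else:
                                    px, py, pz = x1, y1, z1
                            else:
                                if plane[i] == 1:
                                    px, py, pz = x1, y1, z1
                                else:
                                    px, py, pz = x2, y2, z2
            else:
                if i < 3 or n < 4:
                    px = coords[t - 1, i, 0]
                    py = coords[t - 1, i, 1]
                    pz = coords[t - 1, i, 2]
                else:
                    px, py, pz = _mol_delta_pred(
                        coords, t, i, refs[i, 0], refs[i, 1], refs[i, 2], level
                    )
            coords[t, i, 0] = _dec_coord(st, data, nb, kmod, pc, fk, 0, px)
            coords[t, i, 1] = _dec_coord(st, data, nb, kmod, pc, fk, 1, py)
            coords[t, i, 2] = _dec_coord(st, data, nb, kmod, pc, fk, 2, pz)
    return st[3]


@njit(cache=True, nogil=True)
def encode_block_wat(coords, level, doh, dhh, buf):
    T, n = coords.shape[0], coords.shape[1]
    nmol = n // 3
    st = np.zeros(5, dtype=np.int64)
    _enc_init(st)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    cmod = np.full(N_CHOICE, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    for t in range(T):
        fk = 0 if t == 0 else 1
        for w in range(nmol):
            i0 = 3 * w
            # --- oxygen ---
            if t == 0:
                if w == 0:
                    px = np.int64(0)
                    py = np.int64(0)
                    pz = np.int64(0)
                else:
                    px = coords[0, i0 - 3, 0]
                    py = coords[0, i0 - 3, 1]
                    pz = coords[0, i0 - 3, 2]
            else:
                px = coords[t - 1, i0, 0]
                py = coords[t - 1, i0, 1]
                pz = coords[t - 1, i0, 2]
            _enc_coord(st, buf, kmod, pc, fk, 0, coords[t, i0, 0], px)
            _enc_coord(st, buf, kmod, pc, fk, 1, coords[t, i0, 1], py)
            _enc_coord(st, buf, kmod, pc, fk, 2, coords[t, i0, 2], pz)
            ox = coords[t, i0, 0]
            oy = coords[t, i0, 1]
            oz = coords[t, i0, 2]
            # --- first hydrogen: x,y copied from O; z from the dOH sphere ---
            i1 = i0 + 1
            _enc_coord(st, buf, kmod, pc, fk, 0, coords[t, i1, 0], ox)
            _enc_coord(st, buf, kmod, pc, fk, 1, coords[t, i1, 1], oy)
            hx = coords[t, i1, 0]
            hy = coords[t, i1, 1]
            ok, zlo, zhi = sphere_line_z_kernel(ox, oy, oz, hx, hy, doh)
            if ok:
                tz = coords[t, i1, 2]
                bit = 1 if abs(tz - zhi) < abs(tz - zlo) else 0
                _enc_bit(st, buf, cmod, 1, bit)
                pz = zhi if bit else zlo
            else:
                pz = oz
            _enc_coord(st, buf, kmod, pc, fk, 2, coords[t, i1, 2], pz)
            h1x = coords[t, i1, 0]
            h1y = coords[t, i1, 1]
            h1z = coords[t, i1, 2]
            # --- second hydrogen ---
            i2 = i0 + 2
            px = ox
            if level >= 5:
                okx, xc = water_h2_x_kernel(ox, oy, oz, h1x, h1y, h1z, doh, dhh)
                if okx:
                    px = xc
            _enc_coord(st, buf, kmod, pc, fk, 0, coords[t, i2, 0], px)
            x2t = coords[t, i2, 0]
            py = oy
            if level >= 3:
                oky, yc1, yc2 = water_h2_y_kernel(
                    ox, oy, oz, h1x, h1y, h1z, x2t, doh, dhh
                )
                if oky:
                    ty = coords[t, i2, 1]
                    bit = 1 if abs(ty - yc2) < abs(ty - yc1) else 0
                    _enc_bit(st, buf, cmod, 2, bit)
                    py = yc2 if bit else yc1
            _enc_coord(st, buf, kmod, pc, fk, 1, coords[t, i2, 1], py)
            y2t = coords[t, i2, 1]
            okz, zlo, zhi = sphere_line_z_kernel(ox, oy, oz, x2t, y2t, doh)
            if not okz:
                okz, zlo, zhi = sphere_line_z_kernel(h1x, h1y, h1z, x2t, y2t, dhh)
            if okz:
                tz = coords[t, i2, 2]
                bit = 1 if abs(tz - zhi) < abs(tz - zlo) else 0
                _enc_bit(st, buf, cmod, 3, bit)
                pz = zhi if bit else zlo
            else:
                pz = oz
            _enc_coord(st, buf, kmod, pc, fk, 2, coords[t, i2, 2], pz)
    return _enc_flush(st, buf)


@njit(cache=True, nogil=True)
def decode_block_wat(data, T, n, level, doh, dhh, coords):
    nmol = n // 3
    st = np.zeros(5, dtype=np.int64)
    nb = data.shape[0]
    _dec_init(st, data, nb)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    cmod = np.full(N_CHOICE, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    for t in range(T):
        fk = 0 if t == 0 else 1
        for w in range(nmol):
            i0 = 3 * w
            if t == 0:
                if w == 0:
                    px = np.int64(0)
                    py = np.int64(0)
                    pz = np.int64(0)
                else:
                    px = coords[0, i0 - 3, 0]
                    py = coords[0, i0 - 3, 1]
                    pz = coords[0, i0 - 3, 2]
            else:
                px = coords[t - 1, i0, 0]
                py = coords[t - 1, i0, 1]
                pz = coords[t - 1, i0, 2]
            coords[t, i0, 0] = _dec_coord(st, data, nb, kmod, pc, fk, 0, px)
            coords[t, i0, 1] = _dec_coord(st, data, nb, kmod, pc, fk, 1, py)
            coords[t, i0, 2] = _dec_coord(st, data, nb, kmod, pc, fk, 2, pz)
            ox = coords[t, i0, 0]
            oy = coords[t, i0, 1]
            oz = coords[t, i0, 2]
            i1 = i0 + 1
            coords[t, i1, 0] = _dec_coord(st, data, nb, kmod, pc, fk, 0, ox)
            coords[t, i1, 1] = _dec_coord(st, data, nb, kmod, pc, fk, 1, oy)
            hx = coords[t, i1, 0]
            hy = coords[t, i1, 1]
            ok, zlo, zhi = sphere_line_z_kernel(ox, oy, oz, hx, hy, doh)
            if ok:
                bit = _dec_bit(st, data, nb, cmod, 1)
                pz = zhi if bit else zlo
            else:
                pz = oz
            coords[t, i1, 2] = _dec_coord(st, data, nb, kmod, pc, fk, 2, pz)
            h1x = coords[t, i1, 0]
            h1y = coords[t, i1, 1]
            h1z = coords[t, i1, 2]
            i2 = i0 + 2
            px = ox
            if level >= 5:
                okx, xc = water_h2_x_kernel(ox, oy, oz, h1x, h1y, h1z, doh, dhh)
                if okx:
                    px = xc
            coords[t, i2, 0] = _dec_coord(st, data, nb, kmod, pc, fk, 0, px)
            x2t = coords[t, i2, 0]
            py = oy
            if level >= 3:
                oky, yc1, yc2 = water_h2_y_kernel(
                    ox, oy, oz, h1x, h1y, h1z, x2t, doh, dhh
                )
                if oky:
                    bit = _dec_bit(st, data, nb, cmod, 2)
                    py = yc2 if bit else yc1
            coords[t, i2, 1] = _dec_coord(st, data, nb, kmod, pc, fk, 1, py)
            y2t = coords[t, i2, 1]
            okz, zlo, zhi = sphere_line_z_kernel(ox, oy, oz, x2t, y2t, doh)
            if not okz:
                okz, zlo, zhi = sphere_line_z_kernel(h1x, h1y, h1z, x2t, y2t, dhh)
            if okz:
                bit = _dec_bit(st, data, nb, cmod, 3)
                pz = zhi if bit else zlo
            else:
                pz = oz
            coords[t, i2, 2] = _dec_coord(st, data, nb, kmod, pc, fk, 2, pz)
    return st[3]


@njit(cache=True, nogil=True)
def encode_block_oth(coords, buf):
    T, n = coords.shape[0], coords.shape[1]
    st = np.zeros(5, dtype=np.int64)
    _enc_init(st)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    for t in range(T):
        fk = 0 if t == 0 else 1
        for i in range(n):
            if t == 0:
                if i == 0:
                    px = np.int64(0)
                    py = np.int64(0)
                    pz = np.int64(0)
                else:
                    px = coords[0, i - 1, 0]
                    py = coords[0, i - 1, 1]
                    pz = coords[0, i - 1, 2]
            else:
                px = coords[t - 1, i, 0]
                py = coords[t - 1, i, 1]
                pz = coords[t - 1, i, 2]
            _enc_coord(st, buf, kmod, pc, fk, 0, coords[t, i, 0], px)
            _enc_coord(st, buf, kmod, pc, fk, 1, coords[t, i, 1], py)
            _enc_coord(st, buf, kmod, pc, fk, 2, coords[t, i, 2], pz)
    return _enc_flush(st, buf)


@njit(cache=True, nogil=True)
def decode_block_oth(data, T, n, coords):
    st = np.zeros(5, dtype=np.int64)
    nb = data.shape[0]
    _dec_init(st, data, nb)
    kmod = np.full(N_KMODELS, PROB_INIT, dtype=np.int64)
    pc = np.zeros(3, dtype=np.int64)
    for t in range(T):
        fk = 0 if t == 0 else 1
        for i in range(n):
            if t == 0:
                if i == 0:
                    px = np.int64(0)
                    py = np.int64(0)
                    pz = np.int64(0)
                else:
                    px = coords[0, i - 1, 0]
                    py = coords[0, i - 1, 1]
                    pz = coords[0, i - 1, 2]
            else:
                px = coords[t - 1, i, 0]
                py = coords[t - 1, i, 1]
                pz = coords[t - 1, i, 2]
            coords[t, i, 0] = _dec_coord(st, data, nb, kmod, pc, fk, 0, px)
            coords[t, i, 1] = _dec_coord(st, data, nb, kmod, pc, fk, 1, py)
            coords[t, i, 2] = _dec_coord(st, data, nb, kmod, pc, fk, 2, pz)
    return st[3]
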