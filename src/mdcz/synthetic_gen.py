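"""Deterministic synthetic systems for exercising every compression stage.

Three building blocks, assembled in structure-file order (chain "protein",
then rigid 3-point waters, then free ions):

* ``gen_chain`` — a freely rotating chain (~0.15 nm bonds, tetrahedral bond
  angles, random dihedrals) whose
  per-frame motion is rigid-body drift + rotation, torsion-like hinge
  rotations at fixed interior pivots, and a small mean-reverting bond
  vibration correlated along the chain.  Nearby atoms therefore move almost
  rigidly together — the statistical structure the MOL predictors exploit —
  while bonded geometry stays stable over the whole trajectory, as it does
  under a stiff bonded force field;
* ``gen_waterbox`` — rigid 3-point waters (dOH = 0.09572 nm, H-O-H 104.52°,
  hence dHH ≈ 0.15139 nm) that diffuse and tumble between frames;
* free ions performing independent random walks (the hardest case: no
  positional information from neighbours).

Every output is a pure function of (spec, seed); there is no global
randomness.  No force field or periodic wrapping is applied — only the
statistics that matter to a coordinate compressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajectory_io import Atom, RawFrame, TopologyLite, write_structure, write_trajectory

__all__ = [
    "GenSpec",
    "WATER_DOH_NM",
    "WATER_DHH_NM",
    "gen_chain",
    "gen_waterbox",
    "gen_ions",
    "gen_system",
    "write_fixture",
]

WATER_DOH_NM = 0.09572
WATER_HOH_DEG = 104.52
WATER_DHH_NM = 2 * WATER_DOH_NM * math.sin(math.radians(WATER_HOH_DEG) / 2)

_BOND_NM = 0.15
_BOND_ANGLE_DEG = 109.47  # tetrahedral backbone bond angle


@dataclass(frozen=True)
class GenSpec:
    n_chain_atoms: int = 0
    n_waters: int = 0
    n_ions: int = 0
    n_frames: int = 10
    step_sigma_nm: float = 0.01  # per-axis RMS inter-frame displacement
    rigid: bool = True  # exact water geometry (no per-atom jitter)
    seed: int = 0
    jitter_nm: float = 0.001  # per-atom noise when rigid is off
    box_nm: float = 6.0
    dt_ps: float = 1.0


def _unit(v):
    return v / np.linalg.norm(v)


def _rot_matrix(axis, angle):
    axis = _unit(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _rand_rot(rng, angle_sigma=None):
    axis = _unit(rng.normal(size=3))
    angle = rng.uniform(0, 2 * math.pi) if angle_sigma is None else rng.normal(
        0, angle_sigma
    )
    return _rot_matrix(axis, angle)


_HINGE_SPACING = 50  # chain atoms per torsion pivot
_VIB_FRAC = 0.15  # bond-vibration share of the per-axis displacement scale
_DRIFT_FRAC = 0.30  # rigid translation share
_CHAIN_RHO = 0.95  # vibration correlation between chain neighbours
_VIB_MEMORY = 0.5  # frame-to-frame persistence of the vibration offset


def _chain_correlated(rng, n, scale):
    """Gaussian (n, 3) field with per-axis std ``scale`` and AR(1)
    correlation ``_CHAIN_RHO`` between consecutive chain atoms."""
    eps = rng.normal(0.0, scale, (n, 3))
    out = np.empty_like(eps)
    out[0] = eps[0]
    w = math.sqrt(1.0 - _CHAIN_RHO**2)
    for i in range(1, n):
        out[i] = _CHAIN_RHO * out[i - 1] + w * eps[i]
    return out


def gen_chain(spec: GenSpec, rng=None) -> np.ndarray:
    """Frames ``(n_frames, n_chain_atoms, 3)`` of the synthetic chain (nm).

    Per-frame motion is composed of (i) a rigid-body translation and a
    rotation about the centre of mass, (ii) torsion-like rotations of the
    chain tail about fixed interior hinge atoms, and (iii) a small
    mean-reverting per-atom vibration correlated along the chain.  The
    rotation and hinge magnitudes are calibrated each frame from the current
    geometry so the expected mean per-atom displacement norm matches the
    isotropic-Gaussian value ``sqrt(8/pi) * step_sigma_nm`` (per-axis RMS
    displacement ≈ ``step_sigma_nm``, exactly equal when the motion field is
    homogeneous).  Components (i) and (ii) move every local neighbourhood
    rigidly, so bonded geometry is exactly preserved by them; only the
    vibration term perturbs inter-atomic distances, and it stays bounded
    instead of accumulating.
    """
    if spec.n_chain_atoms < 6:
        raise ValueError("a chain needs at least 6 atoms")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, T, sigma = spec.n_chain_atoms, spec.n_frames, spec.step_sigma_nm
    # initial configuration: freely rotating chain — ~0.15 nm bonds at a
    # fixed tetrahedral bond angle with random dihedrals, so consecutive
    # atom triples are always well bent (near-colinear reference triples,
    # which no bonded backbone produces, would make the local coordinate
    # systems used by the MOL predictors ill-conditioned)
    pos = np.zeros((n, 3))
    d = _unit(rng.normal(size=3))
    center = np.full(3, spec.box_nm / 2)
    pos[0] = center
    deflection = math.radians(180.0 - _BOND_ANGLE_DEG)
    for i in range(1, n):
        perp = _unit(np.cross(d, rng.normal(size=3)))
        d = math.cos(deflection) * d + math.sin(deflection) * perp
        pos[i] = pos[i - 1] + _BOND_NM * d
    pos -= pos.mean(axis=0) - center
    # drift + vibration are homogeneous; rotation + hinges are scaled per
    # frame so the total mean displacement norm hits the target below
    sig_drift = _DRIFT_FRAC * sigma
    sig_vib = _VIB_FRAC * sigma
    hinges = np.arange(_HINGE_SPACING, n - 3, _HINGE_SPACING)
    # mean-reverting vibration: per-frame displacement variance of the OU
    # offset v_t = a v_{t-1} + sqrt(1-a^2) eps equals 2(1-a) var(v) per axis
    vib_disp_var = 2.0 * (1.0 - _VIB_MEMORY) * sig_vib**2
    # E|N(0, s^2 I3)| = sqrt(8/pi) s; same constant approximates the norm
    # inflation that isotropic noise of per-axis variance v^2 adds to a
    # deterministic displacement mu: E|mu + noise| ~ sqrt(|mu|^2 + (8/pi) v^2)
    norm_c = 8.0 / math.pi
    target = math.sqrt(norm_c) * sigma
    frames = np.empty((T, n, 3))
    vib = _chain_correlated(rng, n, sig_vib) if sig_vib > 0 else np.zeros((n, 3))
    frames[0] = pos + vib
    for t in range(1, T):
        drift = rng.normal(0.0, sig_drift, 3) if sig_drift > 0 else np.zeros(3)
        field = np.zeros((n, 3))
        # global rotation about the centre of mass (linearized for scaling)
        com = pos.mean(axis=0)
        theta = rng.normal()
        rot_axis = _unit(rng.normal(size=3))
        rot_field = theta * np.cross(rot_axis, pos - com)
        rot_rms = math.sqrt(float(np.mean(np.sum(rot_field**2, axis=1))))
        if rot_rms > 0:
            w_rot = 1.0 if hinges.size == 0 else math.sqrt(0.4)
            field += (w_rot / rot_rms) * rot_field
        # torsion-like hinge rotations; each hinge swings either the head or
        # the tail of the chain so displacement stays spread along the chain
        spans, gains, axes = [], None, None
        if hinges.size:
            gains = rng.normal(size=hinges.size)
            axes = np.stack([_unit(rng.normal(size=3)) for _ in hinges])
            tails = rng.random(hinges.size) < 0.5
            spans = [
                slice(a + 1, n) if tails[h] else slice(0, a)
                for h, a in enumerate(hinges)
            ]
            hfield = np.zeros((n, 3))
            for h, a in enumerate(hinges):
                hfield[spans[h]] += gains[h] * np.cross(
                    axes[h], pos[spans[h]] - pos[a]
                )
            h_rms = math.sqrt(float(np.mean(np.sum(hfield**2, axis=1))))
            if h_rms > 0:
                field += (math.sqrt(0.6) / h_rms) * hfield
        # solve mean_i sqrt(|s field_i + drift|^2 + (8/pi) vib_var) = target
        scale = 0.0
        if sigma > 0 and float(np.max(np.abs(field))) > 0:
            floor = norm_c * vib_disp_var

            def mean_norm(s):
                mu = s * field + drift
                return float(np.mean(np.sqrt(np.sum(mu**2, axis=1) + floor)))

            lo, hi = 0.0, target
            while mean_norm(hi) < target and hi < 1e6 * target:
                hi *= 2.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if mean_norm(mid) < target:
                    lo = mid
                else:
                    hi = mid
            scale = 0.5 * (lo + hi)
        # apply the motions exactly (rigid rotations, not the linearization)
        if scale > 0 and hinges.size:
            s_h = scale * math.sqrt(0.6) / h_rms if h_rms > 0 else 0.0
            for h, a in enumerate(hinges):
                rot = _rot_matrix(axes[h], s_h * gains[h])
                pos[spans[h]] = (pos[spans[h]] - pos[a]) @ rot.T + pos[a]
        if scale > 0 and rot_rms > 0:
            w_rot = 1.0 if hinges.size == 0 else math.sqrt(0.4)
            rot = _rot_matrix(rot_axis, scale * w_rot * theta / rot_rms)
            pos = (pos - com) @ rot.T + com
        pos = pos + drift
        if sig_vib > 0:
            vib = _VIB_MEMORY * vib + _chain_correlated(
                rng, n, sig_vib * math.sqrt(1.0 - _VIB_MEMORY**2)
            )
        frames[t] = pos + vib
    return frames


def _water_local():
    a = math.radians(WATER_HOH_DEG)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_DOH_NM, 0.0, 0.0],
            [WATER_DOH_NM * math.cos(a), WATER_DOH_NM * math.sin(a), 0.0],
        ]
    )


def gen_waterbox(spec: GenSpec, rng=None) -> np.ndarray:
    """Frames ``(n_frames, 3 * n_waters, 3)`` of rigid waters (nm)."""
    if spec.n_waters < 1:
        raise ValueError("need at least one water")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    T, nw = spec.n_frames, spec.n_waters
    local = _water_local()
    side = max(int(math.ceil(nw ** (1.0 / 3.0))), 1)
    spacing = spec.box_nm / max(side, 1)
    centers = np.empty((nw, 3))
    rots = np.empty((nw, 3, 3))
    for w in range(nw):
        gx, gy, gz = w % side, (w // side) % side, w // (side * side)
        centers[w] = (np.array([gx, gy, gz]) + 0.5) * spacing + rng.normal(
            0, 0.05 * spacing, 3
        )
        rots[w] = _rand_rot(rng)
    frames = np.empty((T, 3 * nw, 3))
    tumble = 0.3  # rad per frame, picosecond-scale water reorientation
    for t in range(T):
        if t > 0:
            centers = centers + rng.normal(0, spec.step_sigma_nm, (nw, 3))
            for w in range(nw):
                rots[w] = _rand_rot(rng, tumble) @ rots[w]
        for w in range(nw):
            atoms = local @ rots[w].T + centers[w]
            if not spec.rigid and spec.jitter_nm > 0:
                atoms = atoms + rng.normal(0, spec.jitter_nm, (3, 3))
            frames[t, 3 * w : 3 * w + 3] = atoms
    return frames


def gen_ions(spec: GenSpec, rng=None) -> np.ndarray:
    """Frames ``(n_frames, n_ions, 3)`` of independent random walkers (nm)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    T, ni = spec.n_frames, spec.n_ions
    pos = rng.uniform(0, spec.box_nm, (ni, 3))
    frames = np.empty((T, ni, 3))
    frames[0] = pos
    for t in range(1, T):
        pos = pos + rng.normal(0, spec.step_sigma_nm, (ni, 3))
        frames[t] = pos
    return frames


_CHAIN_RESNAMES = ("ALA", "GLY", "SER", "VAL", "LEU")
_CHAIN_ATOMS = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


def gen_system(spec: GenSpec):
    """Assemble chain + waters + ions into ``(TopologyLite, [RawFrame])``.

    Segment classification of the result yields exactly [MOL, WAT, OTH] (each
    present iff its count is positive), in that order.
    """
    if spec.n_chain_atoms + 3 * spec.n_waters + spec.n_ions < 1:
        raise ValueError("system must contain at least one atom")
    rng = np.random.default_rng(spec.seed)
    blocks = []
    atoms = []
    resid = 0
    mol = -1
    if spec.n_chain_atoms:
        blocks.append(gen_chain(spec, rng))
        mol += 1
        for i in range(spec.n_chain_atoms):
            if i % len(_CHAIN_ATOMS) == 0:
                resid += 1
            name, element = _CHAIN_ATOMS[i % len(_CHAIN_ATOMS)]
            resname = _CHAIN_RESNAMES[(resid - 1) % len(_CHAIN_RESNAMES)]
            atoms.append(Atom(element, name, resname, resid, mol))
    if spec.n_waters:
        blocks.append(gen_waterbox(spec, rng))
        for _ in range(spec.n_waters):
            resid += 1
            mol += 1
            atoms.append(Atom("O", "OW", "SOL", resid, mol))
            atoms.append(Atom("H", "HW1", "SOL", resid, mol))
            atoms.append(Atom("H", "HW2", "SOL", resid, mol))
    if spec.n_ions:
        blocks.append(gen_ions(spec, rng))
        for _ in range(spec.n_ions):
            resid += 1
            mol += 1
            atoms.append(Atom("Na", "NA", "NA", resid, mol))
    topo = TopologyLite(atoms)
    coords = np.concatenate(blocks, axis=1)
    box = np.diag([spec.box_nm] * 3)
    frames = [
        RawFrame(coords[t], box, t * spec.dt_ps, t) for t in range(spec.n_frames)
    ]
    return topo, frames


def write_fixture(spec: GenSpec, gro_path, trr_path):
    """Write a matched (system.gro, traj.trr) pair; returns (topo, frames)."""
    topo, frames = gen_system(spec)
    write_structure(gro_path, topo, frames[0])
    write_trajectory(trr_path, "trr", frames)
    return topo, frames
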