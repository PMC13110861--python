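"""Reading and writing structures and trajectories (GRO text, TRR binary).

Internal units follow the GROMACS convention: nanometers and picoseconds.
The TRR dialect handled here is big-endian, single-precision, magic 1993,
with a mandatory coordinate block; velocity/force blocks are skipped on read
and never written, and double-precision files are rejected loudly.  XTC input
is available as an optional adapter through MDAnalysis.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from typing import List, NamedTuple

import numpy as np

__all__ = [
    "Atom",
    "TopologyLite",
    "RawFrame",
    "ParseError",
    "TrajectoryFormatError",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "write_structure",
    "sniff_format",
]


class ParseError(ValueError):
    """Malformed structure/trajectory text (message names the line)."""


class TrajectoryFormatError(ValueError):
    """Unreadable or inconsistent trajectory data."""


class Atom(NamedTuple):
    element: str
    name: str
    resname: str
    resid: int
    molecule: int


@dataclass
class TopologyLite:
    """Ordered atom records with inferred molecule boundaries."""

    atoms: List[Atom]

    def __post_init__(self) -> None:
        mol = -1
        for i, a in enumerate(self.atoms):
            if not a.element or not a.resname:
                raise ValueError(f"atom {i} lacks an element or residue name")
            if a.molecule < mol:
                raise ValueError("molecule indices must be non-decreasing")
            mol = a.molecule

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_molecules(self) -> int:
        return self.atoms[-1].molecule + 1 if self.atoms else 0


@dataclass
class RawFrame:
    """One trajectory frame: per-atom coordinates (nm), box (nm), time (ps)."""

    coords: np.ndarray
    box: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    time: float = 0.0
    step: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3, 3)
        if not np.all(np.isfinite(self.box)):
            raise ValueError("box entries must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# Element and molecule inference (GRO files carry no explicit bonds).
# ---------------------------------------------------------------------------

AMINO_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
    TYR VAL HID HIE HIP HSD HSE HSP CYX CYM ASH GLH LYN ACE NME NMA""".split()
)

_TWO_LETTER_ELEMENTS = frozenset(
    "NA CL MG ZN CA FE BR MN CU CO NI LI RB CS SR BA CD HG AL SI SE".split()
)


def infer_element(atom_name: str, resname: str) -> str:
    """Element from the leading alphabetic characters of the atom name.

    A name identical to an ion-like residue name (NA, CL, MG, ...) maps to the
    two-letter element; otherwise the first letter wins, which is the MD
    convention for protein/water atom names (CA is an alpha carbon).
    """
    run = re.match(r"\d*([A-Za-z]+)", atom_name.strip())
    if not run:
        return ""
    alpha = run.group(1).upper()
    if alpha == resname.strip().upper() and alpha in _TWO_LETTER_ELEMENTS:
        return alpha.capitalize()
    return alpha[0]


def assign_molecules(records) -> List[Atom]:
    """Apply the residue-transition molecule rule to (element, name, resname,
    resid) records: a new molecule starts when the residue index decreases or
    at any residue change, except that runs of consecutive amino-acid residues
    stay one molecule (protein chains)."""
    atoms: List[Atom] = []
    mol = 0
    prev_resid = None
    prev_resname = None
    for element, name, resname, resid in records:
        if prev_resid is not None:
            new_residue = resid != prev_resid or resname != prev_resname
            if new_residue:
                same_chain = (
                    resid >= prev_resid
                    and resname.upper() in AMINO_RESNAMES
                    and prev_resname.upper() in AMINO_RESNAMES
                )
                if not same_chain:
                    mol += 1
        atoms.append(Atom(element, name, resname, resid, mol))
        prev_resid, prev_resname = resid, resname
    return atoms


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------


def _parse_gro_box(line: str, lineno: int) -> np.ndarray:
    try:
        v = [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric box entry") from exc
    box = np.zeros((3, 3))
    if len(v) == 3:
        box[0, 0], box[1, 1], box[2, 2] = v
    elif len(v) == 9:
        (box[0, 0], box[1, 1], box[2, 2], box[0, 1], box[0, 2],
         box[1, 0], box[1, 2], box[2, 0], box[2, 1]) = v
    else:
        raise ParseError(f"line {lineno}: box line must have 3 or 9 values")
    return box


def _read_gro_block(lines, start):
    """Parse one GRO model starting at line index ``start``.

    Returns (records, coords, box, time_or_None, next_start).
    """
    if start >= len(lines) or not lines[start].strip() and start + 1 >= len(lines):
        raise ParseError(f"line {start + 1}: empty file or truncated model")
    title = lines[start]
    m = re.search(r"\bt\s*=\s*([-+0-9.eE]+)", title)
    time = float(m.group(1)) if m else None
    if start + 1 >= len(lines):
        raise ParseError(f"line {start + 2}: missing atom count line")
    try:
        natoms = int(lines[start + 1].strip())
    except ValueError as exc:
        raise ParseError(f"line {start + 2}: malformed atom count") from exc
    first_atom = start + 2
    records = []
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        ln = first_atom + i
        if ln >= len(lines):
            raise ParseError(f"line {ln + 1}: truncated atom record block")
        line = lines[ln]
        if len(line.rstrip("\n")) < 44:
            raise ParseError(f"line {ln + 1}: truncated atom record")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            coords[i, 0] = float(line[20:28])
            coords[i, 1] = float(line[28:36])
            coords[i, 2] = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"line {ln + 1}: malformed atom record") from exc
        records.append((infer_element(name, resname), name, resname, resid))
    box_ln = first_atom + natoms
    if box_ln >= len(lines):
        raise ParseError(f"line {box_ln + 1}: missing box line")
    box = _parse_gro_box(lines[box_ln], box_ln + 1)
    return records, coords, box, time, box_ln + 1


def read_structure(path) -> TopologyLite:
    """Parse the first model of a GRO file into a :class:`TopologyLite`."""
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("line 1: empty file")
    records, _, _, _, _ = _read_gro_block(lines, 0)
    return TopologyLite(assign_molecules(records))


def _read_gro_trajectory(path) -> List[RawFrame]:
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("line 1: empty file")
    frames: List[RawFrame] = []
    pos = 0
    while pos < len(lines):
        if not any(s.strip() for s in lines[pos:]):
            break  # trailing blank lines
        _, coords, box, time, pos = _read_gro_block(lines, pos)
        frames.append(
            RawFrame(coords, box, time if time is not None else float(len(frames)),
                     step=len(frames))
        )
    return frames


def _write_gro(path, frames, topo=None) -> None:
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"mdcz frame {fi}, t= {frame.time:.5f}\n")
            fh.write(f"{frame.n_atoms:5d}\n")
            for i in range(frame.n_atoms):
                if topo is not None:
                    a = topo.atoms[i]
                    resid, resname, name = a.resid % 100000, a.resname, a.name
                else:
                    resid, resname, name = (i % 100000) + 1, "UNK", "X"
                x, y, z = frame.coords[i]
                fh.write(
                    f"{resid:5d}{resname:<5.5s}{name:>5.5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            b = frame.box
            off_diag = b - np.diag(np.diag(b))
            if np.any(off_diag != 0):
                fh.write(
                    " ".join(
                        f"{v:10.5f}" for v in (
                            b[0, 0], b[1, 1], b[2, 2], b[0, 1], b[0, 2],
                            b[1, 0], b[1, 2], b[2, 0], b[2, 1],
                        )
                    ) + "\n"
                )
            else:
                fh.write(f"{b[0, 0]:10.5f} {b[1, 1]:10.5f} {b[2, 2]:10.5f}\n")


def write_structure(path, topo: TopologyLite, frame: RawFrame) -> None:
    """Write a single-model GRO carrying the topology's names."""
    _write_gro(path, [frame], topo)


# ---------------------------------------------------------------------------
# TRR (big-endian, single precision, magic 1993)
# ---------------------------------------------------------------------------

_TRR_MAGIC = 1993
_TRR_VERSION = b"GMX_trn_file"


def _read_trr_frames(path) -> List[RawFrame]:
    frames: List[RawFrame] = []
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) == 0:
        raise TrajectoryFormatError(f"{path}: zero-length file")
    off = 0
    n = len(data)
    while off < n:
        if n - off < 4:
            raise TrajectoryFormatError(f"{path}: truncated TRR header")
        (magic,) = struct.unpack_from(">i", data, off)
        if magic != _TRR_MAGIC:
            raise TrajectoryFormatError(
                f"{path}: bad TRR magic {magic} at offset {off}"
            )
        try:
            len1, len2 = struct.unpack_from(">ii", data, off + 4)
            tag_end = off + 12 + len2
            tag = data[off + 12 : tag_end]
            (ir_size, e_size, box_size, vir_size, pres_size, top_size,
             sym_size, x_size, v_size, f_size, natoms, step, nre) = (
                struct.unpack_from(">13i", data, tag_end)
            )
        except struct.error as exc:
            raise TrajectoryFormatError(f"{path}: truncated TRR header") from exc
        if tag != _TRR_VERSION:
            raise TrajectoryFormatError(f"{path}: unknown TRR version tag {tag!r}")
        fsize = 0
        if box_size:
            fsize = box_size // 9
        elif x_size:
            fsize = x_size // (natoms * 3)
        if fsize == 8:
            raise TrajectoryFormatError(
                f"{path}: double-precision TRR is not supported"
            )
        if fsize not in (0, 4):
            raise TrajectoryFormatError(f"{path}: inconsistent TRR block sizes")
        if x_size == 0:
            raise TrajectoryFormatError(
                f"{path}: TRR frame without coordinate block"
            )
        pos = tag_end + 52
        try:
            t, lam = struct.unpack_from(">ff", data, pos)
        except struct.error as exc:
            raise TrajectoryFormatError(f"{path}: truncated TRR header") from exc
        pos += 8
        box = np.zeros((3, 3))
        if box_size:
            box = np.frombuffer(data, ">f4", 9, pos).astype(np.float64).reshape(3, 3)
            pos += box_size
        pos += vir_size + pres_size
        if pos + x_size > n:
            raise TrajectoryFormatError(f"{path}: truncated coordinate block")
        coords = (
            np.frombuffer(data, ">f4", natoms * 3, pos)
            .astype(np.float64)
            .reshape(natoms, 3)
        )
        pos += x_size + v_size + f_size
        frames.append(RawFrame(coords, box, float(t), int(step)))
        off = pos
    return frames


def _write_trr(path, frames) -> None:
    with open(path, "wb") as fh:
        for frame in frames:
            natoms = frame.n_atoms
            x_size = natoms * 3 * 4
            box_size = 36
            header = struct.pack(
                ">i ii 12s 13i ff".replace(" ", ""),
                _TRR_MAGIC, 13, 12, _TRR_VERSION,
                0, 0, box_size, 0, 0, 0, 0, x_size, 0, 0,
                natoms, frame.step, 0,
                float(frame.time), 0.0,
            )
            fh.write(header)
            fh.write(frame.box.astype(">f4").tobytes())
            fh.write(frame.coords.astype(">f4").tobytes())


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def sniff_format(path) -> str:
    """Detect trr/xtc by magic number or gro by text heuristic; binary garbage
    yields ``"unknown"`` rather than an exception."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(4096)
    except OSError:
        return "unknown"
    if len(head) >= 4:
        (magic,) = struct.unpack_from(">i", head, 0)
        if magic == _TRR_MAGIC:
            return "trr"
        if magic == 1995:
            return "xtc"
    try:
        text = head.decode("utf-8")
    except UnicodeDecodeError:
        return "unknown"
    lines = text.splitlines()
    if len(lines) >= 2 and lines[1].strip().isdigit():
        return "gro"
    return "unknown"


def _read_xtc(path) -> List[RawFrame]:
    try:
        import MDAnalysis.coordinates.XTC as mda_xtc
    except ImportError as exc:  # pragma: no cover - optional adapter
        raise TrajectoryFormatError(
            "XTC input requires the optional MDAnalysis adapter"
        ) from exc
    frames = []
    with mda_xtc.XTCReader(str(path)) as reader:
        for ts in reader:
            frames.append(
                RawFrame(
                    ts.positions.astype(np.float64) / 10.0,  # A -> nm
                    ts.triclinic_dimensions.astype(np.float64) / 10.0,
                    float(ts.time),
                    int(ts.frame),
                )
            )
    return frames


def read_trajectory(path, fmt: str = "auto") -> List[RawFrame]:
    """Read all frames of a trajectory; coordinates in nm, frames in file order."""
    if fmt == "auto":
        fmt = sniff_format(path)
    if fmt == "trr":
        frames = _read_trr_frames(path)
    elif fmt == "gro":
        frames = _read_gro_trajectory(path)
    elif fmt == "xtc":
        frames = _read_xtc(path)
    else:
        raise TrajectoryFormatError(f"{path}: unrecognized trajectory format")
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    n0 = frames[0].n_atoms
    for i, f in enumerate(frames):
        if f.n_atoms != n0:
            raise TrajectoryFormatError(
                f"{path}: frame {i} has {f.n_atoms} atoms, expected {n0}"
            )
    return frames


def write_trajectory(path, fmt: str, frames, topo: TopologyLite | None = None) -> None:
    """Write frames as TRR (single-precision) or GRO (3 decimals = 1 pm)."""
    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an empty frame list")
    n0 = frames[0].n_atoms
    if any(f.n_atoms != n0 for f in frames):
        raise ValueError("all frames must have the same atom count")
    if fmt == "trr":
        _write_trr(path, frames)
    elif fmt == "gro":
        _write_gro(path, frames, topo)
    else:
        raise ValueError(f"unsupported output format {fmt!r} (use trr or gro)")
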