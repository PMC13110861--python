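"""Structure/trajectory I/O: GRO and TRR round trips, sniffing, errors.

MDAnalysis is used purely as an independent oracle for the TRR dialect.
"""

import numpy as np
import pytest

from mdcz import GenSpec, RawFrame, read_structure, read_trajectory, sniff_format
from mdcz.synthetic_gen import write_fixture
from mdcz.trajectory_io import (
    ParseError,
    TrajectoryFormatError,
    infer_element,
    write_structure,
    write_trajectory,
)

SOL_GRO = """water
    3
    1SOL     OW    1   1.000   1.000   1.000
    1SOL    HW1    2   1.096   1.000   1.000
    1SOL    HW2    3   0.976   1.092   1.000
   3.0   3.0   3.0
"""


def _frames(n_frames, n_atoms, rng, box_nm=3.0):
    box = np.diag([box_nm] * 3)
    return [
        RawFrame(rng.uniform(0, box_nm, (n_atoms, 3)), box, 0.5 * t, t)
        for t in range(n_frames)
    ]


class TestReadStructure:
    def test_single_water_residue(self, tmp_path):
        path = tmp_path / "sol.gro"
        path.write_text(SOL_GRO)
        topo = read_structure(path)
        assert topo.n_atoms == 3
        assert topo.n_molecules == 1
        assert [a.element for a in topo.atoms] == ["O", "H", "H"]
        assert [a.resname for a in topo.atoms] == ["SOL"] * 3

    def test_fixture_chain_plus_waters(self, tmp_path):
        spec = GenSpec(n_chain_atoms=60, n_waters=5, n_frames=2, seed=1)
        topo_gen, _ = write_fixture(spec, tmp_path / "s.gro", tmp_path / "t.trr")
        topo = read_structure(tmp_path / "s.gro")
        assert topo.n_atoms == 75
        # 1 chain molecule + 5 waters
        assert topo.n_molecules == 6
        assert [a.element for a in topo.atoms] == [a.element for a in topo_gen.atoms]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.gro"
        path.write_text("")
        with pytest.raises(ParseError):
            read_structure(path)

    def test_malformed_atom_count_names_line(self, tmp_path):
        path = tmp_path / "bad.gro"
        path.write_text("title\nnot-a-number\n")
        with pytest.raises(ParseError, match="line 2"):
            read_structure(path)

    def test_truncated_atom_records(self, tmp_path):
        path = tmp_path / "short.gro"
        path.write_text("title\n    3\n    1SOL     OW    1   1.0   1.0   1.0\n")
        with pytest.raises(ParseError):
            read_structure(path)


class TestElementInference:
    @pytest.mark.parametrize(
        "name,resname,element",
        [
            ("CA", "ALA", "C"),  # alpha carbon in an amino acid, not calcium
            ("OW", "SOL", "O"),
            ("HW1", "SOL", "H"),
            ("NA", "NA", "Na"),
            ("CL", "CL", "Cl"),
            ("1HB", "ALA", "H"),  # leading digits skipped
        ],
    )
    def test_examples(self, name, resname, element):
        assert infer_element(name, resname) == element


class TestTrrRoundTrip:
    def test_coordinates_within_single_precision(self, tmp_path, rng):
        frames = _frames(10, 17, rng)
        path = tmp_path / "t.trr"
        write_trajectory(path, "trr", frames)
        back = read_trajectory(path)
        assert len(back) == 10
        for f, g in zip(frames, back):
            assert np.allclose(f.coords, g.coords, rtol=2**-23, atol=2**-26)
            assert np.allclose(f.box, g.box, rtol=2**-23)
            assert g.time == pytest.approx(f.time, rel=1e-6)
            assert g.step == f.step

    def test_rewrite_is_byte_identical(self, tmp_path, rng):
        a, b = tmp_path / "a.trr", tmp_path / "b.trr"
        write_trajectory(a, "trr", _frames(3, 8, rng))
        write_trajectory(b, "trr", read_trajectory(a))
        assert a.read_bytes() == b.read_bytes()

    def test_matches_mdanalysis_reader(self, tmp_path, rng):
        mda = pytest.importorskip("MDAnalysis")
        frames = _frames(4, 12, rng)
        path = tmp_path / "oracle.trr"
        write_trajectory(path, "trr", frames)
        u = mda.coordinates.TRR.TRRReader(str(path))
        assert u.n_frames == 4
        for f, ts in zip(frames, u):
            # MDAnalysis reports Angstrom
            assert np.allclose(ts.positions / 10.0, f.coords, atol=1e-5)
            assert ts.time == pytest.approx(f.time, abs=1e-5)

    def test_reads_mdanalysis_written_trr(self, tmp_path, rng):
        mda = pytest.importorskip("MDAnalysis")
        frames = _frames(3, 9, rng)
        ours = tmp_path / "ours.trr"
        theirs = tmp_path / "theirs.trr"
        write_trajectory(ours, "trr", frames)
        u = mda.Universe.empty(9, trajectory=True)
        with mda.coordinates.TRR.TRRWriter(str(theirs), n_atoms=9) as w:
            for ts in mda.coordinates.TRR.TRRReader(str(ours)):
                u.atoms.positions = ts.positions
                u.dimensions = ts.dimensions
                w.write(u.atoms)
        back = read_trajectory(theirs)
        assert len(back) == 3
        for f, g in zip(frames, back):
            assert np.allclose(f.coords, g.coords, atol=1e-5)

    def test_zero_length_file(self, tmp_path):
        path = tmp_path / "zero.trr"
        path.write_bytes(b"")
        with pytest.raises(TrajectoryFormatError):
            read_trajectory(path)

    def test_unknown_magic(self, tmp_path):
        path = tmp_path / "junk.trr"
        path.write_bytes(b"\x00" * 128)
        with pytest.raises(TrajectoryFormatError):
            read_trajectory(path, fmt="trr")


class TestGroTrajectory:
    def test_multi_frame_times_from_title(self, tmp_path, rng):
        frames = _frames(5, 6, rng)
        path = tmp_path / "t.gro"
        write_trajectory(path, "gro", frames)
        back = read_trajectory(path)
        assert len(back) == 5
        for f, g in zip(frames, back):
            assert np.allclose(f.coords, g.coords, atol=5.1e-4)  # 3 decimals nm
            assert g.time == pytest.approx(f.time, abs=1e-6)

    def test_times_default_to_frame_index(self, tmp_path):
        block = SOL_GRO.replace("water", "no time here")
        path = tmp_path / "t.gro"
        path.write_text(block * 3)
        back = read_trajectory(path)
        assert [f.time for f in back] == [0.0, 1.0, 2.0]

    def test_structure_round_trip(self, tmp_path, rng):
        spec = GenSpec(n_chain_atoms=12, n_waters=2, n_ions=1, n_frames=1, seed=9)
        from mdcz import gen_system

        topo, frames = gen_system(spec)
        path = tmp_path / "s.gro"
        write_structure(path, topo, frames[0])
        topo2 = read_structure(path)
        assert [a.name for a in topo2.atoms] == [a.name for a in topo.atoms]
        assert [a.molecule for a in topo2.atoms] == [a.molecule for a in topo.atoms]


class TestWriteValidation:
    def test_empty_frame_list(self, tmp_path):
        with pytest.raises(ValueError):
            write_trajectory(tmp_path / "x.trr", "trr", [])

    def test_mismatched_atom_counts(self, tmp_path, rng):
        f1 = _frames(1, 5, rng)[0]
        f2 = _frames(1, 6, rng)[0]
        with pytest.raises(ValueError):
            write_trajectory(tmp_path / "x.trr", "trr", [f1, f2])

    def test_inconsistent_frames_on_read(self, tmp_path, rng):
        a, b = tmp_path / "a.trr", tmp_path / "b.trr"
        write_trajectory(a, "trr", _frames(1, 5, rng))
        write_trajectory(b, "trr", _frames(1, 6, rng))
        combined = tmp_path / "c.trr"
        combined.write_bytes(a.read_bytes() + b.read_bytes())
        with pytest.raises(TrajectoryFormatError):
            read_trajectory(combined)


class TestSniff:
    def test_trr(self, tmp_path, rng):
        path = tmp_path / "t.trr"
        write_trajectory(path, "trr", _frames(1, 4, rng))
        assert sniff_format(path) == "trr"

    def test_gro(self, tmp_path):
        path = tmp_path / "t.gro"
        path.write_text(SOL_GRO)
        assert sniff_format(path) == "gro"

    def test_random_bytes_unknown(self, tmp_path, rng):
        path = tmp_path / "t.bin"
        path.write_bytes(bytes(rng.integers(0, 256, 100, dtype=np.uint8)))
        assert sniff_format(path) == "unknown"
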