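"""Segment classification, subsegment tiling, and description round trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdcz.segmentation import (
    MOL,
    OFF,
    OTH,
    WAT,
    Segment,
    SegmentFormatError,
    classify_segments,
    describe_segments,
    parse_segments,
    split_subsegments,
)
from mdcz.trajectory_io import Atom, TopologyLite


def _chain(n, mol, resname="ALA"):
    return [Atom("C", "CA", resname, mol + 1, mol) for _ in range(n)]


def _water(mol, resname="SOL"):
    return [
        Atom("O", "OW", resname, mol + 1, mol),
        Atom("H", "HW1", resname, mol + 1, mol),
        Atom("H", "HW2", resname, mol + 1, mol),
    ]


def _ion(mol, element="Na", resname="NA"):
    return [Atom(element, element.upper(), resname, mol + 1, mol)]


def _topo(*molecule_groups):
    atoms = []
    for group in molecule_groups:
        atoms.extend(group)
    return TopologyLite(atoms)


class TestClassification:
    def test_mixed_system_tiling(self):
        """Large chain, small chain, a block of waters, then ions."""
        groups = [_chain(1200, 0), _chain(30, 1)]
        mol = 2
        for _ in range(500):
            groups.append(_water(mol))
            mol += 1
        for _ in range(10):
            groups.append(_ion(mol))
            mol += 1
        segs = classify_segments(_topo(*groups))
        assert [(s.kind, s.atom_count) for s in segs] == [
            (MOL, 1200),
            (MOL, 30),
            (WAT, 1500),
            (OTH, 10),
        ]
        assert [s.atom_start for s in segs] == [0, 1200, 1230, 2730]

    def test_six_atom_molecule_is_mol(self):
        segs = classify_segments(_topo(_chain(6, 0)))
        assert [(s.kind, s.atom_count) for s in segs] == [(MOL, 6)]

    def test_five_atom_molecule_is_oth(self):
        segs = classify_segments(_topo(_chain(5, 0)))
        assert [(s.kind, s.atom_count) for s in segs] == [(OTH, 5)]

    def test_two_ions_form_one_oth_run(self):
        segs = classify_segments(_topo(_ion(0), _ion(1, "Cl", "CL")))
        assert [(s.kind, s.atom_count) for s in segs] == [(OTH, 2)]

    def test_wrong_atom_order_water_is_oth(self):
        """H,O,H is not a valid 3-point water ordering."""
        bad = [
            Atom("H", "HW1", "SOL", 1, 0),
            Atom("O", "OW", "SOL", 1, 0),
            Atom("H", "HW2", "SOL", 1, 0),
        ]
        segs = classify_segments(_topo(bad))
        assert [(s.kind, s.atom_count) for s in segs] == [(OTH, 3)]

    def test_non_whitelisted_resname_is_oth(self):
        segs = classify_segments(_topo(_water(0, resname="MEO")))
        assert [s.kind for s in segs] == [OTH]

    def test_water_whitelist_variants(self):
        groups = []
        for i, resname in enumerate(["SOL", "WAT", "HOH", "TIP3", "H2O"]):
            groups.append(_water(i, resname=resname))
        segs = classify_segments(_topo(*groups))
        assert [(s.kind, s.atom_count) for s in segs] == [(WAT, 15)]

    def test_water_run_broken_by_ion(self):
        segs = classify_segments(_topo(_water(0), _ion(1), _water(2)))
        assert [(s.kind, s.atom_count) for s in segs] == [
            (WAT, 3),
            (OTH, 1),
            (WAT, 3),
        ]

    def test_segments_tile_the_atom_list(self, small_system):
        topo, _ = small_system
        segs = classify_segments(topo)
        pos = 0
        for seg in segs:
            assert seg.atom_start == pos
            pos += seg.atom_count
        assert pos == topo.n_atoms

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Segment("XYZ", 0, 10)


class TestSubsegments:
    def test_mol_split(self):
        seg = Segment(MOL, 0, 250)
        split_subsegments(seg, 100)
        assert seg.subsegments == [(0, 100), (100, 100), (200, 50)]

    def test_wat_split_rounds_to_whole_molecules(self):
        seg = Segment(WAT, 0, 1500)
        split_subsegments(seg, 100)
        assert seg.subsegments[:2] == [(0, 99), (99, 99)]
        assert seg.subsegments[-1] == (1485, 15)
        assert len(seg.subsegments) == 16
        assert all(c % 3 == 0 for _, c in seg.subsegments)

    def test_off_yields_single_subsegment(self):
        seg = Segment(MOL, 40, 250)
        split_subsegments(seg, OFF)
        assert seg.subsegments == [(40, 250)]

    def test_size_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            split_subsegments(Segment(MOL, 0, 100), 5)

    def test_offset_segment_absolute_starts(self):
        seg = Segment(OTH, 1230, 20)
        split_subsegments(seg, 8)
        assert seg.subsegments == [(1230, 8), (1238, 8), (1246, 4)]

    @given(
        kind=st.sampled_from([MOL, WAT, OTH]),
        start=st.integers(0, 10_000),
        count=st.integers(1, 5_000),
        size=st.integers(6, 500),
    )
    def test_subsegments_tile_segment(self, kind, start, count, size):
        seg = split_subsegments(Segment(kind, start, count), size)
        pos = start
        for s, c in seg.subsegments:
            assert s == pos and c > 0
            pos += c
        assert pos == start + count


class TestDescriptionRoundTrip:
    def test_round_trip(self):
        segs = [
            split_subsegments(Segment(MOL, 0, 250), 100),
            split_subsegments(Segment(WAT, 250, 1500), 100),
            split_subsegments(Segment(OTH, 1750, 20), OFF),
        ]
        back = parse_segments(describe_segments(segs))
        assert back == segs

    def test_empty_list(self):
        assert parse_segments(describe_segments([])) == []

    def test_byte_flip_detected(self):
        data = bytearray(describe_segments([Segment(MOL, 0, 10, [(0, 10)])]))
        data[6] ^= 0xFF
        with pytest.raises(SegmentFormatError):
            parse_segments(bytes(data))

    def test_truncation_detected(self):
        data = describe_segments([Segment(WAT, 0, 9, [(0, 9)])])
        with pytest.raises(SegmentFormatError):
            parse_segments(data[: len(data) // 2])

    def test_trailing_bytes_detected(self):
        import struct
        import zlib

        data = describe_segments([])
        body = data[:-4] + b"\x00"
        bad = body + struct.pack("<I", zlib.crc32(body))
        with pytest.raises(SegmentFormatError):
            parse_segments(bad)

    def test_bad_magic_detected(self):
        import struct
        import zlib

        body = b"XXXX" + describe_segments([])[4:-4]
        bad = body + struct.pack("<I", zlib.crc32(body))
        with pytest.raises(SegmentFormatError):
            parse_segments(bad)
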