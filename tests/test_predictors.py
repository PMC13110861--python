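"""Geometric predictors: analytic cases, degeneracies, and rigid-motion oracles."""

import numpy as np
import pytest

from mdcz.model_builder import MolModelEntry, WatModel
from mdcz.predictors import (
    CandidatePair,
    LocalFrame,
    build_local_frame,
    plane_side,
    predict_mol_anchor,
    predict_mol_delta,
    predict_oth,
    predict_water,
    sphere_line_z,
    trilaterate,
    water_h2_x,
    water_h2_y,
)


class TestPredictOth:
    def test_first_atom_anchor_is_origin(self):
        assert predict_oth(None, None, "anchor").tolist() == [0, 0, 0]

    def test_anchor_copies_predecessor(self):
        assert predict_oth((5, 6, 7), None, "anchor").tolist() == [5, 6, 7]

    def test_delta_copies_previous_frame(self):
        assert predict_oth((5, 6, 7), (9, 9, 9), "delta").tolist() == [9, 9, 9]

    def test_delta_requires_previous_frame(self):
        with pytest.raises(ValueError):
            predict_oth((1, 2, 3), None, "delta")


class TestSphereLineZ:
    def test_axis_case(self):
        c = sphere_line_z((0, 0, 0), 0, 0, 10)
        assert c.ok
        assert sorted((c.first, c.second)) == [-10, 10]

    def test_tangent_case(self):
        c = sphere_line_z((0, 0, 0), 6, 8, 10)
        assert c.ok
        assert (c.first, c.second) == (0, 0)

    def test_line_misses_sphere(self):
        assert not sphere_line_z((0, 0, 0), 0, 20, 10).ok

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            sphere_line_z((0, 0, 0), 0, 0, 0)


class TestWaterH2X:
    def test_symmetric_lens(self):
        c = water_h2_x((0, 0, 0), (10, 0, 0), 10, 10)
        assert c.ok and c.first == 5

    def test_center_displaced_in_y_only(self):
        c = water_h2_x((0, 0, 0), (0, 10, 0), 10, 10)
        assert c.ok and c.first == 0

    def test_disjoint_spheres(self):
        assert not water_h2_x((0, 0, 0), (100, 0, 0), 10, 10).ok

    def test_contained_spheres(self):
        assert not water_h2_x((0, 0, 0), (1, 0, 0), 100, 10).ok


class TestWaterH2Y:
    def test_circle_subtraction_forces_y(self):
        c = water_h2_y((0, 0, 0), (0, 8, 0), 0, 10, 10)
        assert c.ok
        assert (c.first, c.second) == (4, 4)

    def test_plane_beyond_sphere(self):
        assert not water_h2_y((0, 0, 0), (0, 8, 0), 50, 10, 10).ok

    def test_recovers_constructed_truth(self, rng):
        # construct H2, hand the predictor the *exact* distances: the
        # construction is its own oracle
        checked = 0
        while checked < 200:
            O = rng.integers(-1000, 1000, 3)
            H1 = O + rng.integers(-120, 120, 3)
            H2 = O + rng.integers(-120, 120, 3)
            dOH = float(np.linalg.norm(H2 - O))
            dHH = float(np.linalg.norm(H2 - H1))
            if dOH < 5 or dHH < 5:
                continue
            checked += 1
            c = water_h2_y(O, H1, int(H2[0]), dOH, dHH)
            assert c.ok
            assert min(abs(c.first - H2[1]), abs(c.second - H2[1])) <= 1


class TestTrilaterate:
    def test_symmetric_construction(self):
        c = trilaterate((0, 0, 0), (10, 0, 0), (0, 10, 0), 10, 14, 14)
        assert c.ok
        above, below = c.first, c.second
        assert np.abs(above - np.array([0, 0, 10])).max() <= 1
        assert np.abs(below - np.array([0, 0, -10])).max() <= 1

    def test_above_candidate_first(self):
        c = trilaterate((0, 0, 0), (10, 0, 0), (0, 10, 0), 10, 14, 14)
        assert plane_side((0, 0, 0), (10, 0, 0), (0, 10, 0), c.first) == "above"
        assert plane_side((0, 0, 0), (10, 0, 0), (0, 10, 0), c.second) == "below"

    def test_colinear_references_degenerate(self):
        assert not trilaterate((0, 0, 0), (10, 0, 0), (20, 0, 0), 5, 5, 5).ok

    def test_recovers_exact_constructions(self, rng):
        for _ in range(200):
            P = rng.integers(-1000, 1000, (3, 3))
            if not isinstance(build_local_frame(*P), LocalFrame):
                continue
            X = rng.integers(-1000, 1000, 3)
            d = [float(np.linalg.norm(X - P[k])) for k in range(3)]
            if min(d) < 1:
                continue
            c = trilaterate(P[0], P[1], P[2], *d)
            assert c.ok
            best = min(
                np.abs(c.first - X).max(), np.abs(c.second - X).max()
            )
            assert best <= 1


class TestPlaneSide:
    P = ((0, 0, 0), (1, 0, 0), (0, 1, 0))

    def test_above(self):
        assert plane_side(*self.P, (0, 0, 5)) == "above"

    def test_below(self):
        assert plane_side(*self.P, (0, 0, -5)) == "below"

    def test_in_plane_counts_as_above(self):
        assert plane_side(*self.P, (3, 4, 0)) == "above"

    def test_colinear_references_raise(self):
        with pytest.raises(ValueError):
            plane_side((0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 0, 5))


class TestBuildLocalFrame:
    def test_identity_basis(self):
        f = build_local_frame((0, 0, 0), (10, 0, 0), (0, 10, 0))
        assert isinstance(f, LocalFrame)
        assert np.allclose(f.basis, np.eye(3))
        assert f.origin == (0, 0, 0)

    def test_colinear_degenerate(self):
        f = build_local_frame((0, 0, 0), (5, 0, 0), (10, 0, 0))
        assert isinstance(f, CandidatePair) and not f.ok

    def test_coincident_degenerate(self):
        f = build_local_frame((3, 3, 3), (3, 3, 3), (0, 10, 0))
        assert isinstance(f, CandidatePair) and not f.ok

    def test_orthonormality(self, rng):
        checked = 0
        while checked < 50:
            P = rng.integers(-500, 500, (3, 3))
            f = build_local_frame(*P)
            if not isinstance(f, LocalFrame):
                continue
            checked += 1
            assert np.abs(f.basis @ f.basis.T - np.eye(3)).max() < 1e-9
            assert np.linalg.det(f.basis) == pytest.approx(1.0, abs=1e-9)


MODEL = MolModelEntry(0, 1, 2, 10, 14, 14, "above")
REFS = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=np.int64)


class TestPredictMolAnchor:
    def test_first_atom_is_origin(self):
        pred, bit, _ = predict_mol_anchor(2, 0, np.empty((0, 3), np.int64))
        assert pred.tolist() == [0, 0, 0] and not bit

    def test_second_atom_copies_first(self):
        truth = np.array([[4, 5, 6]], dtype=np.int64)
        pred, bit, _ = predict_mol_anchor(2, 1, truth)
        assert pred.tolist() == [4, 5, 6] and not bit

    def test_low_levels_copy_reference_p(self):
        truth = np.array([[7, 7, 7], [1, 1, 1], [2, 2, 2]], dtype=np.int64)
        pred, bit, _ = predict_mol_anchor(2, 3, truth, MODEL)
        assert pred.tolist() == [7, 7, 7] and not bit

    def test_level_four_emits_choice_bit(self):
        pred, bit, cand = predict_mol_anchor(4, 3, REFS, MODEL)
        assert bit
        best = min(
            np.abs(np.asarray(cand.first) - [0, 0, 10]).max(),
            np.abs(np.asarray(cand.second) - [0, 0, 10]).max(),
        )
        assert best <= 1

    def test_level_five_uses_plane_flag(self):
        pred, bit, _ = predict_mol_anchor(5, 3, REFS, MODEL)
        assert not bit
        assert np.abs(pred - [0, 0, 10]).max() <= 1

    def test_degenerate_falls_back_to_copy(self):
        colinear = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], dtype=np.int64)
        pred, bit, _ = predict_mol_anchor(4, 3, colinear, MODEL)
        assert pred.tolist() == [0, 0, 0] and not bit


class TestPredictMolDelta:
    def test_movement_vector_rule(self):
        refs_prev = REFS
        refs_cur = REFS + np.array([3, -1, 2])
        pred = predict_mol_delta(2, (0, 0, 0), refs_prev, refs_cur)
        assert pred.tolist() == [3, -1, 2]

    def test_rigid_translation_is_exact_at_level_five(self, rng):
        for _ in range(50):
            refs = rng.integers(-500, 500, (3, 3))
            if not isinstance(build_local_frame(*refs), LocalFrame):
                continue
            prev = rng.integers(-500, 500, 3)
            t = rng.integers(-100, 100, 3)
            pred = predict_mol_delta(5, prev, refs, refs + t)
            assert pred.tolist() == (prev + t).tolist()

    def test_rotation_carried_through_local_frame(self):
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        refs_prev = REFS + np.array([50, 20, -30])
        prev = np.array([17, -40, 25])
        pivot = refs_prev[0]
        refs_cur = (refs_prev - pivot) @ rot.T + pivot
        expected = (prev - pivot) @ rot.T + pivot
        pred = predict_mol_delta(5, prev, refs_prev, refs_cur)
        assert np.abs(pred - expected).max() <= 1

    def test_degenerate_frame_falls_back_to_movement(self):
        colinear = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        pred = predict_mol_delta(5, (1, 2, 3), colinear, colinear + 7)
        assert pred.tolist() == [8, 9, 10]


class TestPredictWater:
    # H1 straight above O, H2 on the intersection circle where x = centre x,
    # so every hydrogen coordinate closes geometrically up to rounding.
    TRUTH = np.array([[0, 0, 0], [0, 0, 96], [0, 93, -23]], dtype=np.int64)
    MODEL = WatModel(96, 151)

    def test_first_molecule_anchor_oxygen_origin(self):
        pred, _ = predict_water(1, self.TRUTH, wat_model=self.MODEL)
        assert pred[0].tolist() == [0, 0, 0]

    def test_anchor_oxygen_copies_previous_molecule(self):
        pred, _ = predict_water(
            1, self.TRUTH, prev_molecule_O=(4, 4, 4), wat_model=self.MODEL
        )
        assert pred[0].tolist() == [4, 4, 4]

    def test_delta_oxygen_copies_previous_frame(self):
        pred, _ = predict_water(
            1, self.TRUTH, prev_frame_O=(9, 8, 7), frame_kind="delta",
            wat_model=self.MODEL,
        )
        assert pred[0].tolist() == [9, 8, 7]

    def test_rigid_molecule_hydrogen_residuals_within_one_unit(self):
        pred, flags = predict_water(5, self.TRUTH, wat_model=self.MODEL)
        assert np.abs(pred[1:] - self.TRUTH[1:]).max() <= 1
        # sphere/circle intersections found -> choice bits on H1 z, H2 y, H2 z
        assert flags[1, 2] and flags[2, 1] and flags[2, 2]

    def test_low_level_h2_xy_copy_oxygen(self):
        pred, flags = predict_water(2, self.TRUTH, wat_model=self.MODEL)
        assert pred[2, 0] == self.TRUTH[0, 0]
        assert pred[2, 1] == self.TRUTH[0, 1]
        assert not flags[2, 1]

    def test_h1_outside_sphere_falls_back_to_oxygen_z(self):
        truth = self.TRUTH.copy()
        truth[1] = [500, 500, 96]  # (x, y) far outside sphere(O, dOH)
        pred, flags = predict_water(5, truth, wat_model=self.MODEL)
        assert pred[1, 2] == truth[0, 2]
        assert not flags[1, 2]

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            predict_water(1, np.zeros((2, 3)), wat_model=self.MODEL)
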