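"""Binding-axis geometry, positional coordinate, greedy matching, subsites."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gtase import pose, synth
from gtase.pose import DegenerateAxisError, OrientationError

from conftest import (
    greedy_match_oracle,
    optimal_match_count,
    xyz_to_pose,
    xyz_to_reference,
)


def make_axis_reference(start, end, origin):
    """Three-atom reference whose anchors are at the given positions."""
    return xyz_to_reference(np.array([start, end, origin], dtype=float))


class TestBindingAxis:
    def test_orthogonal_projection_by_inspection(self):
        ref = make_axis_reference([0, 0, 0], [2, 0, 0], [1, 5, 0])
        axis = pose.build_binding_axis(ref)
        np.testing.assert_allclose(axis.direction, [1, 0, 0])
        np.testing.assert_allclose(axis.origin, [1, 0, 0])

    def test_oblique_axis_projection(self):
        ref = make_axis_reference([0, 0, 0], [3, 4, 0], [3, 4, 12])
        axis = pose.build_binding_axis(ref)
        np.testing.assert_allclose(axis.direction, [0.6, 0.8, 0])
        np.testing.assert_allclose(axis.origin, [3, 4, 0], atol=1e-12)

    def test_coincident_anchors_are_degenerate(self):
        ref = make_axis_reference([1, 1, 1], [1, 1, 1], [0, 0, 0])
        with pytest.raises(DegenerateAxisError):
            pose.build_binding_axis(ref)


class TestPositionalCoordinate:
    def test_centroid_at_origin_is_zero(self):
        ref = make_axis_reference([0, 0, 0], [2, 0, 0], [1, 5, 0])
        axis = pose.build_binding_axis(ref)
        p = xyz_to_pose([[1, 3, 0], [1, -3, 0]])  # centroid (1,0,0) = origin
        assert pose.positional_coordinate(p, axis) == pytest.approx(0.0)

    def test_displaced_centroid_gives_signed_projection(self):
        ref = make_axis_reference([0, 0, 0], [2, 0, 0], [1, 5, 0])
        axis = pose.build_binding_axis(ref)
        p = xyz_to_pose([axis.origin + 2.5 * axis.direction])
        assert pose.positional_coordinate(p, axis) == pytest.approx(2.5)

    @given(t=st.floats(-20, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_along_axis_is_linear(self, t):
        ref = synth.gen_reference_ligand(seed=5)
        axis = pose.build_binding_axis(ref)
        base = synth.gen_poses(ref, synth.PoseGenConfig(n_poses=1, seed=2))[0]
        shifted = xyz_to_pose(base.coordinates() + t * axis.direction)
        c0 = pose.positional_coordinate(base, axis)
        c1 = pose.positional_coordinate(shifted, axis)
        assert c1 - c0 == pytest.approx(t, abs=1e-9)


class TestGreedyMatch:
    def test_identity_pose_matches_fully(self):
        ref = synth.gen_reference_ligand(seed=0)
        p = xyz_to_pose(ref.coordinates())
        metrics = pose.greedy_match_percent(p, ref)
        assert metrics.match_percent == 100.0
        assert len(metrics.matched_pairs) == len(ref.atoms)

    def test_single_reference_atom_serves_nearest_pose_atom_only(self):
        # nearer pose atom takes the only reference atom; the other cannot match
        ref = xyz_to_reference([[0, 0, 0], [50, 0, 0], [100, 0, 0]])
        p = xyz_to_pose([[0.5, 0, 0], [0.9, 0, 0]])
        metrics = pose.greedy_match_percent(p, ref)
        assert metrics.match_percent == 50.0
        assert metrics.matched_pairs == [(0, 0)]

    def test_uniform_translation_beyond_threshold_matches_nothing(self):
        xyz = np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0]], float)
        ref = xyz_to_reference(xyz)
        p = xyz_to_pose(xyz + np.array([2.0, 0, 0]) / np.sqrt(1))
        assert pose.greedy_match_percent(p, ref).match_percent == 0.0

    def test_nonpositive_threshold_rejected(self):
        ref = xyz_to_reference([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            pose.greedy_match_percent(xyz_to_pose([[0, 0, 0]]), ref, threshold=0)

    @given(
        n_pose=st.integers(2, 12),
        n_ref=st.integers(3, 12),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_replay(self, n_pose, n_ref, seed):
        rng = np.random.default_rng(seed)
        pose_xyz = rng.uniform(0, 5, size=(n_pose, 3))
        ref_xyz = rng.uniform(0, 5, size=(n_ref, 3))
        metrics = pose.greedy_match_percent(
            xyz_to_pose(pose_xyz), xyz_to_reference(ref_xyz)
        )
        oracle = greedy_match_oracle(pose_xyz, ref_xyz)
        assert metrics.matched_pairs == oracle
        assert metrics.match_percent == pytest.approx(100 * len(oracle) / n_pose)

    @given(
        n_pose=st.integers(2, 4), n_ref=st.integers(3, 4),
        seed=st.integers(0, 5_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_greedy_never_beats_optimal_matching(self, n_pose, n_ref, seed):
        rng = np.random.default_rng(seed)
        pose_xyz = rng.uniform(0, 2, size=(n_pose, 3))
        ref_xyz = rng.uniform(0, 2, size=(n_ref, 3))
        greedy = len(
            pose.greedy_match_percent(
                xyz_to_pose(pose_xyz), xyz_to_reference(ref_xyz)
            ).matched_pairs
        )
        assert greedy <= optimal_match_count(pose_xyz, ref_xyz)

    def test_match_invariant_to_atom_order(self):
        rng = np.random.default_rng(7)
        pose_xyz = rng.uniform(0, 4, size=(10, 3))
        ref_xyz = rng.uniform(0, 4, size=(12, 3))
        base = pose.greedy_match_percent(
            xyz_to_pose(pose_xyz), xyz_to_reference(ref_xyz)
        ).match_percent
        perm_p = rng.permutation(10)
        perm_r = rng.permutation(12)
        shuffled = pose.greedy_match_percent(
            xyz_to_pose(pose_xyz[perm_p]), xyz_to_reference(ref_xyz[perm_r])
        ).match_percent
        assert shuffled == base


class TestRigidMotionEquivariance:
    def test_rotation_plus_translation_leaves_metrics_unchanged(self):
        ref = synth.gen_reference_ligand(seed=3)
        axis = pose.build_binding_axis(ref)
        p = synth.gen_poses(
            ref, synth.PoseGenConfig(n_poses=1, displacement_along_axis=1.7,
                                     jitter_sd=0.4, seed=9)
        )[0]
        coord = pose.positional_coordinate(p, axis)
        match = pose.greedy_match_percent(p, ref).match_percent

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        shift = np.array([5.0, -2.0, 11.0])

        def transform(xyz):
            return xyz @ rot.T + shift

        ref_t = xyz_to_reference(transform(ref.coordinates()))
        pose_t = xyz_to_pose(transform(p.coordinates()))
        # rebuild the axis from the transformed anchor positions directly
        start = transform(ref.atom("C4A").position[None])[0]
        end = transform(ref.atom("C1").position[None])[0]
        origin = transform(ref.atom("N4A").position[None])[0]
        axis_t = pose.build_binding_axis(
            make_axis_reference(start, end, origin)
        )
        coord_t = pose.positional_coordinate(pose_t, axis_t)
        match_t = pose.greedy_match_percent(pose_t, ref_t).match_percent
        assert coord_t == pytest.approx(coord, abs=1e-6)
        assert match_t == match


class TestSubsites:
    def test_calibration_from_constructed_moieties(self):
        ref = synth.gen_reference_ligand(n_moieties=4, spacing=4.0, seed=0)
        axis = pose.build_binding_axis(ref)
        calibration = pose.calibrate_subsites(ref, axis)
        assert calibration == pytest.approx({-1: -2.0, 1: 2.0, 2: 6.0, 3: 10.0})

    def test_swapped_axis_anchors_flag_orientation(self):
        ref = synth.gen_reference_ligand(seed=0)
        ref.axis_start_name, ref.axis_end_name = (
            ref.axis_end_name, ref.axis_start_name,
        )
        axis = pose.build_binding_axis(ref)
        with pytest.raises(OrientationError):
            pose.calibrate_subsites(ref, axis)

    def test_single_moiety_calibration_has_no_monotonicity_check(self):
        ref = xyz_to_reference([[0, 0, 0], [1, 0, 0], [2, 1, 0], [3, 0, 0]])
        axis = pose.build_binding_axis(ref)
        calibration = pose.calibrate_subsites(ref, axis)
        assert list(calibration) == [-1]

    @pytest.mark.parametrize(
        "coordinate, expected",
        [(3.0, "+1"), (-4.0, "-1"), (-0.5, "-1"), (9.0, "unassigned")],
    )
    def test_assignment_with_donor_side_tie_break(self, coordinate, expected):
        # -0.5 is exactly midway between the two centroids: tie goes to the
        # donor-side subsite; 9.0 is 6 A past +1, beyond max_distance
        calibration = {1: 3.0, -1: -4.0}
        assert pose.assign_subsite(
            coordinate, calibration, max_distance=4.0
        ) == expected


class TestResidueLigandDistance:
    def test_three_four_five_triangle(self, tripeptide_pdb):
        from gtase import structure

        model = structure.read_structure(tripeptide_pdb, dialect="pdb")
        # alanine's only side-chain heavy atom is CB: a 3-4-5 construction
        # from it gives distances 5 and 10; the minimum is 5
        cb = next(
            a for a in model.get_residue("A", 3) if a.name == "CB"
        ).position
        ligand = xyz_to_pose([cb + np.array([30.0, 40.0, 0.0]) / 10.0,
                              cb + np.array([6.0, 8.0, 0.0])]).atoms
        contact = pose.min_residue_ligand_distance(model, "A", 3, ligand)
        assert contact.distance == pytest.approx(5.0)
        assert not contact.used_ca_fallback

    def test_identical_coordinates_give_zero(self, tripeptide_pdb):
        from gtase import structure

        model = structure.read_structure(tripeptide_pdb, dialect="pdb")
        cb = model.get_residue("A", 1)[4].position
        ligand = xyz_to_pose([cb]).atoms
        assert pose.min_residue_ligand_distance(
            model, "A", 1, ligand
        ).distance == pytest.approx(0.0)

    def test_matches_brute_force_over_all_pairs(self, tripeptide_pdb):
        from gtase import structure

        model = structure.read_structure(tripeptide_pdb, dialect="pdb")
        rng = np.random.default_rng(11)
        ligand = xyz_to_pose(rng.uniform(-5, 5, size=(4, 3))).atoms
        side_chain = [
            a for a in model.get_residue("A", 1)
            if a.name not in {"N", "CA", "C", "O", "OXT"}
        ]
        brute = min(
            np.linalg.norm(s.position - l.position)
            for s in side_chain for l in ligand
        )
        contact = pose.min_residue_ligand_distance(model, "A", 1, ligand)
        assert contact.distance == pytest.approx(brute)

    def test_glycine_falls_back_to_ca_with_flag(self, tripeptide_pdb):
        from gtase import structure

        model = structure.read_structure(tripeptide_pdb, dialect="pdb")
        ca = model.get_residue("A", 2)[1].position
        ligand = xyz_to_pose([ca + np.array([1.0, 0, 0])]).atoms
        contact = pose.min_residue_ligand_distance(model, "A", 2, ligand)
        assert contact.used_ca_fallback
        assert contact.distance == pytest.approx(1.0)
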