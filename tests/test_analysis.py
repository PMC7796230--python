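"""Geometry observables, occupancies, clustering, classification and the
free-energy surface, each against an independent oracle where one exists."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from grestlite.analysis import (
    DomainAngles,
    HbondCriteria,
    StateRule,
    center_of_mass,
    classify_states,
    contact_map,
    count_transitions,
    domain_angles,
    free_energy_surface,
    hbond_occupancy,
    hinge_angle,
    identify_salt_bridges,
    kmeans_states,
    radius_of_gyration,
    rmsd,
    superpose,
    twist_angle,
)
from grestlite.constants import KB
from grestlite.errors import ShapeError, ValidationError
from grestlite.structure import Trajectory, make_domains
from grestlite.toy import SyntheticTrajectorySpec, generate_synthetic_trajectory

DOM3 = make_domains(ntd=[(1, 1)], ctd=[(3, 3)], hinge=[(2, 2)])
DOM4 = make_domains(ntd=[(1, 2)], ctd=[(3, 4)], hinge=[(5, 5)],
                    ntd_base=[(1, 1)], ctd_base=[(4, 4)])


class TestCenterOfMass:
    def test_single_atom_is_its_position(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(center_of_mass(x, [0], [7.0]), x[0])

    def test_equal_masses_at_plus_minus_one_give_origin(self):
        x = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert np.allclose(center_of_mass(x, [0, 1], [3.0, 3.0]), 0.0)

    def test_matches_direct_weighted_sum(self, rng):
        x = rng.normal(0, 5, (10, 3))
        m = rng.uniform(1, 20, 10)
        expected = (x * m[:, None]).sum(0) / m.sum()
        assert np.allclose(center_of_mass(x, range(10), m), expected,
                           atol=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError):
            center_of_mass(np.zeros((2, 3)), [], [1.0, 1.0])


class TestHingeAngle:
    def test_collinear_is_180(self):
        frame = np.array([[-3.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]])
        assert hinge_angle(frame, DOM3, np.ones(3)) == pytest.approx(180.0)

    def test_perpendicular_is_90(self):
        frame = np.array([[2.0, 0, 0], [0.0, 0, 0], [0.0, 3.0, 0]])
        assert hinge_angle(frame, DOM3, np.ones(3)) == pytest.approx(90.0)

    def test_matches_arccos_oracle(self, rng):
        frame = rng.normal(0, 4, (3, 3))
        u = frame[0] - frame[1]
        v = frame[2] - frame[1]
        expected = np.degrees(np.arccos(
            np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)))
        assert hinge_angle(frame, DOM3, np.ones(3)) == \
            pytest.approx(expected, abs=1e-9)

    def test_coincident_coms_rejected(self):
        frame = np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValidationError):
            hinge_angle(frame, DOM3, np.ones(3))


class TestTwistAngle:
    def test_planar_cis_is_zero(self):
        frame = np.array([[1.0, 1, 0], [0.0, 0, 0], [3.0, 0, 0],
                          [2.0, 1, 0], [0.0, 0, 9]])
        assert twist_angle(frame, DOM4, np.ones(5)) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_planar_trans_is_180(self):
        frame = np.array([[1.0, 1, 0], [0.0, 0, 0], [3.0, 0, 0],
                          [2.0, -1, 0], [0.0, 0, 9]])
        assert abs(twist_angle(frame, DOM4, np.ones(5))) == \
            pytest.approx(180.0, abs=1e-9)

    def test_matches_atan2_oracle(self, rng):
        frame = rng.normal(0, 4, (5, 3))
        p1, p2, p3, p4 = frame[0], frame[:2].mean(0), frame[2:4].mean(0), \
            frame[3]
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        expected = np.degrees(np.arctan2(
            np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2),
            np.dot(n1, n2)))
        assert twist_angle(frame, DOM4, np.ones(5)) == \
            pytest.approx(expected, abs=1e-9)

    def test_collinear_axis_rejected(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0],
                          [3.0, 0, 0], [9.0, 0, 0]])
        with pytest.raises(ValidationError):
            twist_angle(frame, DOM4, np.ones(5))

    def test_missing_base_regions_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            twist_angle(frame, DOM3, np.ones(3))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_angles_invariant_under_rigid_motion(seed):
    """θ and φ must not change under global rotation plus translation."""
    rng = np.random.default_rng(seed)
    frame = rng.normal(0, 5, (5, 3))
    masses = rng.uniform(1, 10, 5)
    rot = Rotation.random(random_state=np.random.RandomState(seed))
    moved = rot.apply(frame) + rng.normal(0, 20, 3)
    assert hinge_angle(moved, DOM4, masses) == \
        pytest.approx(hinge_angle(frame, DOM4, masses), abs=1e-8)
    assert twist_angle(moved, DOM4, masses) == \
        pytest.approx(twist_angle(frame, DOM4, masses), abs=1e-8)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.array([[3.0, 1, 2]]), [5.0]) == 0.0

    def test_two_unit_masses_two_angstrom_apart(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(frame, [1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self, rng):
        frame = rng.normal(0, 3, (20, 3))
        m = rng.uniform(1, 30, 20)
        com = (frame * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt((m * ((frame - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(frame, m) == pytest.approx(expected,
                                                             abs=1e-12)


class TestRmsd:
    def test_identical_frames_give_zero(self, rng):
        frame = rng.normal(0, 3, (8, 3))
        assert rmsd(frame, frame) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_to_zero(self, rng):
        frame = rng.normal(0, 3, (8, 3))
        rot = Rotation.random(random_state=np.random.RandomState(0))
        moved = rot.apply(frame) + np.array([5.0, -3.0, 11.0])
        assert rmsd(moved, frame, superpose_flag=True) == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_method_oracle(self, rng):
        frame = rng.normal(0, 3, (10, 3))
        ref = rng.normal(0, 3, (10, 3))

        # quaternion (Kearsley) method as the independent oracle
        x = frame - frame.mean(0)
        y = ref - ref.mean(0)
        sm = x.T @ y
        sxx, sxy, sxz = sm[0]
        syx, syy, syz = sm[1]
        szx, szy, szz = sm[2]
        k = np.array([
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
        lam = np.linalg.eigvalsh(k)[-1]
        e0 = (x ** 2).sum() + (y ** 2).sum()
        expected = np.sqrt(max(0.0, e0 - 2 * lam) / 10)
        assert rmsd(frame, ref, superpose_flag=True) == \
            pytest.approx(expected, abs=1e-9)

    def test_superposed_never_exceeds_plain(self, rng):
        for _ in range(5):
            a = rng.normal(0, 3, (7, 3))
            b = rng.normal(0, 3, (7, 3))
            assert rmsd(a, b, superpose_flag=True) <= \
                rmsd(a, b, superpose_flag=False) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestContactMap:
    def test_single_frame_returns_frame_distances(self, toy_system):
        s = toy_system.to_structure("closed")
        traj = Trajectory(coords=s.coords[None], structure=s)
        rids, cmap = contact_map(traj)
        i, j = 0, 5
        expected = np.linalg.norm(s.coords[i] - s.coords[j])
        assert cmap[i, j] == pytest.approx(expected, abs=1e-12)

    def test_matrix_is_symmetric(self, toy_system):
        s = toy_system.to_structure("closed")
        traj = Trajectory(coords=s.coords[None], structure=s)
        _, cmap = contact_map(traj)
        assert np.allclose(cmap, cmap.T, equal_nan=True)

    def test_three_frame_mean(self, toy_system):
        s = toy_system.to_structure("closed")
        frames = np.stack([s.coords, s.coords + 1.0, s.coords * 1.1])
        traj = Trajectory(coords=frames, structure=s)
        _, cmap = contact_map(traj, residue_pairs=[(1, 4)])
        per_frame = [np.linalg.norm(f[0] - f[3]) for f in frames]
        assert cmap[0, 3] == pytest.approx(np.mean(per_frame), abs=1e-12)


class TestSaltBridges:
    def test_no_opposite_charges_gives_empty_list(self):
        cmap = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert identify_salt_bridges(cmap, [1, 2], {1: 1, 2: 1}) == []

    def test_planted_bridge_at_3A_included_and_sorted(self):
        cmap = np.array([[0, 3.0, 8.0], [3.0, 0, 5.0], [8.0, 5.0, 0]])
        charges = {1: 1, 2: -1, 3: -1}
        out = identify_salt_bridges(cmap, [1, 2, 3], charges, 10.0)
        assert out[0] == (1, 2, 3.0)
        assert (1, 3, 8.0) in out

    def test_zero_cutoff_gives_empty_list(self):
        cmap = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert identify_salt_bridges(cmap, [1, 2], {1: 1, 2: -1}, 0.0) == []


class TestHbondOccupancy:
    def make_traj(self, toy_system, n_frames, bridge_frames):
        """Bridge pair sits at 3 Å in ``bridge_frames``, 30 Å otherwise."""
        s = toy_system.to_structure("closed")
        i, j = toy_system.planted["interface_pairs"][0]
        frames = np.repeat(s.coords[None], n_frames, axis=0)
        for f in range(n_frames):
            frames[f, j] = frames[f, i] + \
                ([3.0, 0, 0] if f in bridge_frames else [30.0, 0, 0])
        return Trajectory(coords=frames, structure=s), (i + 1, j + 1)

    def test_always_satisfied_pair_is_100_percent(self, toy_system):
        traj, pair = self.make_traj(toy_system, 10, set(range(10)))
        table = hbond_occupancy(traj, [pair], HbondCriteria(4.0, None),
                                ["X"] * 10)
        assert table.occupancy.iloc[0, 0] == pytest.approx(100.0)

    def test_828_of_1000_frames_is_82_8_percent(self, toy_system):
        traj, pair = self.make_traj(toy_system, 1000, set(range(828)))
        table = hbond_occupancy(traj, [pair], HbondCriteria(4.0, None),
                                ["H_C"] * 1000)
        assert table.occupancy.loc[f"{pair[0]}-{pair[1]}", "H_C"] == \
            pytest.approx(82.8)
        assert table.stderr.iloc[0, 0] >= 0.0

    def test_never_satisfied_pair_is_zero(self, toy_system):
        traj, pair = self.make_traj(toy_system, 10, set())
        table = hbond_occupancy(traj, [pair], HbondCriteria(4.0, None),
                                ["X"] * 10)
        assert table.occupancy.iloc[0, 0] == 0.0

    def test_state_with_zero_frames_is_flagged(self, toy_system):
        traj, pair = self.make_traj(toy_system, 4, {0})
        labels = ["A", "A", "A", "A"]
        table = hbond_occupancy(traj, [pair], HbondCriteria(4.0, None),
                                labels)
        assert table.empty_states == ()
        # an explicitly requested-but-absent state can only arise from the
        # labels themselves, so all listed states have frames here
        assert not np.isnan(table.occupancy.to_numpy()).any()


class TestKmeansStates:
    def test_k1_center_is_mean_structure(self, toy_system):
        traj = generate_synthetic_trajectory(
            toy_system, SyntheticTrajectorySpec(("closed",) * 6, 0.1, 3))
        res = kmeans_states(traj, 1, seed=0)
        aligned = np.array([superpose(f, traj.coords[0])
                            for f in traj.coords])
        assert np.allclose(res.centers[0], aligned.mean(0), atol=1e-8)
        assert res.populations[0] == 1.0

    def test_planted_four_states_recovered(self, toy_system):
        rng = np.random.default_rng(12)
        states = ("closed", "open", "intermediate", "twisted")
        labels = tuple(states[i] for i in rng.integers(0, 4, 400))
        traj = generate_synthetic_trajectory(
            toy_system, SyntheticTrajectorySpec(labels, sigma=0.2, seed=5))
        res = kmeans_states(traj, 4, seed=0)
        truth = np.array([states.index(lbl) for lbl in labels])
        agree = 0
        for c in range(4):
            members = truth[res.labels == c]
            if members.size:
                agree += np.bincount(members).max()
        assert agree / len(labels) >= 0.99

    def test_duplicate_frames_share_a_label(self, toy_system):
        traj = generate_synthetic_trajectory(
            toy_system, SyntheticTrajectorySpec(
                ("closed", "closed", "open", "open"), 0.0, 0))
        res = kmeans_states(traj, 2, seed=0)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]

    def test_k_larger_than_frames_rejected(self, toy_system):
        traj = generate_synthetic_trajectory(
            toy_system, SyntheticTrajectorySpec(("closed",) * 3, 0.0, 0))
        with pytest.raises(ValidationError):
            kmeans_states(traj, 5)


class TestClassifyStates:
    RULES = [StateRule("excluded", theta_gt=146.0),
             StateRule("A_T", phi_lt=58.0)]

    def classify_one(self, theta, phi):
        angles = DomainAngles(theta=np.array([theta]), phi=np.array([phi]),
                              rg=np.array([0.0]))
        return classify_states(angles, self.RULES)[0]

    def test_twist_below_58_is_twisted_state(self):
        assert self.classify_one(100.0, 57.0) == "A_T"

    def test_large_hinge_angle_is_excluded_first(self):
        assert self.classify_one(150.0, 30.0) == "excluded"

    def test_boundary_is_strict(self):
        assert self.classify_one(100.0, 58.0) == "unassigned"
        assert self.classify_one(146.0, 58.0) == "unassigned"


class TestFreeEnergySurface:
    def test_uniform_two_bins_both_zero(self):
        theta = np.array([1.0] * 50 + [3.0] * 50)
        phi = np.zeros(100)
        fes = free_energy_surface(theta, phi, 300.0, 2.0)
        populated = fes.free_energy[np.isfinite(fes.free_energy)]
        assert np.allclose(populated, 0.0, atol=1e-12)

    def test_two_bin_count_ratio_closed_form(self):
        n1, n2 = 2718, 1000
        theta = np.array([1.0] * n1 + [3.0] * n2)
        phi = np.zeros(n1 + n2)
        fes = free_energy_surface(theta, phi, 300.0, 2.0)
        populated = np.sort(fes.free_energy[np.isfinite(fes.free_energy)])
        expected = -KB * 300.0 * np.log(n2 / n1)
        assert populated[0] == pytest.approx(0.0, abs=1e-12)
        assert populated[1] == pytest.approx(expected, abs=1e-9)

    def test_minimum_over_populated_bins_is_zero(self, toy_system):
        traj = generate_synthetic_trajectory(
            toy_system, SyntheticTrajectorySpec(
                ("closed", "open", "twisted") * 30, 0.3, 2))
        ang = domain_angles(traj, toy_system.domains)
        fes = free_energy_surface(ang.theta, ang.phi)
        assert np.nanmin(fes.free_energy) == pytest.approx(0.0, abs=1e-12)
        assert fes.mask.any()

    def test_invariant_to_duplicating_the_series(self):
        theta = np.array([1.0, 1.0, 3.0])
        phi = np.array([1.0, 1.0, 1.0])
        a = free_energy_surface(theta, phi, 300.0, 2.0)
        b = free_energy_surface(np.tile(theta, 3), np.tile(phi, 3),
                                300.0, 2.0)
        assert np.allclose(a.free_energy, b.free_energy, equal_nan=True)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            free_energy_surface(np.array([]), np.array([]))


class TestCountTransitions:
    def test_hysteresis_ignores_mid_band_noise(self):
        series = [0, 0.4, 0.6, 0.4, 1.0, 0.5, 0.0, 1.0]
        assert count_transitions(series, 0.25, 0.75) == 3

    def test_no_transition_within_one_basin(self):
        assert count_transitions([0, 0.1, 0.2, 0.1], 0.25, 0.75) == 0

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            count_transitions([0.0], 0.8, 0.2)
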