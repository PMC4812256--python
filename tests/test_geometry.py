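"""Superposition, COM clouds, distance distributions and dihedrals."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from allocross.core import Selection, Trajectory, select
from allocross.geometry import (
    COMCloud,
    apply_transform,
    circular_mean,
    com,
    com_cloud,
    dihedral,
    dihedral_series,
    distance_from_start,
    kabsch_fit,
    pair_distance_distribution,
    residue_pair_distance_series,
    rmsd_series,
)
from allocross.core import Atom, Frame, Topology

from conftest import random_rigid_motion, static_trajectory, two_state_simulation
from oracles import dihedral_cross_oracle, grid_rmsd_oracle


class TestKabsch:
    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(0)
        P = rng.standard_normal((12, 3))
        R_true = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        t_true = np.array([1.0, -2.0, 0.5])
        Q = P @ R_true.T + t_true
        R, t, rmsd = kabsch_fit(P, Q)
        assert rmsd < 1e-10
        np.testing.assert_allclose(R, R_true, atol=1e-10)
        np.testing.assert_allclose(apply_transform(P, R, t), Q, atol=1e-10)

    def test_translation_only(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        Q = P + np.array([2.0, 3.0, -1.0])
        R, t, rmsd = kabsch_fit(P, Q)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, [2.0, 3.0, -1.0], atol=1e-12)
        assert rmsd < 1e-12

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(1)
        P = rng.standard_normal((6, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]  # reflection
        R, _, _ = kabsch_fit(P, Q)
        assert np.linalg.det(R) > 0.99

    def test_degenerate_sets_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_fit(line, line + 1.0)
        point = np.zeros((4, 3))
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_fit(point, point)

    def test_agrees_with_rotation_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            P = rng.standard_normal((4, 3))
            Q = P.copy()
            Q[rng.integers(0, 4)] += rng.standard_normal(3) * 0.3
            _, _, rmsd = kabsch_fit(P, Q)
            assert abs(rmsd - grid_rmsd_oracle(P, Q)) <= 1e-3


def _two_atom_topology(masses=(1.0, 1.0)):
    return Topology(
        [Atom("A", "C", masses[0], 1, "X"), Atom("B", "C", masses[1], 2, "X")]
    )


class TestCOM:
    def test_equal_mass_midpoint(self):
        top = _two_atom_topology()
        frame = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        sel = Selection(np.array([0, 1]))
        np.testing.assert_allclose(com(frame, sel, top), [1.0, 0.0, 0.0])

    def test_mass_weighted_mean(self):
        top = _two_atom_topology((1.0, 3.0))
        frame = Frame(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        sel = Selection(np.array([0, 1]))
        np.testing.assert_allclose(com(frame, sel, top), [3.0, 0.0, 0.0])

    def test_geometric_vs_mass_weighting(self):
        top = _two_atom_topology((1.0, 3.0))
        frame = Frame(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        sel = Selection(np.array([0, 1]))
        geo = com(frame, sel, top, weighting="geometric")
        np.testing.assert_allclose(geo, [2.0, 0.0, 0.0])  # differs by 1 nm in x
        assert com(frame, sel, top)[0] - geo[0] == pytest.approx(1.0)

    def test_empty_selection_errors(self):
        top = _two_atom_topology()
        with pytest.raises(ValueError, match="empty"):
            com(Frame(np.zeros((2, 3))), Selection(np.array([], dtype=int)), top)


def _cloud_selections(structure):
    fit = select(structure.topology, structure.arch.core_range, {"CA"})
    mob = select(structure.topology, structure.arch.appended_range, "all")
    return fit, mob


class TestCOMCloud:
    def test_static_trajectory_gives_reference_point(self, ca_structure):
        traj = static_trajectory(ca_structure, 10)
        fit, mob = _cloud_selections(ca_structure)
        cloud = com_cloud([traj], fit, mob, (ca_structure.topology, ca_structure.frame))
        assert np.abs(cloud.points - cloud.reference).max() < 1e-10

    def test_two_state_centroid_separation(self, ca_structure):
        sim = two_state_simulation(ca_structure, weights=(0.5, 0.5), n_frames=400, seed=2)
        fit, mob = _cloud_selections(ca_structure)
        cloud = com_cloud(
            [sim.trajectory], fit, mob, (ca_structure.topology, ca_structure.frame)
        )
        c0 = cloud.points[sim.states == 0].mean(axis=0)
        c1 = cloud.points[sim.states == 1].mean(axis=0)
        sep = np.linalg.norm(c0 - c1) * 10.0
        assert abs(sep - 20.0) <= 1.0  # planted 2 nm offset

    def test_invariant_under_global_rigid_motion(self, ca_structure):
        traj = static_trajectory(ca_structure, 5, sigma=0.03, seed=7)
        rng = np.random.default_rng(3)
        moved = traj.xyz.copy()
        for f in range(traj.n_frames):
            Q, t = random_rigid_motion(rng)
            moved[f] = traj.xyz[f] @ Q.T + t
        traj2 = Trajectory(traj.topology, moved, traj.times)
        fit, mob = _cloud_selections(ca_structure)
        ref = (ca_structure.topology, ca_structure.frame)
        a = com_cloud([traj], fit, mob, ref)
        b = com_cloud([traj2], fit, mob, ref)
        assert np.abs(a.points - b.points).max() < 1e-6

    def test_empty_runs_error(self, ca_structure):
        fit, mob = _cloud_selections(ca_structure)
        with pytest.raises(ValueError, match="empty|no runs"):
            com_cloud([], fit, mob, (ca_structure.topology, ca_structure.frame))


class TestDistanceDistributions:
    def test_identity_cloud_all_mass_at_zero(self):
        pts = np.zeros((50, 3))
        cloud = COMCloud(pts, np.zeros(3))
        dist = distance_from_start(cloud)
        assert dist.mean == 0.0
        assert dist.peak == 0.0
        assert dist.counts[0] == 50

    def test_single_state_planted_offset(self, ca_structure):
        sim = two_state_simulation(
            ca_structure, weights=(0.0, 1.0), offset_nm=1.5, n_frames=100,
            seed=1, domain_sigma=0.001, linker_sigma=0.001,
        )
        fit, mob = _cloud_selections(ca_structure)
        cloud = com_cloud(
            [sim.trajectory], fit, mob, (ca_structure.topology, ca_structure.frame)
        )
        dist = distance_from_start(cloud)
        assert abs(dist.mean - 15.0) <= 0.5

    def test_mixture_mean_is_weighted_average(self, ca_structure):
        sim = two_state_simulation(
            ca_structure, weights=(0.5, 0.5), offset_nm=2.0, n_frames=1000,
            seed=4, domain_sigma=0.001, linker_sigma=0.001,
        )
        fit, mob = _cloud_selections(ca_structure)
        cloud = com_cloud(
            [sim.trajectory], fit, mob, (ca_structure.topology, ca_structure.frame)
        )
        dist = distance_from_start(cloud)
        se = 10.0 * np.sqrt(0.25 / 1000)  # binomial error on the 0/20 Å mix
        assert abs(dist.mean - 10.0) <= 3 * se + 0.2

    def test_equilateral_pair_distances(self):
        pts = np.array(
            [[0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]]
        )  # 1 nm sides = 10 Å
        cloud = COMCloud(pts, np.zeros(3))
        dist = pair_distance_distribution(cloud)
        assert dist.counts.sum() == 3
        assert dist.peak == 10.0

    def test_two_blob_peak_follows_pair_counting(self):
        # p² + (1−p)² vs 2p(1−p) decides whether the within-blob (0 Å) or
        # between-blob (20 Å) mode dominates; verify against brute force.
        rng = np.random.default_rng(0)
        for p, expected_peak in [(0.7, 0.0), (0.5, 20.0)]:
            n = 200
            k = int(round(p * n))
            pts = np.zeros((n, 3))
            pts[k:, 0] = 2.0  # 20 Å apart
            pts += rng.standard_normal((n, 3)) * 0.01
            cloud = COMCloud(pts, np.zeros(3))
            dist = pair_distance_distribution(cloud)
            assert dist.peak == expected_peak
            # brute-force enumeration agrees with the histogram total
            assert dist.counts.sum() == n * (n - 1) // 2
            brute = pdist(pts) * 10.0
            within = (brute < 10.0).sum()
            between = (brute >= 10.0).sum()
            assert (within > between) == (expected_peak == 0.0)

    def test_modes_reports_secondary_blob(self):
        pts = np.zeros((100, 3))
        pts[70:, 0] = 2.0
        cloud = COMCloud(pts, np.zeros(3))
        modes = pair_distance_distribution(cloud).modes(min_separation=5.0)
        assert modes[0] == 0.0 and modes[1] == 20.0


class TestResiduePairDistance:
    def test_static_distance_matches_hand_measurement(self, ca_structure):
        traj = static_trajectory(ca_structure, 5)
        top = ca_structure.topology
        i, j = 3, 10
        expected = (
            np.linalg.norm(
                ca_structure.frame.coords[top.ca_index(i)]
                - ca_structure.frame.coords[top.ca_index(j)]
            )
            * 10.0
        )
        series, avg = residue_pair_distance_series(traj, i, j)
        assert np.allclose(series, expected)
        assert avg == pytest.approx(float(np.mean(series)))

    def test_ca_vs_closest_heavy_rules(self):
        # residue 1: CA at origin, O at (0.1, 0, 0); residue 2: CA at (1, 0, 0)
        top = Topology(
            [
                Atom("CA", "C", 12.0, 1, "X"),
                Atom("O", "O", 16.0, 1, "X"),
                Atom("CA", "C", 12.0, 2, "X"),
            ]
        )
        xyz = np.array([[[0.0, 0, 0], [0.1, 0, 0], [1.0, 0, 0]]])
        traj = Trajectory(top, xyz)
        _, ca_avg = residue_pair_distance_series(traj, 1, 2, "ca")
        _, heavy_avg = residue_pair_distance_series(traj, 1, 2, "closest-heavy")
        assert ca_avg == pytest.approx(10.0)
        assert heavy_avg == pytest.approx(9.0)  # O is 0.1 nm closer


class TestDihedrals:
    def test_planar_trans_is_180(self):
        p = [np.array([0.0, 1, 0]), np.zeros(3), np.array([1.0, 0, 0]), np.array([1.0, -1, 0])]
        assert dihedral(*p) == pytest.approx(180.0)

    def test_ninety_degree_twist_sign(self):
        p0 = np.array([0.0, 1, 0])
        p1 = np.zeros(3)
        p2 = np.array([1.0, 0, 0])
        p3 = np.array([1.0, 0, 1.0])
        ang = dihedral(p0, p1, p2, p3)
        assert ang == pytest.approx(dihedral_cross_oracle(p0, p1, p2, p3), abs=1e-9)
        assert abs(ang) == pytest.approx(90.0)

    def test_agrees_with_cross_product_oracle_on_random_quads(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.standard_normal((4, 3))
            ours = dihedral(*pts)
            theirs = dihedral_cross_oracle(*pts)
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_collinear_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="collinear"):
            ang = dihedral(
                np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]),
                np.array([3.0, 1, 0]),
            )
        assert np.isnan(ang)

    def test_circular_mean_wraps(self):
        mean, _ = circular_mean(np.array([170.0, -170.0]))
        assert mean == pytest.approx(180.0)

    def test_circular_mean_recovers_wrapped_normal_location(self):
        rng = np.random.default_rng(11)
        loc, sigma, n = 150.0, 20.0, 2000
        sample = ((rng.normal(loc, sigma, n) + 180) % 360) - 180
        mean, _ = circular_mean(sample)
        delta = (mean - loc + 180) % 360 - 180
        assert abs(delta) <= 3 * sigma / np.sqrt(n)

    def test_dihedral_series_over_trajectory(self, bb_structure):
        traj = static_trajectory(bb_structure, 4)
        top = bb_structure.topology
        quad = [top.residue_atoms(5)[0], top.ca_index(5), top.residue_atoms(5)[2],
                top.residue_atoms(6)[0]]
        series = dihedral_series(traj, quad)
        assert len(series) == 4
        assert np.allclose(series.angles, series.angles[0])
        assert series.circ_variance == pytest.approx(0.0, abs=1e-12)


class TestRMSDSeries:
    def test_identity_and_rotated_copies_are_zero(self, ca_structure):
        traj = static_trajectory(ca_structure, 5)
        sel = select(ca_structure.topology, ca_structure.arch.core_range, {"CA"})
        series = rmsd_series(traj, ca_structure.frame, sel)
        assert np.abs(series).max() < 1e-9
        rng = np.random.default_rng(8)
        Q, t = random_rigid_motion(rng)
        rotated = Trajectory(
            traj.topology, traj.xyz @ Q.T + t, traj.times
        )
        series = rmsd_series(rotated, ca_structure.frame, sel)
        assert np.abs(series).max() < 1e-6

    def test_perturbed_frame_matches_grid_oracle(self):
        rng = np.random.default_rng(13)
        top = Topology([Atom("CA", "C", 12.0, i + 1, "X") for i in range(4)])
        base = rng.standard_normal((4, 3))
        pert = base.copy()
        pert[2] += rng.standard_normal(3) * 0.2
        traj = Trajectory(top, pert[np.newaxis])
        sel = Selection(np.arange(4))
        series = rmsd_series(traj, Frame(base), sel)
        assert abs(series[0] - grid_rmsd_oracle(pert, base)) <= 1e-3

    def test_pairwise_mode_requires_matched_lengths(self, ca_structure):
        a = static_trajectory(ca_structure, 5)
        b = static_trajectory(ca_structure, 6)
        sel = select(ca_structure.topology, ca_structure.arch.core_range, {"CA"})
        with pytest.raises(ValueError, match="matched"):
            rmsd_series(a, b, sel)
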