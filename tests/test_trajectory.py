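"""Trajectory metrics against closed forms, oracles, and rigid-motion invariance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mstnpop import (Trajectory, concat_fitted, fel, hbond_count,
                     kabsch_superpose, pca, radius_of_gyration, rmsd_series,
                     rmsf, sasa)
from mstnpop.simulate import (TrajectorySpec, default_atom_table,
                              simulate_trajectory)
from mstnpop.trajectory import PCAResult, read_trajectory


def make_traj(coords, atoms=None):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(coords, atoms if atoms is not None
                      else default_atom_table(coords.shape[1]))


def random_structure(rng, n):
    return rng.normal(size=(n, 3))


class TestKabsch:
    def test_identical_structures(self):
        rng = np.random.default_rng(0)
        x = random_structure(rng, 8)
        assert kabsch_superpose(x, x)[2] == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_removed(self):
        rng = np.random.default_rng(1)
        x = random_structure(rng, 8)
        assert kabsch_superpose(x + [1.0, -2.0, 0.5], x)[2] == pytest.approx(0.0, abs=1e-12)

    def test_pure_rotation_removed(self):
        rng = np.random.default_rng(2)
        x = random_structure(rng, 8)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        assert kabsch_superpose(x @ rot.T, x)[2] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_matches_rotation_space_minimization(self):
        # independent oracle: coarse rotation grid + local refinement
        rng = np.random.default_rng(3)
        mobile = random_structure(rng, 10)
        reference = random_structure(rng, 10)
        _, _, rmsd = kabsch_superpose(mobile, reference)

        a = mobile - mobile.mean(axis=0)
        b = reference - reference.mean(axis=0)

        def cost(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            return math.sqrt((((a @ r.T) - b) ** 2).sum(axis=1).mean())

        best = math.inf
        grid = np.linspace(-math.pi, math.pi, 7)
        for vx in grid:
            for vy in grid:
                for vz in grid:
                    res = minimize(cost, [vx, vy, vz], method="Nelder-Mead",
                                   options={"xatol": 1e-6, "fatol": 1e-12})
                    best = min(best, res.fun)
        assert rmsd == pytest.approx(best, abs=1e-3)


class TestRMSD:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(4)
        x = random_structure(rng, 6)
        series = rmsd_series(make_traj(np.repeat(x[None], 5, axis=0)))
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_reference_frame_scores_zero(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(4, 6, 3))
        series = rmsd_series(make_traj(coords), reference_frame=2)
        assert series.values[2] == pytest.approx(0.0, abs=1e-12)

    def test_two_state_trajectory_has_known_plateaus(self):
        rng = np.random.default_rng(6)
        x = random_structure(rng, 8)
        y = x + rng.normal(scale=0.3, size=x.shape)
        plateau = kabsch_superpose(y, x)[2]
        coords = np.stack([x, x, x, y, y, y])
        series = rmsd_series(make_traj(coords))
        assert np.allclose(series.values[:3], 0.0, atol=1e-12)
        assert np.allclose(series.values[3:], plateau, atol=1e-12)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(7)
        x = random_structure(rng, 5)
        assert np.allclose(rmsf(make_traj(np.repeat(x[None], 4, axis=0))), 0.0)

    def test_single_oscillating_atom_closed_form(self):
        # atom 0 moves +-a along x around its mean; no fitting
        a = 0.25
        n_frames = 16
        base = np.zeros((3, 3))
        base[1] = [1.0, 0.0, 0.0]
        base[2] = [0.0, 1.0, 0.0]
        coords = np.repeat(base[None], n_frames, axis=0)
        phases = np.sin(2 * np.pi * np.arange(n_frames) / n_frames)
        coords[:, 0, 0] += a * phases
        vals = rmsf(make_traj(coords), selection="all", fit=False)
        assert vals[0] == pytest.approx(a / math.sqrt(2), abs=1e-12)
        assert np.allclose(vals[1:], 0.0, atol=1e-12)

    def test_harmonic_mode_amplitude_proportionality(self):
        rng = np.random.default_rng(8)
        pattern = np.zeros((6, 3))
        pattern[2, 1] = 1.0
        base = random_structure(rng, 6) * 5.0
        out = []
        for amp in (0.1, 0.2):
            spec = TrajectorySpec(n_atoms=6, n_frames=32,
                                  mode_amplitudes=[amp],
                                  mode_displacements=[pattern], seed=9)
            traj = simulate_trajectory(spec, base=base)
            out.append(rmsf(traj, selection="all", fit=False)[2])
        assert out[0] == pytest.approx(0.1 / math.sqrt(2), abs=1e-12)
        assert out[1] / out[0] == pytest.approx(2.0, abs=1e-9)

    def test_single_frame_returns_zeros(self):
        vals = rmsf(make_traj(np.zeros((1, 4, 3))), selection="all", fit=False)
        assert np.allclose(vals, 0.0)


class TestRg:
    def test_two_point_dumbbell(self):
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        assert radius_of_gyration(make_traj(coords)).values[0] == pytest.approx(1.0)

    def test_coincident_atoms(self):
        coords = np.zeros((2, 5, 3))
        assert np.allclose(radius_of_gyration(make_traj(coords)).values, 0.0)

    def test_uniform_ring(self):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        ring = np.stack([3.0 * np.cos(theta), 3.0 * np.sin(theta),
                         np.zeros_like(theta)], axis=1)
        assert radius_of_gyration(make_traj(ring[None])).values[0] == pytest.approx(3.0)


class TestSASA:
    def test_isolated_atom_is_a_sphere(self):
        atoms = default_atom_table(1)
        t = make_traj(np.zeros((1, 1, 3)), atoms)
        r = 0.15 + 0.14
        expected = 4 * math.pi * r ** 2
        assert sasa(t).values[0] == pytest.approx(expected, rel=0.01)

    def test_fully_overlapping_atoms_count_once(self):
        # two identical spheres with near-coincident centers: each sphere is
        # half-buried in the other, so the total equals one sphere's area
        atoms = default_atom_table(2)
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 1e-6
        one = sasa(make_traj(np.zeros((1, 1, 3)), default_atom_table(1))).values[0]
        assert sasa(make_traj(coords, atoms)).values[0] == pytest.approx(one, rel=0.02)

    def test_distant_atoms_are_additive(self):
        atoms = default_atom_table(2)
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 5.0
        one = sasa(make_traj(np.zeros((1, 1, 3)), default_atom_table(1))).values[0]
        assert sasa(make_traj(coords, atoms)).values[0] == pytest.approx(2 * one, rel=1e-9)

    def test_point_count_refines_the_estimate(self):
        rng = np.random.default_rng(12)
        atoms = default_atom_table(5)
        t = make_traj(rng.normal(scale=0.2, size=(1, 5, 3)), atoms)
        vals = [sasa(t, n_points=n).values[0] for n in (240, 960, 3840)]
        assert abs(vals[2] - vals[1]) <= abs(vals[2] - vals[0]) + 1e-9


def hbond_atoms():
    atoms = default_atom_table(3)
    atoms.loc[0, "donor"] = True
    atoms.loc[1, "hydrogen"] = True
    atoms.loc[1, "parent"] = 0
    atoms.loc[2, "acceptor"] = True
    return atoms


class TestHbonds:
    def place(self, d_da, angle_deg):
        coords = np.zeros((1, 3, 3))
        coords[0, 1] = [0.1, 0.0, 0.0]   # hydrogen along +x from donor
        ang = math.radians(angle_deg)
        coords[0, 2] = [d_da * math.cos(ang), d_da * math.sin(ang), 0.0]
        return make_traj(coords, hbond_atoms())

    def test_collinear_bond_counts(self):
        assert hbond_count(self.place(0.30, 0.0)).values[0] == 1

    def test_distance_cutoff(self):
        assert hbond_count(self.place(0.40, 0.0)).values[0] == 0

    def test_angle_cutoff(self):
        assert hbond_count(self.place(0.30, 45.0)).values[0] == 0

    def test_base_pairing_filter_excludes_unflagged(self):
        t = self.place(0.30, 0.0)
        assert hbond_count(t, pair_filter="base_pairing").values[0] == 0
        t.atoms.loc[:, "base_pairing"] = True
        assert hbond_count(t, pair_filter="base_pairing").values[0] == 1

    def test_no_triples_warns_and_returns_zeros(self):
        t = make_traj(np.zeros((2, 3, 3)))
        assert np.allclose(hbond_count(t).values, 0.0)


class TestPCA:
    def test_single_direction_of_motion(self):
        spec = TrajectorySpec(n_atoms=5, n_frames=24, mode_amplitudes=[0.5],
                              mode_displacements=[np.eye(5, 3)], seed=1)
        traj = simulate_trajectory(spec)
        res = pca(traj, selection="all", fit=False)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_sum_to_total_variance(self):
        rng = np.random.default_rng(13)
        coords = rng.normal(size=(20, 4, 3))
        res = pca(make_traj(coords), selection="all", fit=False)
        x = coords.reshape(20, -1)
        x = x - x.mean(axis=0)
        total = (x ** 2).sum() / 19
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert np.allclose(res.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_isotropic_noise_spreads_variance(self):
        spec = TrajectorySpec(n_atoms=6, n_frames=400, noise_sd=0.1, seed=2)
        res = pca(simulate_trajectory(spec), selection="all", fit=False)
        # sample eigenvalues of iid noise stay inside the Marchenko-Pastur
        # support [(1-sqrt(g))^2, (1+sqrt(g))^2] * var, g = dim/frames = 0.045
        var = 0.1 ** 2
        g = math.sqrt(18 / 400)
        assert res.eigenvalues.max() < (1 + g) ** 2 * var * 1.1
        assert res.eigenvalues.min() > (1 - g) ** 2 * var * 0.9

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            pca(make_traj(np.zeros((1, 4, 3))))


class TestFEL:
    @staticmethod
    def from_projections(xy):
        xy = np.asarray(xy, dtype=float)
        return PCAResult(mean_structure=np.zeros((1, 3)),
                         eigenvectors=np.eye(2), eigenvalues=np.ones(2),
                         projections=xy, variance_fractions=np.full(2, 0.5))

    def test_single_bin_is_zero_energy(self):
        grid = fel(self.from_projections(np.zeros((10, 2))), bins=4)
        finite = grid.free_energy[np.isfinite(grid.free_energy)]
        assert finite.tolist() == [0.0]

    def test_modal_bin_zero_and_all_finite_nonnegative(self):
        rng = np.random.default_rng(14)
        grid = fel(self.from_projections(rng.normal(size=(500, 2))), bins=8)
        finite = grid.free_energy[np.isfinite(grid.free_energy)]
        assert finite.min() == pytest.approx(0.0)
        assert (finite >= 0.0).all()

    def test_count_ratio_e_gives_one_kt(self):
        n = 271  # ~ e * 100
        xy = np.array([[0.25, 0.25]] * n + [[0.75, 0.75]] * 100)
        grid = fel(self.from_projections(xy), bins=2)
        finite = np.sort(grid.free_energy[np.isfinite(grid.free_energy)])
        assert finite[0] == 0.0
        assert finite[1] == pytest.approx(math.log(n / 100), abs=1e-12)


class TestRigidMotionInvariance:
    def test_all_metrics_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(15)
        atoms = hbond_atoms()
        coords = rng.normal(scale=0.3, size=(5, 3, 3))
        t1 = make_traj(coords, atoms)
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        shift = rng.normal(size=3)
        t2 = make_traj(coords @ rot.T + shift, atoms.copy())
        assert np.allclose(rmsd_series(t1, selection="all").values,
                           rmsd_series(t2, selection="all").values, atol=1e-9)
        assert np.allclose(radius_of_gyration(t1).values,
                           radius_of_gyration(t2).values, atol=1e-9)
        # SASA is rotation invariant only up to sphere-point quadrature error
        assert np.allclose(sasa(t1).values, sasa(t2).values, rtol=0.02)
        assert np.allclose(hbond_count(t1).values, hbond_count(t2).values)
        assert np.allclose(rmsf(t1, selection="all"),
                           rmsf(t2, selection="all"), atol=1e-9)


class TestConcat:
    def test_self_concat_doubles_frames_with_provenance(self):
        rng = np.random.default_rng(16)
        t = make_traj(rng.normal(size=(4, 5, 3)))
        ref = t.coords[0][t.selection("backbone")]
        out = concat_fitted([t, t], ref)
        assert out.n_frames == 8
        assert out.frame_labels == ["traj0"] * 4 + ["traj1"] * 4

    def test_pre_rotated_copy_aligns_to_reference(self):
        rng = np.random.default_rng(17)
        coords = rng.normal(size=(3, 6, 3))
        rot = Rotation.from_rotvec([0.2, 0.4, -0.3]).as_matrix()
        t1 = make_traj(coords)
        t2 = make_traj(coords @ rot.T + [1.0, 2.0, 3.0])
        ref = coords[0]
        out = concat_fitted([t1, t2], ref, selection="all")
        assert np.allclose(out.coords[0], out.coords[3], atol=1e-9)

    def test_atom_count_mismatch_rejected(self):
        rng = np.random.default_rng(19)
        t1 = make_traj(rng.normal(size=(2, 4, 3)))
        t2 = make_traj(rng.normal(size=(2, 5, 3)))
        with pytest.raises(ValueError, match="atom counts"):
            concat_fitted([t1, t2], t1.coords[0], selection="all")


class TestIO:
    def test_round_trip_through_plain_text(self, tmp_path):
        rng = np.random.default_rng(18)
        coords = rng.normal(size=(3, 4, 3))
        rows = []
        for f in range(3):
            for a in range(4):
                rows.append({"frame": f, "atom": a, "x": coords[f, a, 0],
                             "y": coords[f, a, 1], "z": coords[f, a, 2]})
        pd.DataFrame(rows).to_csv(tmp_path / "coords.csv", index=False)
        default_atom_table(4).to_csv(tmp_path / "atoms.csv", index=False)
        t = read_trajectory(tmp_path / "coords.csv", tmp_path / "atoms.csv")
        assert t.n_frames == 3 and t.n_atoms == 4
        assert np.allclose(t.coords, coords)
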