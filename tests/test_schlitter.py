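"""Schlitter entropy: covariance construction, closed form, splits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from linkerthermo import synthetic as syn
from linkerthermo import units
from linkerthermo.errors import NumericalError, StructuralError
from linkerthermo.schlitter import (CovarianceModel, EntropyReport,
                                    build_covariance, entropy_from_eigenvalues,
                                    replicate_summary, rigid_body_generators,
                                    schlitter_entropy, split_conformational)
from linkerthermo.trajectory import TrajectoryFrames
from conftest import oracle_schlitter_minus_ts, rotation_matrix


def _cov_model(matrix, masses, coords=None):
    n = len(masses)
    coords = np.zeros((n, 3)) if coords is None else coords
    return CovarianceModel(matrix=matrix, masses=np.asarray(masses, float),
                           mean_coordinates=coords, n_frames_used=1000)


class TestBuildCovariance:
    def test_static_trajectory_zero_matrix(self, small_trajectory):
        coords = np.repeat(small_trajectory.coordinates[:1], 5, axis=0)
        static = TrajectoryFrames(coordinates=coords,
                                  times=np.arange(5, dtype=float),
                                  topology=small_trajectory.topology)
        cm = build_covariance(static, start_time_ps=0.0)
        assert np.abs(cm.matrix).max() < 1e-24  # zero up to mean roundoff

    def test_single_coordinate_variance(self):
        # 1 particle jittering in x: C_xx ~ m * s^2
        rng = np.random.default_rng(5)
        s = 0.02
        n = 4000
        coords = np.zeros((n, 1, 3))
        coords[:, 0, 0] = s * rng.standard_normal(n)
        ens = syn.gaussian_ensemble(np.zeros((3, 3)), 12.0, 2, seed=1)
        traj = TrajectoryFrames(coordinates=coords,
                                times=np.arange(n, dtype=float),
                                topology=ens.frames.topology)
        cm = build_covariance(traj, start_time_ps=0.0)
        se = 12.0 * s ** 2 * math.sqrt(2.0 / n)
        assert cm.matrix[0, 0] == pytest.approx(12.0 * s ** 2, abs=2 * se)

    def test_correlated_atoms_off_diagonal(self):
        # two atoms moving identically: off-diagonal block equals the
        # geometric mean of the diagonals
        rng = np.random.default_rng(6)
        n = 500
        x = 0.03 * rng.standard_normal(n)
        coords = np.zeros((n, 2, 3))
        coords[:, 0, 0] = x
        coords[:, 1, 0] = x
        topo = syn._generic_topology(2, [12.0, 48.0])
        traj = TrajectoryFrames(coordinates=coords,
                                times=np.arange(n, dtype=float), topology=topo)
        cm = build_covariance(traj, start_time_ps=0.0, check_drift=False)
        expected = math.sqrt(cm.matrix[0, 0] * cm.matrix[3, 3])
        assert cm.matrix[0, 3] == pytest.approx(expected, rel=1e-10)

    def test_start_time_discard(self, small_trajectory):
        cm = build_covariance(small_trajectory, start_time_ps=6.0)
        assert cm.n_frames_used == 6

    def test_too_few_frames(self, small_trajectory):
        with pytest.raises(StructuralError, match=">= 2 frames"):
            build_covariance(small_trajectory, start_time_ps=11.5)

    def test_drift_detection(self, capped_topology):
        n = 40
        coords = np.zeros((n, 8, 3))
        coords += np.linspace(0, 3, n)[:, None, None]  # steady drift
        traj = TrajectoryFrames(coordinates=coords,
                                times=np.arange(n, dtype=float),
                                topology=capped_topology)
        with pytest.raises(NumericalError, match="drift"):
            build_covariance(traj, start_time_ps=0.0)


class TestSchlitterFormula:
    def test_zero_covariance_zero_entropy(self):
        cm = _cov_model(np.zeros((3, 3)), [12.0])
        rep = schlitter_entropy(cm, 300.0, remove_rigid_modes=0)
        assert rep.minus_TS_schlitter == 0.0

    def test_single_mode_closed_form(self):
        # 1D mode, m = 12 amu, sigma^2 = 1e-4 nm^2, T = 300 K
        m, var, t = 12.0, 1e-4, 300.0
        matrix = np.zeros((3, 3))
        matrix[0, 0] = m * var
        rep = schlitter_entropy(_cov_model(matrix, [m]), t, remove_rigid_modes=0)
        oracle = oracle_schlitter_minus_ts(matrix, t)
        assert rep.minus_TS_schlitter == pytest.approx(oracle, rel=1e-10)

    def test_multimode_matches_logdet_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((9, 9)) * 0.05
        cov = a @ a.T
        masses = np.array([12.0, 1.008, 15.999])
        w = np.sqrt(np.repeat(masses, 3))
        mw = cov * np.outer(w, w)
        rep = schlitter_entropy(_cov_model(mw, masses), 300.0,
                                remove_rigid_modes=0)
        assert rep.minus_TS_schlitter == pytest.approx(
            oracle_schlitter_minus_ts(mw, 300.0), rel=1e-10)

    def test_gaussian_ensemble_estimator(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((9, 9)) * 0.02
        cov = a @ a.T + 1e-4 * np.eye(9)
        ens = syn.gaussian_ensemble(cov, 12.0, 100_000, seed=1)
        cm = build_covariance(ens.frames, start_time_ps=0.0)
        rep = schlitter_entropy(cm, 300.0, remove_rigid_modes=0)
        assert rep.minus_TS_schlitter == pytest.approx(
            ens.truth["minus_TS_schlitter"], rel=0.01)

    def test_mode_additivity_for_diagonal_covariance(self):
        lams = np.array([1e-5, 3e-4, 2e-3])
        total = entropy_from_eigenvalues(lams, 300.0)
        parts = sum(entropy_from_eigenvalues(np.array([l]), 300.0) for l in lams)
        assert total == pytest.approx(parts, rel=1e-14)

    @given(scale=st.floats(1.01, 50.0))
    def test_monotonic_in_covariance_scale(self, scale):
        lams = np.array([1e-6, 5e-5, 7e-4])
        assert (entropy_from_eigenvalues(scale * lams, 300.0)
                > entropy_from_eigenvalues(lams, 300.0))

    def test_removing_rigid_modes_never_increases_entropy(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((12, 12)) * 0.03
        masses = np.full(4, 12.0)
        coords = rng.uniform(0, 1, (4, 3))
        cm = _cov_model(a @ a.T, masses, coords)
        full = schlitter_entropy(cm, 300.0, remove_rigid_modes=0)
        reduced = schlitter_entropy(cm, 300.0, remove_rigid_modes=6)
        assert reduced.minus_TS_schlitter >= full.minus_TS_schlitter
        assert reduced.modes_removed == 6

    def test_rotation_invariance(self):
        # rotating all frames rigidly, then superposing, leaves -TS unchanged
        from linkerthermo.trajectory import superpose
        ens = syn.gaussian_ensemble(2e-4 * np.eye(12), 12.0, 4000, seed=9)
        R = rotation_matrix([1.0, 0.3, -0.8], 1.1)
        rot = TrajectoryFrames(coordinates=ens.frames.coordinates @ R,
                               times=ens.frames.times,
                               topology=ens.frames.topology)
        reps = []
        for traj in (ens.frames, rot):
            fitted, _ = superpose(traj)
            cm = build_covariance(fitted, start_time_ps=0.0)
            reps.append(schlitter_entropy(cm, 300.0).minus_TS_schlitter)
        assert reps[0] == pytest.approx(reps[1], abs=1e-6)

    def test_convergence_with_frames(self):
        # |estimate - truth| shrinks with trajectory length on average
        cov = 3e-4 * np.eye(9)
        errs = []
        for n in (1000, 10_000, 100_000):
            per_seed = []
            for seed in range(3):
                ens = syn.gaussian_ensemble(cov, 12.0, n, seed=seed)
                cm = build_covariance(ens.frames, start_time_ps=0.0)
                rep = schlitter_entropy(cm, 300.0, remove_rigid_modes=0)
                per_seed.append(abs(rep.minus_TS_schlitter
                                    - ens.truth["minus_TS_schlitter"]))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]

    def test_negative_eigenvalue_errors(self):
        m = np.diag([-1e-3, 1e-4, 1e-4])
        with pytest.raises(NumericalError, match="below numerical floor"):
            schlitter_entropy(_cov_model(m, [12.0]), 300.0, remove_rigid_modes=0)

    def test_largest_policy_drops_top_modes(self):
        lams = np.array([1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1] + [1.0] * 6)
        cm = _cov_model(np.diag(np.repeat(lams[:4], 3)), [1.0] * 4)
        naive = schlitter_entropy(cm, 300.0, remove_rigid_modes=6,
                                  policy="largest")
        expect = entropy_from_eigenvalues(np.sort(np.repeat(lams[:4], 3))[:-6],
                                          300.0)
        assert naive.minus_TS_schlitter == pytest.approx(-300.0 * expect,
                                                         rel=1e-12)


class TestRigidGenerators:
    def test_orthonormal_and_complete(self):
        rng = np.random.default_rng(8)
        masses = rng.uniform(1, 20, 5)
        coords = rng.uniform(0, 1, (5, 3))
        G = rigid_body_generators(masses, coords)
        assert G.shape == (6, 15)
        np.testing.assert_allclose(G @ G.T, np.eye(6), atol=1e-10)

    def test_linear_geometry_five_generators(self):
        coords = np.zeros((4, 3))
        coords[:, 0] = np.arange(4)
        G = rigid_body_generators(np.full(4, 12.0), coords)
        assert G.shape[0] == 5


class TestReports:
    def test_split_paper_style_difference(self):
        # conformational = Schlitter - vibrational, exactly
        rep = split_conformational(-95.07, -80.61)
        assert rep.minus_TS_conformational == pytest.approx(-14.46, abs=1e-12)
        rep2 = split_conformational(-1374.0, -790.7)
        assert rep2.minus_TS_conformational == pytest.approx(-583.3, abs=1e-9)
        assert split_conformational(-5.0, -5.0).minus_TS_conformational == 0.0

    def test_replicate_summary_stats(self):
        reps = [EntropyReport(minus_TS_schlitter=v, temperature=300.0)
                for v in (-1.0, -2.0, -3.0)]
        summ = replicate_summary(reps)
        assert summ.mean.minus_TS_schlitter == pytest.approx(-2.0)
        assert summ.sd["minus_TS_schlitter"] == pytest.approx(1.0)
        assert summ.n == 3

    def test_replicate_summary_degenerate(self):
        one = replicate_summary([EntropyReport(minus_TS_schlitter=-4.0,
                                               temperature=300.0)])
        assert one.n == 1 and one.sd["minus_TS_schlitter"] == 0.0
        equal = replicate_summary(
            [EntropyReport(minus_TS_schlitter=-7.0, temperature=300.0)] * 3)
        assert equal.mean.minus_TS_schlitter == -7.0
        assert equal.sd["minus_TS_schlitter"] == 0.0

    def test_mixed_temperatures_rejected(self):
        reps = [EntropyReport(minus_TS_schlitter=-1.0, temperature=300.0),
                EntropyReport(minus_TS_schlitter=-1.0, temperature=310.0)]
        with pytest.raises(ValueError, match="mixed temperatures"):
            replicate_summary(reps)

    def test_positive_minus_ts_rejected(self):
        with pytest.raises(NumericalError):
            EntropyReport(minus_TS_schlitter=2.0, temperature=300.0)
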