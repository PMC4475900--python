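"""Skew-symmetric dynamics fitting, plane extraction, and orientation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import solve_sylvester, subspace_angles

from jpca.datasets import StateMatrix, DerivativePair, JPCAPlane
from jpca.model import (
    make_derivative_pair,
    fit_unconstrained,
    fit_skew,
    extract_planes,
    orient_plane,
    project,
    JPCA,
)


def pair_from(X, X_dot, bw=10.0):
    X = np.asarray(X, dtype=float)
    return DerivativePair(X=X, X_dot=np.asarray(X_dot, dtype=float),
                          bin_width_ms=bw, n_conditions=1, n_timebins=X.shape[1])


def random_skew(d, rng, scale=1.0):
    a = rng.normal(size=(d, d)) * scale
    return (a - a.T) / 2


class TestDerivativePair:
    def test_constant_trajectory_zero_derivative(self):
        traj = np.tile(np.arange(3).reshape(1, 3, 1), (2, 1, 5)).astype(float)
        st_ = StateMatrix.from_trajectories(traj, 10.0)
        pair = make_derivative_pair(st_)
        np.testing.assert_array_equal(pair.X_dot, 0.0)

    def test_column_count_c_times_t_minus_1(self):
        rng = np.random.default_rng(0)
        st_ = StateMatrix.from_trajectories(rng.normal(size=(8, 6, 25)), 10.0)
        pair = make_derivative_pair(st_)
        assert pair.X.shape == (6, 192) and pair.X_dot.shape == (6, 192)

    def test_linear_trajectory_constant_slope(self):
        slope = np.array([1.0, -2.0])
        traj = (np.arange(6)[None, None, :] * slope[None, :, None]).astype(float)
        pair = make_derivative_pair(StateMatrix.from_trajectories(traj, 10.0))
        np.testing.assert_allclose(pair.X_dot, slope[:, None] * np.ones((1, 5)))

    def test_differencing_respects_condition_boundaries(self):
        rng = np.random.default_rng(1)
        traj = rng.normal(size=(3, 2, 4))
        pair = make_derivative_pair(StateMatrix.from_trajectories(traj, 10.0))
        # column 3 starts condition 1: X_dot[:,3] = traj[1,:,1]-traj[1,:,0]
        np.testing.assert_allclose(pair.X_dot[:, 3], traj[1, :, 1] - traj[1, :, 0])

    def test_single_time_point_raises(self):
        st_ = StateMatrix.from_trajectories(np.zeros((2, 2, 1)), 10.0)
        with pytest.raises(ValueError):
            make_derivative_pair(st_)


class TestUnconstrainedFit:
    def test_identity_states_recover_derivatives(self):
        d_mat = np.random.default_rng(2).normal(size=(3, 3))
        m = fit_unconstrained(pair_from(np.eye(3), d_mat))
        np.testing.assert_allclose(m, d_mat, atol=1e-12)

    def test_exact_model_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 4))
        x = rng.normal(size=(4, 50))
        m = fit_unconstrained(pair_from(x, a @ x))
        np.testing.assert_allclose(m, a, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 60))
        xd = rng.normal(size=(4, 60))
        m = fit_unconstrained(pair_from(x, xd))
        oracle = xd @ x.T @ np.linalg.inv(x @ x.T)
        np.testing.assert_allclose(m, oracle, atol=1e-8)

    def test_rank_deficient_warns(self):
        x = np.zeros((3, 10))
        x[0] = 1.0
        with pytest.warns(UserWarning, match="least-norm"):
            fit_unconstrained(pair_from(x, np.zeros((3, 10))))


class TestSkewFit:
    def test_exact_rotation_generator(self):
        m = fit_skew(pair_from([[1, 0], [0, 1]], [[0, -1], [1, 0]]))
        np.testing.assert_allclose(m, [[0.0, -1.0], [1.0, 0.0]], atol=1e-12)

    def test_closed_form_2d(self):
        """k = sum(x1*dx2 - x2*dx1) / sum(|x|^2) = 0.5 for this instance."""
        m = fit_skew(pair_from([[1, 0], [0, 1]], [[1, 0], [1, 0]]))
        np.testing.assert_allclose(m, [[0.0, -0.5], [0.5, 0.0]], atol=1e-12)

    @pytest.mark.parametrize("d", [4, 6])
    def test_matches_sylvester_oracle(self, d):
        """The stationarity condition M*(XX') + (XX')*M = X_dot X' - X X_dot'
        solved by an independent Sylvester-equation route."""
        rng = np.random.default_rng(d)
        for _ in range(10):
            x = rng.normal(size=(d, 80))
            xd = rng.normal(size=(d, 80))
            m = fit_skew(pair_from(x, xd))
            s = x @ x.T
            q = xd @ x.T - x @ xd.T
            oracle = solve_sylvester(s, s, q)
            np.testing.assert_allclose(m, oracle, atol=1e-8)

    def test_skew_exact_and_residual_ordering(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 100))
        xd = rng.normal(size=(6, 100))
        pair = pair_from(x, xd)
        ms = fit_skew(pair)
        mu = fit_unconstrained(pair)
        np.testing.assert_allclose(ms + ms.T, 0.0, atol=1e-12)
        assert np.linalg.norm(xd - mu @ x) <= np.linalg.norm(xd - ms @ x) + 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_skew_symmetry_and_imaginary_eigenvalues(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 7))
        x = rng.normal(size=(d, 40))
        xd = rng.normal(size=(d, 40))
        m = fit_skew(pair_from(x, xd))
        np.testing.assert_allclose(m + m.T, 0.0, atol=1e-10)
        assert np.max(np.abs(np.linalg.eigvals(m).real)) < 1e-8


class TestExtractPlanes:
    def make_state(self, d=4, seed=0, c=6, t=20):
        rng = np.random.default_rng(seed)
        return StateMatrix.from_trajectories(rng.normal(size=(c, d, t)), 10.0)

    def test_block_diagonal_frequency_order(self):
        m = np.zeros((4, 4))
        m[0, 1], m[1, 0] = -1.0, 1.0  # omega 1 in dims (0,1)
        m[2, 3], m[3, 2] = -3.0, 3.0  # omega 3 in dims (2,3)
        planes = extract_planes(m, self.make_state())
        top = planes[0].basis
        assert np.allclose(np.abs(top[:2, :]), 0.0, atol=1e-10)  # spans dims 2,3
        assert planes[0].angular_frequency > planes[1].angular_frequency

    def test_zero_matrix_degenerate_planes(self):
        with pytest.warns(UserWarning, match="zero-frequency"):
            planes = extract_planes(np.zeros((4, 4)), self.make_state())
        assert len(planes) == 2
        assert all(p.angular_frequency == 0.0 for p in planes)
        b = np.concatenate([p.basis for p in planes], axis=1)
        np.testing.assert_allclose(b.T @ b, np.eye(4), atol=1e-10)

    def test_invariant_subspace_oracle(self):
        """Top plane matches the invariant subspace of the largest
        eigenpair, checked by principal angles."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_skew(6, rng)
            planes = extract_planes(m, self.make_state(d=6, seed=1))
            w, v = np.linalg.eig(m)
            i = np.argmax(w.imag)
            sub = np.column_stack([v[:, i].real, v[:, i].imag])
            ang = subspace_angles(planes[0].basis, sub).max()
            assert ang < 1e-8

    def test_deterministic_under_repeat(self):
        m = random_skew(6, np.random.default_rng(12))
        s = self.make_state(d=6, seed=2)
        a = extract_planes(m, s)
        b = extract_planes(m, s)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.basis, pb.basis)


class TestOrientPlane:
    def make_plane(self, d=4):
        b = np.zeros((d, 2))
        b[0, 0] = b[1, 1] = 1.0
        return JPCAPlane(basis=b, angular_frequency=1.0,
                         angular_frequency_corrected=1.0,
                         variance_captured_reduced=0.5, variance_captured_full=0.5)

    def test_rank_one_spread_sets_jpc1(self):
        rng = np.random.default_rng(13)
        state = StateMatrix.from_trajectories(rng.normal(size=(6, 4, 10)), 10.0)
        pre = np.zeros((6, 4))
        pre[:, 0] = pre[:, 1] = np.linspace(-1, 1, 6)  # along (1,1)/sqrt2 in-plane
        out = orient_plane(self.make_plane(), pre, state)
        jpc1_inplane = self.make_plane().basis.T @ out.basis[:, 0]
        target = np.array([1.0, 1.0]) / np.sqrt(2)
        assert min(np.linalg.norm(jpc1_inplane - target),
                   np.linalg.norm(jpc1_inplane + target)) < 1e-10

    def test_clockwise_rotation_flipped_to_ccw(self):
        t = np.linspace(0, np.pi, 30)
        traj = np.zeros((2, 2, 30))
        for c, phase in enumerate((0.0, 1.0)):
            traj[c, 0] = np.cos(-t + phase)
            traj[c, 1] = np.sin(-t + phase)  # clockwise
        state = StateMatrix.from_trajectories(traj, 10.0)
        pre = traj[:, :, 0]
        out = orient_plane(self.make_plane(d=2), pre, state)
        xy = np.einsum("dk,cdt->ckt", out.basis, traj)
        cross = np.sum(xy[:, 0, :-1] * np.diff(xy[:, 1], axis=1)
                       - xy[:, 1, :-1] * np.diff(xy[:, 0], axis=1))
        assert cross > 0
        assert out.orientation_flipped["jpc2_sign"]

    def test_jpc1_spread_dominates_sweep_oracle(self):
        """Post-orientation initial-state variance along jPC1 beats every
        in-plane direction probed at 0.1 degree resolution."""
        rng = np.random.default_rng(14)
        for _ in range(10):
            state = StateMatrix.from_trajectories(rng.normal(size=(8, 4, 12)), 10.0)
            pre = rng.normal(size=(8, 4))
            out = orient_plane(self.make_plane(), pre, state)
            p = pre @ out.basis
            v1, v2 = p[:, 0].var(), p[:, 1].var()
            assert v1 >= v2 - 1e-12
            angles = np.radians(np.arange(0, 180, 0.1))
            dirs = np.stack([np.cos(angles), np.sin(angles)])
            sweep = (p @ dirs).var(axis=0).max()
            assert v1 >= sweep - 1e-9

    def test_isotropic_tie_keeps_basis(self):
        state = StateMatrix.from_trajectories(
            np.random.default_rng(15).normal(size=(4, 4, 8)), 10.0)
        pre = np.zeros((4, 4))
        pre[0, 0] = pre[1, 1] = 1.0
        pre[2, 0] = pre[3, 1] = -1.0  # isotropic in-plane covariance
        plane = self.make_plane()
        out = orient_plane(plane, pre, state)
        assert out.orientation_flipped["spread_tie"]
        np.testing.assert_allclose(np.abs(out.basis), np.abs(plane.basis), atol=1e-12)


class TestProject:
    def test_basis_projects_to_unit_axes(self):
        plane = TestOrientPlane().make_plane()
        out = project(plane.basis, plane)
        np.testing.assert_allclose(out, np.eye(2), atol=1e-12)

    def test_projection_norm_bounded(self, rng):
        plane = TestOrientPlane().make_plane()
        x = rng.normal(size=(4, 30))
        out = project(x, plane)
        assert np.all(np.linalg.norm(out, axis=0) <= np.linalg.norm(x, axis=0) + 1e-12)

    def test_projection_variance_identity(self):
        rng = np.random.default_rng(16)
        state = StateMatrix.from_trajectories(rng.normal(size=(5, 4, 10)), 10.0)
        planes = extract_planes(random_skew(4, rng), state)
        p = planes[0]
        proj = project(state, p)
        ss = np.sum(proj**2)
        np.testing.assert_allclose(
            ss, p.variance_captured_reduced * np.sum(state.X_red**2), rtol=1e-10
        )


class TestParameterRecovery:
    def test_noiseless_two_plane_recovery(self, rotational_latents):
        """Data from x' = Sx with 2.5 and 1 Hz planes: the fit recovers the
        invariant subspaces, frequencies, and near-perfect r2."""
        spec = rotational_latents.spec
        res = JPCA.from_trajectories(rotational_latents.states, spec.dt_ms).fit()
        assert res.r2_skew >= 0.99
        true_top = np.zeros((4, 2))
        true_top[0, 0] = true_top[1, 1] = 1.0
        ang = np.degrees(subspace_angles(res.planes[0].basis, true_top)).max()
        assert ang < 2.0
        assert res.planes[0].frequency_hz == pytest.approx(2.5, rel=0.02)
        assert res.planes[1].frequency_hz == pytest.approx(1.0, rel=0.02)

    def test_frequency_error_decreases_with_dt(self):
        """Raw per-bin frequency converges to the true angular frequency
        as the bin width shrinks (monotone over 20, 10, 5, 1 ms)."""
        from jpca.simulate import LatentDynamicsSpec, generate_latents

        errs = []
        for dt in (20.0, 10.0, 5.0, 1.0):
            spec = LatentDynamicsSpec(
                n_dims=4, plane_frequencies=(2 * np.pi * 2.5, 2 * np.pi),
                duration_ms=240.0, dt_ms=dt, seed=7)
            lat = generate_latents(spec, 8)
            res = JPCA.from_trajectories(lat.states, dt).fit()
            errs.append(abs(res.planes[0].angular_frequency - 2 * np.pi * 2.5))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestModelObject:
    def test_summary_contains_key_quantities(self, rotational_trials):
        res = JPCA.from_trialset(rotational_trials).fit()
        text = res.summary()
        assert "R2 (skew-symmetric M)" in text
        assert f"{res.planes[0].frequency_hz:.3f}" in text

    def test_fit_deterministic(self, rotational_trials):
        r1 = JPCA.from_trialset(rotational_trials).fit()
        r2 = JPCA.from_trialset(rotational_trials).fit()
        np.testing.assert_array_equal(r1.M_skew, r2.M_skew)
        assert r1.r2_skew == r2.r2_skew

    def test_r2_ordering_and_plane_invariants(self, rotational_trials):
        res = JPCA.from_trialset(rotational_trials).fit()
        assert res.r2_skew <= res.r2_unconstrained + 1e-12
        for p in res.planes:
            np.testing.assert_allclose(p.basis.T @ p.basis, np.eye(2), atol=1e-10)
        total = sum(p.variance_captured_reduced for p in res.planes)
        assert total == pytest.approx(1.0, abs=1e-9)
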