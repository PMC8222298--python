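"""LQE design: linearization structure, Riccati correctness, gain family
properties, and the nonlinear estimator's behavior in the loop."""

import numpy as np
import pytest

from cpgwalk.engine import _simulate
from cpgwalk.estimator import (EstimatorState, design_estimator,
                               estimator_contact_update, estimator_derivative,
                               gain_family, linearize, lqe_gain,
                               normalized_gain)
from cpgwalk.noise import NoiseSpec
from cpgwalk.walker import WalkerParams, WalkerState, accel, heelstrike_map

RHO_GRID = np.logspace(-4, 0.8, 13)


class TestLinearize:
    def test_kinematic_rows_exact(self, params, control):
        A, Bw, C = linearize(params, control, 1.0)
        assert np.array_equal(A[0:2, 0:2], np.zeros((2, 2)))
        assert np.array_equal(A[0:2, 2:4], np.eye(2))
        assert np.array_equal(Bw[2:4], np.eye(2))
        assert np.array_equal(C[:, 0:2], np.eye(2))

    def test_matches_finite_difference_of_accel(self, params, control):
        """A equals a central-difference Jacobian of the acceleration flow
        computed at a different step size."""
        A, _, _ = linearize(params, control, 1.0)
        eps = 1e-5
        p = WalkerParams()
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            def f(x):
                st = WalkerState.from_role(x, 0)
                return np.concatenate([x[2:4], accel(p, st, np.zeros(2))])
            col = (f(e) - f(-e)) / (2 * eps)
            assert np.allclose(A[:, j], col, atol=1e-6)

    def test_control_folding_shifts_swing_stiffness(self, params, control):
        """Folding the proportional swing torque into A shifts the swing
        angle column by -(M^-1)[:,swing] * k_sw."""
        A_ol, _, _ = linearize(params, control, 1.0, include_control=False)
        A_cl, _, _ = linearize(params, control, 1.0, include_control=True)
        from cpgwalk.walker import dynamics_terms
        st = WalkerState.from_role(np.zeros(4), 0)
        Minv = np.linalg.inv(dynamics_terms(params, st).M)
        shift = A_cl[2:4, 1] - A_ol[2:4, 1]
        assert np.allclose(shift, -Minv[:, 1] * control.k_sw, atol=1e-6)


class TestLQE:
    def test_riccati_residual(self, params, control, ref_noise):
        A, Bw, C = linearize(params, control, 1.0)
        for rho in (1e-3, 1.0, 5.0):
            L, P = lqe_gain(A, Bw, C, ref_noise.process_cov,
                            ref_noise.sensor_cov, rho)
            res = (A @ P + P @ A.T
                   - P @ C.T @ np.linalg.inv(ref_noise.sensor_cov) @ C @ P
                   + Bw @ (rho * ref_noise.process_cov) @ Bw.T)
            assert np.abs(res).max() < 1e-9

    def test_covariance_ratio_invariance(self, params, control, ref_noise):
        A, Bw, C = linearize(params, control, 1.0)
        L1, _ = lqe_gain(A, Bw, C, ref_noise.process_cov,
                         ref_noise.sensor_cov)
        L2, _ = lqe_gain(A, Bw, C, 7.3 * ref_noise.process_cov,
                         7.3 * ref_noise.sensor_cov)
        assert np.allclose(L1, L2, rtol=1e-8)

    def test_gain_monotone_and_brackets_paper_range(self, params, control,
                                                    ref_noise):
        """sigma_max(L) is nondecreasing in rho, does not vanish at small
        rho (unstable stance mode keeps a minimal stabilizing gain), and the
        normalized gains span roughly 0.82 to 1.44 over the design range."""
        fam = gain_family(params, control, ref_noise, RHO_GRID)
        ngs = [d.normalized_gain for d in fam]
        assert all(b - a > -1e-9 for a, b in zip(ngs, ngs[1:]))
        assert ngs[0] > 0.5                      # no feedforward collapse
        assert ngs[0] < 0.83 and ngs[-1] > 1.40  # bracket 0.82 and 1.44

    def test_all_designs_stable(self, params, control, ref_noise):
        for d in gain_family(params, control, ref_noise, RHO_GRID):
            assert np.max(d.estimator_poles().real) < 0

    def test_rejects_indefinite_covariances(self, params, control, ref_noise):
        A, Bw, C = linearize(params, control, 1.0)
        with pytest.raises(ValueError):
            lqe_gain(A, Bw, C, ref_noise.process_cov, np.zeros((2, 2)))
        with pytest.raises(ValueError):
            lqe_gain(A, Bw, C, -np.eye(2), ref_noise.sensor_cov)

    def test_riccati_covariance_matches_linear_monte_carlo(self, params,
                                                           control, design,
                                                           rng):
        """Steady-state error covariance of the linearized loop driven by
        white noise matches the Riccati P to within Monte-Carlo error."""
        A, C, L, P = design.A, design.Cmeas, design.L, design.P
        ns = NoiseSpec()
        Acl = A - L @ C
        dt = 5e-3
        q_cov = design.Bw @ ns.process_cov @ design.Bw.T \
            + L @ ns.sensor_cov @ L.T
        chol = np.linalg.cholesky(q_cov * dt + 1e-16 * np.eye(4))
        nbatch, nsteps, burn = 120, 1400, 400
        e = np.zeros((nbatch, 4))
        acc = np.zeros((4, 4))
        count = 0
        Ad = np.eye(4) + dt * Acl + 0.5 * dt ** 2 * (Acl @ Acl)
        for k in range(nsteps):
            e = e @ Ad.T + rng.standard_normal((nbatch, 4)) @ chol.T
            if k >= burn:
                acc += e.T @ e
                count += nbatch
        cov = acc / count
        scale = np.sqrt(np.outer(np.diag(P), np.diag(P)))
        assert np.abs((cov - P) / scale).max() < 0.10


class TestNormalizedGain:
    def test_identity_and_zero(self, design):
        assert normalized_gain(design.L, design.L) == 1.0
        assert normalized_gain(np.zeros((4, 2)), design.L) == 0.0
        with pytest.raises(ValueError):
            normalized_gain(design.L, np.zeros((4, 2)))


class TestNonlinearEstimator:
    def _est(self, q, stance=0):
        gc = np.zeros(2, bool)
        gc[stance] = True
        return EstimatorState(np.array(q[:2]), np.array(q[2:]), gc)

    def test_zero_error_reduces_to_internal_flow(self, params, control,
                                                 design):
        est = self._est([0.1, -0.2, -0.4, 0.3])
        y = est.theta_hat.copy()
        dth, dw = estimator_derivative(params, control, est, 1.0, y, design.L)
        dth0, dw0 = estimator_derivative(params, control, est, 1.0, y,
                                         np.zeros((4, 2)))
        assert np.allclose(dth, dth0) and np.allclose(dw, dw0)

    def test_zero_gain_ignores_measurements(self, params, control):
        est = self._est([0.1, -0.2, -0.4, 0.3])
        L0 = np.zeros((4, 2))
        d1 = estimator_derivative(params, control, est, 1.0,
                                  np.array([0.5, -0.5]), L0)
        d2 = estimator_derivative(params, control, est, 1.0,
                                  np.array([-9.0, 9.0]), L0)
        assert np.allclose(d1[0], d2[0]) and np.allclose(d1[1], d2[1])

    def test_contact_update_matches_plant_collision(self, params):
        """The estimated collision applied at the true state equals the
        plant's own collision map output."""
        st = WalkerState.from_role(np.array([-0.3, 0.3, -0.5, -0.2]), 0)
        est = EstimatorState(st.theta.copy(), st.thetadot.copy(),
                             st.contact.copy())
        plant_post = heelstrike_map(params, st)
        est_post = estimator_contact_update(params, est)
        assert est_post.stance_leg == plant_post.stance_leg
        assert np.allclose(est_post.thetadot_hat, plant_post.thetadot)

    def test_noiseless_convergence_from_perturbed_estimate(self, system,
                                                           gait):
        """Started 0.05 rad off the true state with the optimal gain and no
        noise, the estimation error contracts every stride (slowest
        estimator pole ~0.58) and decays below 1e-4 within 5 strides."""
        est0 = gait.q0 + np.array([0.05, 0.05, 0.0, 0.0])
        res = _simulate(system, 10, noise=None, L=system.L,
                        record_dt=0.005, h=1e-3, est_init=est0,
                        integral_control=False)
        err = np.linalg.norm(res.states - res.est_states, axis=1)
        assert err[0] > 0.05
        i3 = np.searchsorted(res.time, 3 * 2 * gait.step_time) - 1
        assert err[i3] < 1e-3
        assert err[-1] < 1e-4
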