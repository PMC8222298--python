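"""Internal-model state estimator and its optimal (LQE) gain design.

The CPG's core is an internal model of the leg dynamics that integrates the
same nonlinear equations of motion as the walker, driven by an efference
copy of the motor command, and corrected by the sensory prediction error
``e = y - theta_hat`` through a constant gain ``L``:

    d/dt [theta_hat; thetadot_hat] =
        [thetadot_hat; M^-1 (T - C thetadot_hat - G)] + L (y - theta_hat)

``L`` is designed by linear-quadratic estimation: the dynamics are
linearized about the legs-vertical configuration with a fixed stance/swing
role assignment, and the steady-state estimation Riccati equation is solved
for process covariance ``rho * N_x`` and sensor covariance ``N_y``.  The
family over ``rho`` spans sub- to super-optimal feedback: because the
stance (inverted-pendulum) mode is unstable, the gain does not vanish as
``rho -> 0`` but approaches the smallest stabilizing gain, so the overall
normalized gain spans a finite band around 1.

Sensed ground contact is a separate boolean channel: with non-zero ``L``
any sensed contact change overrides the estimated contact and triggers the
estimated collision; with ``L = 0`` (pure feedforward) the estimator relies
on its own internal-model contact geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from . import _core
from .controller import ControlParams, torque_command
from .noise import NoiseSpec
from .walker import WalkerParams, WalkerState


@dataclass
class EstimatorState:
    """The CPG's belief about the walker state (leg-identity indexed)."""

    theta_hat: np.ndarray
    thetadot_hat: np.ndarray
    gc_hat: np.ndarray

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)
        self.thetadot_hat = np.asarray(self.thetadot_hat, dtype=float)
        self.gc_hat = np.asarray(self.gc_hat, dtype=bool)
        if int(self.gc_hat.sum()) != 1:
            raise ValueError("exactly one leg must be believed in contact")

    @property
    def stance_leg(self) -> int:
        return int(np.argmax(self.gc_hat))

    def as_walker_state(self) -> WalkerState:
        return WalkerState(self.theta_hat.copy(), self.thetadot_hat.copy(),
                           self.gc_hat.copy())

    def role_view(self) -> np.ndarray:
        st = self.stance_leg
        sw = 1 - st
        return np.array([self.theta_hat[st], self.theta_hat[sw],
                         self.thetadot_hat[st], self.thetadot_hat[sw]])


@dataclass(frozen=True)
class EstimatorDesign:
    """Linearized model, covariances and the designed sensory feedback gain."""

    A: np.ndarray             # 4x4 state matrix, x = (th_st, th_sw, w_st, w_sw)
    Bw: np.ndarray            # 4x2 process-noise (acceleration) input map
    Cmeas: np.ndarray         # 2x4 measurement map (leg angles)
    L: np.ndarray             # 4x2 sensory feedback gain
    P: np.ndarray             # Riccati steady-state error covariance
    rho: float                # process-noise design multiplier
    normalized_gain: float    # sigma_max(L) / sigma_max(L*_lqe)

    def estimator_poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.A - self.L @ self.Cmeas)


def linearize(params: WalkerParams, control: ControlParams, s: float,
              reference: np.ndarray | None = None,
              include_control: bool = False,
              eps: float = 1e-7) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearize the internal-model flow about a role-ordered reference state.

    Default reference is legs vertical at rest with the stance role in
    contact.  With `include_control` the state-dependence of the motor
    command (the proportional swing torque) is folded into A, matching the
    estimator's own flow; without it A is the open-loop plant Jacobian.
    """
    pp = params.pack()
    x0 = np.zeros(4) if reference is None else np.asarray(reference, float)

    def flow(x):
        if include_control:
            t1 = -control.stance_torque(s)
            t2 = -control.k_sw * x[1]
        else:
            t1 = t2 = 0.0
        a1, a2 = _core.accel(x[0], x[1], x[2], x[3], t1, t2, 0.0, 0.0, pp)
        return np.array([x[2], x[3], a1, a2])

    A = np.zeros((4, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = eps
        A[:, j] = (flow(x0 + e) - flow(x0 - e)) / (2 * eps)
    A[0:2, 0:2] = 0.0
    A[0:2, 2:4] = np.eye(2)          # exact kinematic rows
    Bw = np.vstack([np.zeros((2, 2)), np.eye(2)])
    Cmeas = np.hstack([np.eye(2), np.zeros((2, 2))])
    return A, Bw, Cmeas


def lqe_gain(A: np.ndarray, Bw: np.ndarray, Cmeas: np.ndarray,
             process_cov: np.ndarray, sensor_cov: np.ndarray,
             rho: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state Kalman (LQE) gain for the continuous-time model.

    Solves A P + P A' - P C' Ny^-1 C P + Bw (rho Nx) Bw' = 0 and returns
    (L, P) with L = P C' Ny^-1.  Requires (A, Cmeas) detectable and the
    sensor covariance positive definite.
    """
    process_cov = np.asarray(process_cov, float)
    sensor_cov = np.asarray(sensor_cov, float)
    if np.any(np.linalg.eigvalsh(sensor_cov) <= 0):
        raise ValueError("sensor covariance must be positive definite")
    if np.any(np.linalg.eigvalsh(process_cov) < -1e-12):
        raise ValueError("process covariance must be positive semidefinite")
    n = A.shape[0]
    obs = np.vstack([Cmeas @ np.linalg.matrix_power(A, k) for k in range(n)])
    if np.linalg.matrix_rank(obs) < n:
        raise ValueError("(A, Cmeas) is unobservable; cannot design estimator")
    Q = Bw @ (rho * process_cov) @ Bw.T
    P = linalg.solve_continuous_are(A.T, Cmeas.T, Q, sensor_cov)
    L = P @ Cmeas.T @ np.linalg.inv(sensor_cov)
    return L, P


def normalized_gain(L: np.ndarray, L_star: np.ndarray) -> float:
    """sigma_max(L) / sigma_max(L*): scalar magnitude of sensory feedback."""
    denom = np.linalg.norm(np.asarray(L_star, float), 2)
    if denom == 0:
        raise ValueError("reference gain L* must be nonzero")
    return float(np.linalg.norm(np.asarray(L, float), 2) / denom)


def design_estimator(params: WalkerParams, control: ControlParams,
                     noise: NoiseSpec, rho: float = 1.0,
                     s: float | None = None,
                     include_control: bool = False) -> EstimatorDesign:
    """Design the estimator gain for a noise condition and multiplier rho."""
    s_val = control.s_init if s is None else s
    A, Bw, Cmeas = linearize(params, control, s_val,
                             include_control=include_control)
    L, P = lqe_gain(A, Bw, Cmeas, noise.process_cov, noise.sensor_cov, rho)
    if rho == 1.0:
        ngain = 1.0
    else:
        L_star, _ = lqe_gain(A, Bw, Cmeas, noise.process_cov,
                             noise.sensor_cov, 1.0)
        ngain = normalized_gain(L, L_star)
    poles = np.linalg.eigvals(A - L @ Cmeas)
    if np.max(poles.real) >= 0:
        raise ValueError("designed estimator is not stable")
    return EstimatorDesign(A=A, Bw=Bw, Cmeas=Cmeas, L=L, P=P, rho=rho,
                           normalized_gain=ngain)


def gain_family(params: WalkerParams, control: ControlParams,
                noise: NoiseSpec, rho_grid: np.ndarray,
                include_control: bool = False) -> list[EstimatorDesign]:
    """Estimator designs over a rho grid, normalized by the rho=1 gain."""
    A, Bw, Cmeas = linearize(params, control, control.s_init,
                             include_control=include_control)
    L_star, _ = lqe_gain(A, Bw, Cmeas, noise.process_cov, noise.sensor_cov, 1.0)
    out = []
    for rho in np.asarray(rho_grid, float):
        L, P = lqe_gain(A, Bw, Cmeas, noise.process_cov, noise.sensor_cov, rho)
        out.append(EstimatorDesign(
            A=A, Bw=Bw, Cmeas=Cmeas, L=L, P=P, rho=float(rho),
            normalized_gain=normalized_gain(L, L_star)))
    return out


def estimator_derivative(params: WalkerParams, control: ControlParams,
                         est: EstimatorState, s: float, y: np.ndarray,
                         L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Time derivative (dtheta_hat, dthetadot_hat) of the nonlinear estimator.

    `y` holds the measured leg angles by leg identity; `L` is role-ordered
    (stance first).  With L = 0 this is the pure feedforward internal model.
    """
    pp = params.pack()
    q = est.role_view()
    st = est.stance_leg
    gc_role = np.array([1.0, 0.0])
    T = torque_command(control, s, q[0:2], gc_role)
    a1, a2 = _core.accel(q[0], q[1], q[2], q[3], T[0], T[1], 0.0, 0.0, pp)
    e = np.array([y[st] - q[0], y[1 - st] - q[1]])
    L = np.asarray(L, float)
    dq = np.array([q[2], q[3]]) + L[0:2] @ e
    dw = np.array([a1, a2]) + L[2:4] @ e
    # back to leg-identity ordering
    dtheta = np.empty(2)
    dthetadot = np.empty(2)
    dtheta[st], dtheta[1 - st] = dq[0], dq[1]
    dthetadot[st], dthetadot[1 - st] = dw[0], dw[1]
    return dtheta, dthetadot


def estimator_contact_update(params: WalkerParams,
                             est: EstimatorState) -> EstimatorState:
    """Apply the estimated heelstrike: flip the believed ground contact and
    transform the estimated velocities by the collision map evaluated at the
    estimated state.  Triggered either by a sensed contact change (non-zero
    L) or by the internal model's own contact geometry (pure feedforward)."""
    q = est.role_view()
    pp = params.pack()
    w1p, w2p = _core.collision(q[0], q[1], q[2], q[3], pp)
    new_st = 1 - est.stance_leg
    theta = est.theta_hat.copy()
    thetadot = np.empty(2)
    thetadot[new_st] = w1p
    thetadot[1 - new_st] = w2p
    gc = np.zeros(2, dtype=bool)
    gc[new_st] = True
    return EstimatorState(theta, thetadot, gc)
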