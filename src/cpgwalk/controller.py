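"""State-based hip-torque command, tonic-drive speed regulation, fall reset,
and calibration of the nominal limit cycle.

The motor command is deliberately simple and robust rather than economical:
a constant extensor torque on the stance leg, scaled by the tonic descending
drive ``s``, and a proportional (spring-like) torque on the swing leg that
tunes swing frequency:

    T_i = -(k_st + mu_st * s) * GC_i - k_sw * theta_i * (1 - GC_i)

A slow discrete integral control on ``s`` holds the average walking speed at
the target despite noise.  Calibration finds the swing gain and stance
torque such that the noiseless limit cycle walks at the target speed while
the step length minimizes positive work per distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .walker import WalkerParams, WalkerState


@dataclass(frozen=True)
class ControlParams:
    """Constants of the state-based motor command (normalized units)."""

    k_st: float           # baseline stance extensor torque (M g l)
    mu_st: float          # stance torque gain on the tonic drive s
    k_sw: float           # swing proportional gain (M g l / rad)
    target_speed: float = 0.4
    k_integral: float = 0.0   # tonic-drive integral gain per unit speed error
    s_init: float = 1.0

    def __post_init__(self) -> None:
        if self.k_sw <= 0:
            raise ValueError("k_sw must be positive")
        if self.target_speed <= 0:
            raise ValueError("target_speed must be positive")
        if self.k_integral < 0:
            raise ValueError("k_integral must be non-negative")

    def stance_torque(self, s: float) -> float:
        """Magnitude of the constant stance extensor torque at drive s."""
        return self.k_st + self.mu_st * s


def torque_command(cp: ControlParams, s: float, theta: np.ndarray,
                   gc: np.ndarray) -> np.ndarray:
    """Hip torques for both legs given (estimated) angles and ground contact.

    Total function of its arguments; also used with estimates
    (theta_hat, GC_hat) when driven by the state estimator.
    """
    theta = np.asarray(theta, dtype=float)
    gc = np.asarray(gc, dtype=float)
    return -(cp.k_st + cp.mu_st * s) * gc - cp.k_sw * theta * (1.0 - gc)


def update_tonic_drive(cp: ControlParams, s: float,
                       measured_speed: float,
                       s_nominal: float | None = None) -> float:
    """Discrete integral update of the tonic drive after a completed stride.

    Includes an anti-windup clamp at five times the nominal drive magnitude.
    """
    s_new = s + cp.k_integral * (cp.target_speed - measured_speed)
    ref = abs(s_nominal if s_nominal is not None else cp.s_init)
    if ref > 0:
        s_new = float(np.clip(s_new, -5.0 * ref, 5.0 * ref))
    return s_new


def fall_reset(nominal_state: WalkerState,
               last_footfall_position: float,
               nominal_step_length: float) -> WalkerState:
    """State after a fall: the nominal initial condition advanced one nominal
    step length past the previous footfall.  No other penalty is applied;
    the time and energy wasted in the fall itself are already in the logs."""
    return replace(
        nominal_state,
        theta=nominal_state.theta.copy(),
        thetadot=nominal_state.thetadot.copy(),
        contact=nominal_state.contact.copy(),
        forward_position=last_footfall_position + nominal_step_length,
    )


@dataclass(frozen=True)
class NominalGait:
    """Calibrated noiseless limit cycle (one step of the stride map)."""

    q0: np.ndarray          # post-heelstrike role state (th_st, th_sw, w_st, w_sw)
    alpha: float            # stance angle magnitude at heelstrike
    step_length: float      # footfall-to-footfall distance, units of l
    step_time: float        # step duration, units of (l/g)^0.5
    speed: float            # average speed, (g l)^0.5
    mcot: float             # positive work / (M g * distance) on the cycle
    residual: float         # stride-map fixed point residual (inf-norm)
    eigvals: np.ndarray     # eigenvalues of the linearized stride map

    @property
    def scuff_angle(self) -> float:
        """10% of the nominal heelstrike stance angle (scuffing exemption)."""
        return 0.1 * self.alpha

    def initial_state(self, stance_leg: int = 0) -> WalkerState:
        return WalkerState.from_role(self.q0.copy(), stance_leg)


class CalibrationError(RuntimeError):
    pass


def _fixed_point(params: WalkerParams, stance_torque: float, k_sw: float,
                 seed_q: np.ndarray, h: float = 1e-3,
                 tol: float = 1e-11) -> tuple[np.ndarray, dict]:
    """Fixed point of the step-to-step (Poincare) map at the post-heelstrike
    section.  Unknowns: (alpha, w_st, w_sw) with q = (alpha, -alpha, w_st, w_sw).
    """
    from .engine import step_map

    info: dict = {}

    def unpack(z):
        return np.array([z[0], -z[0], z[1], z[2]])

    def residual(z):
        q = unpack(z)
        out = step_map(params, q, stance_torque, k_sw,
                       scuff_angle=0.1 * abs(z[0]), h=h)
        if out.event != "heelstrike":
            # keep the solver inside the walking basin
            return np.array([10.0 + abs(z[0]), 10.0, 10.0])
        info["out"] = out
        qn = out.q_next
        return np.array([qn[0] - z[0], qn[2] - z[1], qn[3] - z[2]])

    seeds = [np.array([seed_q[0], seed_q[2], seed_q[3]]),
             np.array([0.28, -0.42, -0.30]),
             np.array([0.22, -0.35, -0.25]),
             np.array([0.35, -0.50, -0.40])]
    last_res = np.inf
    for z0 in seeds:
        sol = optimize.root(residual, z0, method="hybr", tol=1e-13)
        res = np.abs(residual(sol.x)).max()
        last_res = min(last_res, res)
        if res <= tol:
            info["residual"] = res
            return unpack(sol.x), info
    raise CalibrationError(
        f"no limit cycle found (best residual {last_res:.2e}) for stance "
        f"torque {stance_torque:.4f}, k_sw {k_sw:.4f}")


def _cycle_metrics(params: WalkerParams, q0: np.ndarray, stance_torque: float,
                   k_sw: float, h: float = 1e-3) -> dict:
    from .engine import step_map

    out = step_map(params, q0, stance_torque, k_sw,
                   scuff_angle=0.1 * abs(q0[0]), h=h)
    return {
        "step_length": out.step_length,
        "step_time": out.duration,
        "speed": out.step_length / out.duration,
        "work_pos": out.work_pos,
        "mcot": out.work_pos / (params.total_mass * params.gravity
                                * out.step_length),
    }


def _stride_map_jacobian(params: WalkerParams, q0: np.ndarray,
                         stance_torque: float, k_sw: float,
                         h: float = 1e-3, eps: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the step map on the 3-dim section."""
    from .engine import step_map

    scuff = 0.1 * abs(q0[0])

    def fmap(z):
        q = np.array([z[0], -z[0], z[1], z[2]])
        out = step_map(params, q, stance_torque, k_sw, scuff_angle=scuff, h=h)
        return np.array([out.q_next[0], out.q_next[2], out.q_next[3]])

    z0 = np.array([q0[0], q0[2], q0[3]])
    jac = np.zeros((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        jac[:, j] = (fmap(z0 + e) - fmap(z0 - e)) / (2 * eps)
    return jac


def calibrate_nominal(params: WalkerParams,
                      template: ControlParams | None = None,
                      k_sw_bounds: tuple[float, float] = (0.05, 0.6),
                      h: float = 1e-3,
                      seed_q: np.ndarray | None = None,
                      ) -> tuple[ControlParams, NominalGait]:
    """Calibrate the controller to the nominal gait.

    For each swing gain k_sw, the stance torque is solved so that the limit
    cycle's average speed equals the target; among those cycles, the k_sw
    minimizing positive work per distance (mCOT) is returned.  The stance
    torque is split between k_st and mu_st * s so that only their sum
    matters nominally (s_init = 1, k_st = mu_st = torque / 2).
    """
    target = template.target_speed if template is not None else 0.4
    if seed_q is None:
        seed_q = np.array([0.28, -0.28, -0.42, -0.30])

    # warm-started caches across the outer optimization
    state = {"q": seed_q.copy()}

    def speed_at(stance_torque: float, k_sw: float) -> float:
        q, _ = _fixed_point(params, stance_torque, k_sw, state["q"], h=h)
        state["q"] = q
        return _cycle_metrics(params, q, stance_torque, k_sw, h=h)["speed"]

    tq_cache = {"tq": 0.035}

    def torque_for_speed(k_sw: float) -> float:
        f = lambda tq: speed_at(tq, k_sw) - target
        # expand a bracket around the previous solution
        lo = hi = tq_cache["tq"]
        flo = fhi = f(lo)
        for _ in range(40):
            if flo > 0:
                lo *= 0.8
                flo = f(lo)
            elif fhi < 0:
                hi *= 1.25
                fhi = f(hi)
            else:
                break
        if not (flo <= 0 <= fhi):
            raise CalibrationError(
                f"could not bracket the target speed at k_sw={k_sw:.4f} "
                f"(torque range [{lo:.4g}, {hi:.4g}])")
        tq = optimize.brentq(f, lo, hi, xtol=1e-10)
        tq_cache["tq"] = tq
        return tq

    def mcot_of(k_sw: float) -> float:
        tq = torque_for_speed(k_sw)
        q, _ = _fixed_point(params, tq, k_sw, state["q"], h=h)
        return _cycle_metrics(params, q, tq, k_sw, h=h)["mcot"]

    opt = optimize.minimize_scalar(mcot_of, bounds=k_sw_bounds,
                                   method="bounded",
                                   options={"xatol": 1e-4})
    if not opt.success:
        raise CalibrationError(f"swing-gain search failed: {opt}")
    k_sw = float(opt.x)
    stance_torque = torque_for_speed(k_sw)
    q0, info = _fixed_point(params, stance_torque, k_sw, state["q"], h=h)
    met = _cycle_metrics(params, q0, stance_torque, k_sw, h=h)
    jac = _stride_map_jacobian(params, q0, stance_torque, k_sw, h=h)
    eigs = np.linalg.eigvals(jac)

    # integral gain: correction factor ~0.95 per step => ~10-stride time scale
    dv_dT = _speed_sensitivity(params, q0, stance_torque, k_sw, h=h)
    mu_st = stance_torque / 2.0
    k_integral = 0.05 / (mu_st * dv_dT) if dv_dT > 0 else 0.0

    cp = ControlParams(
        k_st=stance_torque / 2.0,
        mu_st=mu_st,
        k_sw=k_sw,
        target_speed=target,
        k_integral=k_integral,
        s_init=1.0,
    )
    gait = NominalGait(
        q0=q0,
        alpha=abs(q0[0]),
        step_length=met["step_length"],
        step_time=met["step_time"],
        speed=met["speed"],
        mcot=met["mcot"],
        residual=info["residual"],
        eigvals=eigs,
    )
    return cp, gait


def _speed_sensitivity(params: WalkerParams, q0: np.ndarray,
                       stance_torque: float, k_sw: float,
                       h: float = 1e-3, rel: float = 0.02) -> float:
    """d(average speed)/d(stance torque) along the limit-cycle family."""
    d = rel * stance_torque
    out = []
    for tq in (stance_torque - d, stance_torque + d):
        q, _ = _fixed_point(params, tq, k_sw, q0, h=h)
        out.append(_cycle_metrics(params, q, tq, k_sw, h=h)["speed"])
    return (out[1] - out[0]) / (2 * d)
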