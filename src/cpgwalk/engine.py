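"""Closed-loop hybrid simulation of the walker with estimator-based control.

The plant, the estimator (the CPG's internal model), the noise signals and
the motor command are integrated together with fixed-step RK4 (numba
kernels in :mod:`cpgwalk._core`); gait events (heelstrike, fall, the
estimator's own internal-model heelstrike in pure-feedforward mode) are
located by bisection to ~1e-12 in time.  This module orchestrates segments
between events, applies the collision maps and fall resets, bookkeeps the
tonic drive, and logs steps, falls and work integrals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import _core
from .controller import NominalGait, update_tonic_drive
from .noise import NoiseSpec, make_noise_signal
from .walker import WalkerParams

_ZERO_COEF = np.zeros((4, 1, 2))


# ---------------------------------------------------------------------------
# single noiseless step (used by calibration)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepOutcome:
    q_next: np.ndarray      # post-collision role state (empty on fall/timeout)
    event: str              # "heelstrike" | "fall" | "timeout"
    duration: float
    step_length: float
    work_pos: float
    work_neg: float


def step_map(params: WalkerParams, q: np.ndarray, stance_torque: float,
             k_sw: float, scuff_angle: float, h: float = 1e-3,
             t_max: float = 8.0) -> StepOutcome:
    """Integrate one noiseless step from a post-heelstrike role state and
    apply the collision.  The estimator is slaved to the plant (zero error),
    so this is the pure plant step-to-step map."""
    pp = params.pack()
    y0 = np.zeros(11)
    y0[0:4] = q
    y0[4:8] = q
    t, y, ev, _ = _core.integrate_segment(
        0.0, y0, t_max, h, pp, stance_torque, k_sw, np.zeros((4, 2)),
        0, 1, 0, 1, _ZERO_COEF, 1.0, _ZERO_COEF, 1.0, 0,
        0.0, 0.0, 0.0, scuff_angle, 1, 0,
        np.zeros(0), np.zeros((0, 11)), 0.0, 0)
    if ev == _core.EV_HEELSTRIKE:
        b1 = params.leg_length - params.foot_radius
        R = params.foot_radius
        jump = b1 * (np.sin(y[1]) - np.sin(y[0]))
        rolled = R * (q[0] - y[0])
        w1p, w2p = _core.collision(y[0], y[1], y[2], y[3], pp)
        q_next = np.array([y[1], y[0], w1p, w2p])
        return StepOutcome(q_next, "heelstrike", t, rolled + jump,
                           y[8], y[9])
    kind = "fall" if ev == _core.EV_FALL else "timeout"
    return StepOutcome(np.empty(0), kind, t, np.nan, y[8], y[9])


# ---------------------------------------------------------------------------
# trial container
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    """Logged outcome of one closed-loop walking trial."""

    time: np.ndarray              # trace sample times (may be empty)
    states: np.ndarray            # (n, 4) plant role states
    est_states: np.ndarray        # (n, 4) estimator role states
    step_times: np.ndarray        # heelstrike times
    step_lengths: np.ndarray
    step_durations: np.ndarray
    step_work_pos: np.ndarray     # positive actuator work per completed step
    fall_times: np.ndarray
    s_history: np.ndarray         # tonic drive after each stride update
    total_time: float
    distance: float               # total forward progression (incl. resets)
    work_pos: float
    work_neg: float
    err_sq_integral: float        # time integral of the squared 4-state error
    n_steps: int
    n_falls: int
    seed: int | None
    config_hash: str

    @property
    def estimation_rmse(self) -> float:
        if self.total_time <= 0:
            return np.nan
        return float(np.sqrt(self.err_sq_integral / (4.0 * self.total_time)))

    @property
    def mean_speed(self) -> float:
        return self.distance / self.total_time if self.total_time > 0 else np.nan


@dataclass(frozen=True)
class SimSystem:
    """Calibrated plant + controller + estimator design bundle."""

    params: WalkerParams
    control: ControlParams
    gait: NominalGait
    L: np.ndarray | None = None        # 4x2 sensory feedback gain; None => 0

    def feedback_gain(self) -> np.ndarray:
        if self.L is None:
            return np.zeros((4, 2))
        return np.asarray(self.L, dtype=float)


def config_hash(obj) -> str:
    """Short stable hash of a jsonable run configuration."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# main orchestrator
# ---------------------------------------------------------------------------

def _simulate(system: SimSystem, n_steps: int,
              noise: NoiseSpec | None = None,
              seed: int | None = None,
              L: np.ndarray | None = None,
              feedforward: bool = False,
              plant_on: bool = True,
              y_mode: int = 0,
              impulse: tuple[float, float, float] = (0.0, 0.0, 0.0),
              record_dt: float = 0.0,
              h: float = 2e-3,
              t_max: float | None = None,
              integral_control: bool = True,
              est_init: np.ndarray | None = None) -> TrialResult:
    params, cp, gait = system.params, system.control, system.gait
    pp = params.pack()
    lmat = np.zeros((4, 2)) if (feedforward or L is None) \
        else np.ascontiguousarray(L, dtype=float)
    feedback_on = 0 if (feedforward or not np.any(lmat)) else 1
    # the estimator keeps its own contact bookkeeping whenever no sensed
    # ground contact is available: pure feedforward, or plant disconnected
    watch_est = 1 if (feedback_on == 0 or not plant_on) else 0

    step_time = gait.step_time
    if t_max is None:
        t_max = step_time * (2.0 * n_steps + 25.0)

    if noise is not None:
        proc = make_noise_signal(noise.process_sd, t_max + 1.0,
                                 noise.sample_freq, noise.truncation_sd,
                                 np.random.SeedSequence([seed or 0, 1]))
        sens = make_noise_signal(noise.sensor_sd, t_max + 1.0,
                                 noise.sample_freq, noise.truncation_sd,
                                 np.random.SeedSequence([seed or 0, 2]))
        proc_coef, proc_dt = proc.coefficients, proc.dt
        sens_coef, sens_dt = sens.coefficients, sens.dt
        has_noise = 1
    else:
        proc_coef = sens_coef = _ZERO_COEF
        proc_dt = sens_dt = 1.0
        has_noise = 0

    imp_t0, imp_t1, imp_amp = impulse

    chash = config_hash({
        "walker": vars(params), "control": vars(cp),
        "noise": None if noise is None else vars(noise),
        "L": lmat, "n_steps": n_steps, "h": h, "seed": seed,
        "plant_on": plant_on, "y_mode": y_mode, "impulse": impulse,
    })

    # state
    y = np.zeros(11)
    y[0:4] = gait.q0
    y[4:8] = gait.q0 if est_init is None else np.asarray(est_init, float)
    roles_aligned = 1
    s = cp.s_init
    stance_torque = cp.stance_torque(s)
    scuff = gait.scuff_angle
    t = 0.0
    fwd = 0.0                      # forward position of the contact point
    last_footfall = 0.0
    q1_seg_start = y[0]

    # recording
    if record_dt > 0:
        nbuf = int(t_max / record_dt) + 4
        rec_t = np.empty(nbuf)
        rec_y = np.empty((nbuf, 11))
        rec_n = 0
    else:
        rec_t = np.zeros(0)
        rec_y = np.zeros((0, 11))
        rec_n = 0

    step_times, step_lengths, step_durations, step_wpos = [], [], [], []
    fall_times, s_hist = [], []
    stride_log: list[tuple[float, float]] = [(0.0, 0.0)]  # (t, fwd) at events
    last_event_t = 0.0
    last_event_wpos = 0.0
    R = params.foot_radius
    b1 = params.leg_length - params.foot_radius

    def est_catchup():
        """Apply the estimator's internal-model collision when its contact
        geometry is met exactly at a segment boundary (simultaneous with a
        plant event — e.g. the bit-identical noiseless feedforward loop —
        which the in-segment crossing detector cannot see)."""
        nonlocal roles_aligned
        if watch_est and (np.cos(y[4]) - np.cos(y[5])) <= 1e-12 \
                and y[4] < -scuff and y[5] > 0.0:
            wh1p, wh2p = _core.collision(y[4], y[5], y[6], y[7], pp)
            y[4], y[5], y[6], y[7] = y[5], y[4], wh1p, wh2p
            if plant_on:
                roles_aligned = -roles_aligned
            return True
        return False

    while len(step_times) < n_steps and t < t_max - 1e-9:
        est_catchup()
        t, y, ev, rec_n = _core.integrate_segment(
            t, y, t_max, h, pp, stance_torque, cp.k_sw, lmat,
            feedback_on, 1 if plant_on else 0, y_mode, roles_aligned,
            proc_coef, proc_dt, sens_coef, sens_dt, has_noise,
            imp_t0, imp_t1, imp_amp, scuff,
            1 if plant_on else 0, watch_est,
            rec_t, rec_y, record_dt, rec_n)
        fwd += R * (q1_seg_start - y[0]) if plant_on else 0.0

        if ev == _core.EV_BLOWUP:
            raise RuntimeError(
                f"integration diverged at t={t:.3f} (state {y[:8]}); "
                f"config {chash}")

        if ev == _core.EV_HEELSTRIKE:
            jump = b1 * (np.sin(y[1]) - np.sin(y[0]))
            w1p, w2p = _core.collision(y[0], y[1], y[2], y[3], pp)
            y[0], y[1], y[2], y[3] = y[1], y[0], w1p, w2p
            fwd += jump
            if feedback_on == 1:
                # sensed ground-contact change overrides the estimate and
                # triggers the estimated collision at the estimated state
                wh1p, wh2p = _core.collision(y[4], y[5], y[6], y[7], pp)
                y[4], y[5], y[6], y[7] = y[5], y[4], wh1p, wh2p
            else:
                roles_aligned = -roles_aligned
            step_times.append(t)
            step_lengths.append(fwd - last_footfall)
            step_durations.append(t - last_event_t)
            step_wpos.append(y[8] - last_event_wpos)
            last_footfall = fwd
            stride_log.append((t, fwd))
            # tonic-drive integral update once per stride (same-leg interval)
            if integral_control and len(stride_log) >= 3:
                t2, f2 = stride_log[-1]
                t0_, f0_ = stride_log[-3]
                if t2 > t0_:
                    v_meas = (f2 - f0_) / (t2 - t0_)
                    s = update_tonic_drive(cp, s, v_meas, cp.s_init)
                    stance_torque = cp.stance_torque(s)
                    s_hist.append(s)
            last_event_t = t
            last_event_wpos = y[8]

        elif ev == _core.EV_FALL:
            fall_times.append(t)
            y[0:4] = gait.q0
            y[4:8] = gait.q0
            roles_aligned = 1
            fwd = last_footfall + gait.step_length
            last_footfall = fwd
            # stride bookkeeping deliberately continues across the fall: the
            # stride-speed measurement then includes the time lost falling,
            # so the tonic drive compensates for falls as well as noise
            last_event_t = t
            last_event_wpos = y[8]

        elif ev == _core.EV_EST_HEELSTRIKE:
            wh1p, wh2p = _core.collision(y[4], y[5], y[6], y[7], pp)
            y[4], y[5], y[6], y[7] = y[5], y[4], wh1p, wh2p
            if plant_on:
                roles_aligned = -roles_aligned
            if not plant_on:
                # fictive mode: internal steps are the step log
                step_times.append(t)
                step_lengths.append(np.nan)
                step_durations.append(t - last_event_t)
                step_wpos.append(np.nan)
                last_event_t = t

        else:  # reached t_max
            break
        q1_seg_start = y[0]

    return TrialResult(
        time=rec_t[:rec_n].copy(),
        states=rec_y[:rec_n, 0:4].copy(),
        est_states=rec_y[:rec_n, 4:8].copy(),
        step_times=np.array(step_times),
        step_lengths=np.array(step_lengths),
        step_durations=np.array(step_durations),
        step_work_pos=np.array(step_wpos),
        fall_times=np.array(fall_times),
        s_history=np.array(s_hist),
        total_time=t,
        distance=fwd,
        work_pos=float(y[8]),
        work_neg=float(y[9]),
        err_sq_integral=float(y[10]),
        n_steps=len(step_times),
        n_falls=len(fall_times),
        seed=seed,
        config_hash=chash,
    )


# ---------------------------------------------------------------------------
# public run modes
# ---------------------------------------------------------------------------

def run_nominal(system: SimSystem, n_steps: int = 100,
                record_dt: float = 0.0, h: float = 1e-3) -> TrialResult:
    """Noiseless periodic walking from the calibrated limit cycle."""
    res = _simulate(system, n_steps, noise=None, L=system.L,
                    record_dt=record_dt, h=h)
    if res.n_falls:
        raise RuntimeError("fall during nominal run: calibration failure")
    return res


def run_trial(system: SimSystem, noise: NoiseSpec | None, n_steps: int,
              seed: int | None = None, L: np.ndarray | None = None,
              record_dt: float = 0.0, h: float = 2e-3,
              feedforward: bool = False) -> TrialResult:
    """One noisy closed-loop trial; `L=None` uses the system's design."""
    if L is None and not feedforward:
        L = system.L
    return _simulate(system, n_steps, noise=noise, seed=seed, L=L,
                     feedforward=feedforward, record_dt=record_dt, h=h)


def apply_impulse(system: SimSystem, mode: str, amplitude: float = 5.0,
                  phase: float = 0.15, pulse_width: float = 1.0 / 16.0,
                  n_steps: int = 20, record_dt: float = 0.0,
                  h: float = 1e-3) -> TrialResult:
    """Single impulsive swing-leg angular acceleration on an otherwise
    noiseless run.

    The "impulse" is a rectangular acceleration pulse of the given width
    (default one noise-sample interval) and amplitude, applied at the given
    fraction of the nominal stride (two-step) time.
    """
    if mode not in ("feedforward", "feedback"):
        raise ValueError("mode must be 'feedforward' or 'feedback'")
    t0 = phase * 2.0 * system.gait.step_time
    imp = (t0, t0 + pulse_width, amplitude)
    return _simulate(system, n_steps, noise=None,
                     L=None if mode == "feedforward" else system.L,
                     feedforward=(mode == "feedforward"),
                     impulse=imp, record_dt=record_dt, h=h)


def run_sensor_noise_only(system: SimSystem, mode: str, sensor_sd: float = 0.1,
                          n_steps: int = 20, seed: int | None = None,
                          L: np.ndarray | None = None,
                          record_dt: float = 0.0, h: float = 2e-3) -> TrialResult:
    """Sensor noise with zero process noise (feedforward vs feedback demo)."""
    spec = NoiseSpec(process_sd=(0.0, 0.0), sensor_sd=(sensor_sd, sensor_sd))
    if mode == "feedforward":
        return _simulate(system, n_steps, noise=spec, seed=seed,
                         feedforward=True, record_dt=record_dt, h=h)
    if mode != "feedback":
        raise ValueError("mode must be 'feedforward' or 'feedback'")
    return _simulate(system, n_steps, noise=spec, seed=seed,
                     L=system.L if L is None else L,
                     record_dt=record_dt, h=h)


def fictive_run(system: SimSystem, mode: str, duration: float,
                gain_reduction: float = 0.5, record_dt: float = 0.01,
                h: float = 1e-3) -> TrialResult:
    """Fictive locomotion: the plant is disconnected and only the estimator
    (internal model) and motor command loop are integrated.

    mode "error_feedback": the error signal e is cut (identically zero); the
    internal model runs free and should sustain the nominal rhythm.
    mode "measurement_feedback": the afferent y is cut (zero) and the
    estimator gain is reduced (default halved); a slower, weaker rhythm is
    expected as the estimate is drawn toward zero.
    """
    n_big = 10 ** 9
    if mode == "error_feedback":
        return _simulate(system, n_big, noise=None, plant_on=False,
                         y_mode=2, L=system.L, record_dt=record_dt, h=h,
                         t_max=duration, integral_control=False)
    if mode != "measurement_feedback":
        raise ValueError("mode must be 'error_feedback' or 'measurement_feedback'")
    L = gain_reduction * system.feedback_gain()
    return _simulate(system, n_big, noise=None, plant_on=False,
                     y_mode=1, L=L, record_dt=record_dt, h=h,
                     t_max=duration, integral_control=False)
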