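"""Half-center oscillator view of the estimator, equivalence checking, and
Poisson spike rendering of motor commands.

The CPG can be written as two mutually inhibiting half-center oscillators,
one per leg, each a second-order "primary neuron" with membrane state u and
adaptation state v, an auxiliary ground-contact neuron c, and an alpha
motoneuron producing the hip torque:

    du_i/dt + a_i u_i = -b_i v_i - sum_j w_ij q_j + sum_j h_ij e_j
                        + sum_j r_ij alpha_j(s, v_j, c_j) + f_i(u, v, c)
    q_i = g(u_i) = u_i
    dv_i/dt + a'_i v_i = q_i + sum_j h'_ij e_j

This is an exact re-labelling of the internal-model state estimator under
the identifications u = thetadot_hat, v = theta_hat, c = GC_hat,
alpha = T, with synaptic weights defined from the internal model's own
equations of motion:

    [[a_1, w_12], [w_21, a_2]] = M^-1 C       (w_ii = 0)
    b_i theta_hat_i - f_i       = (M^-1 G)_i
    [h'; h]                     = L
    r                           = M^-1
    a'_i                        = 0

Because M, C, G are state dependent, the weights are recomputed
continuously from the current estimate; the "neural" form is the same
vector field traversed through different algebra, which is exactly what the
equivalence check exercises.  The adaptation gain b_i is fixed to the
linear-in-angle part of (M^-1 G)_i at the legs-vertical reference, and the
higher-order functions f_i carry the (small) residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .controller import ControlParams, torque_command
from .walker import WalkerParams


@dataclass(frozen=True)
class OscillatorParams:
    """Synaptic weights of the two half-centers at one estimated state."""

    a: np.ndarray          # (2,) decay of u            (diag of M^-1 C)
    a_prime: np.ndarray    # (2,) decay of v            (identically zero)
    b: np.ndarray          # (2,) adaptation gains
    w: np.ndarray          # (2,2) mutual inhibition    (off-diag of M^-1 C)
    h: np.ndarray          # (2,2) sensory gain into u  (rows 3-4 of L)
    h_prime: np.ndarray    # (2,2) sensory gain into v  (rows 1-2 of L)
    r: np.ndarray          # (2,2) efference-copy strengths (M^-1)
    f: np.ndarray          # (2,) higher-order residual at this state

    def stacked_sensory_gain(self) -> np.ndarray:
        """[h'; h], which must reproduce L exactly."""
        return np.vstack([self.h_prime, self.h])


def adaptation_gains(params: WalkerParams, eps: float = 1e-7) -> np.ndarray:
    """b_i: the diagonal linear-in-angle part of M^-1 G at legs vertical."""
    pp = params.pack()

    def minv_g(q1, q2):
        m11, m12, m22, _, _, _, g1, g2 = _core.mcg(q1, q2, 0.0, 0.0, pp)
        det = m11 * m22 - m12 * m12
        return np.array([(m22 * g1 - m12 * g2) / det,
                         (m11 * g2 - m12 * g1) / det])

    b1 = (minv_g(eps, 0.0)[0] - minv_g(-eps, 0.0)[0]) / (2 * eps)
    b2 = (minv_g(0.0, eps)[1] - minv_g(0.0, -eps)[1]) / (2 * eps)
    return np.array([b1, b2])


def to_oscillator_params(params: WalkerParams, est_role_state: np.ndarray,
                         L: np.ndarray,
                         b: np.ndarray | None = None) -> OscillatorParams:
    """Oscillator weights at the current role-ordered estimated state."""
    q1, q2, w1, w2 = np.asarray(est_role_state, float)
    pp = params.pack()
    m11, m12, m22, c11, c12, c21, g1, g2 = _core.mcg(q1, q2, w1, w2, pp)
    M = np.array([[m11, m12], [m12, m22]])
    det = m11 * m22 - m12 * m12
    if det <= 0:
        raise ValueError("singular mass matrix")
    Minv = np.array([[m22, -m12], [-m12, m11]]) / det
    MC = Minv @ np.array([[c11, c12], [c21, 0.0]])
    MG = Minv @ np.array([g1, g2])
    if b is None:
        b = adaptation_gains(params)
    L = np.asarray(L, float)
    return OscillatorParams(
        a=np.diag(MC).copy(),
        a_prime=np.zeros(2),
        b=np.asarray(b, float),
        w=np.array([[0.0, MC[0, 1]], [MC[1, 0], 0.0]]),
        h=L[2:4].copy(),
        h_prime=L[0:2].copy(),
        r=Minv,
        f=np.asarray(b, float) * np.array([q1, q2]) - MG,
    )


def oscillator_derivative(op: OscillatorParams, control: ControlParams,
                          u: np.ndarray, v: np.ndarray, c: np.ndarray,
                          s: float, e: np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Neuron state derivatives and outputs (du, dv, q, alpha)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    e = np.asarray(e, float)
    q = u.copy()                                   # identity output function
    alpha = torque_command(control, s, v, np.asarray(c, float))
    du = (-op.a * u - op.b * v - op.w @ q + op.h @ e + op.r @ alpha + op.f)
    dv = -op.a_prime * v + q + op.h_prime @ e
    return du, dv, q, alpha


# ---------------------------------------------------------------------------
# closed-loop equivalence check
# ---------------------------------------------------------------------------

def _closed_loop_python(params: WalkerParams, control: ControlParams,
                        q0: np.ndarray, scuff_angle: float, L: np.ndarray,
                        n_steps: int, form: str, h: float = 1e-3,
                        record_dt: float = 0.01):
    """Noiseless plant + CPG loop with the CPG integrated either as the
    estimator equations or as the half-center oscillator equations.
    Pure-python reference path (independent of the numba trial engine)."""
    pp = params.pack()
    s = control.s_init
    b = adaptation_gains(params)
    L = np.asarray(L, float)

    def est_rhs(t, y):
        dy = np.empty(8)
        q1, q2, w1, w2, qh1, qh2, wh1, wh2 = y
        e = np.array([q1 - qh1, q2 - qh2])
        T = torque_command(control, s, np.array([qh1, qh2]), np.array([1.0, 0.0]))
        a1, a2 = _core.accel(q1, q2, w1, w2, T[0], T[1], 0.0, 0.0, pp)
        dy[0:4] = (w1, w2, a1, a2)
        if form == "estimator":
            ah1, ah2 = _core.accel(qh1, qh2, wh1, wh2, T[0], T[1], 0.0, 0.0, pp)
            dy[4:6] = np.array([wh1, wh2]) + L[0:2] @ e
            dy[6:8] = np.array([ah1, ah2]) + L[2:4] @ e
        else:
            op = to_oscillator_params(params, y[4:8], L, b=b)
            if form == "oscillator_reduced":
                # drop the higher-order residual terms (reduced-order CPG)
                op = OscillatorParams(a=op.a, a_prime=op.a_prime, b=op.b,
                                      w=op.w, h=op.h, h_prime=op.h_prime,
                                      r=op.r, f=np.zeros(2))
            du, dv, _, _ = oscillator_derivative(
                op, control, np.array([wh1, wh2]), np.array([qh1, qh2]),
                np.array([1.0, 0.0]), s, e)
            dy[4:6] = dv
            dy[6:8] = du
        return dy

    def rk4(t, y, hh):
        k1 = est_rhs(t, y)
        k2 = est_rhs(t + hh / 2, y + hh / 2 * k1)
        k3 = est_rhs(t + hh / 2, y + hh / 2 * k2)
        k4 = est_rhs(t + hh, y + hh * k3)
        return y + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    y = np.concatenate([q0, q0]).astype(float)
    t = 0.0
    ts, ys = [t], [y.copy()]
    steps = 0
    t_max = n_steps * 6.0
    while steps < n_steps and t < t_max:
        clear_old = np.cos(y[0]) - np.cos(y[1])
        y_new = rk4(t, y, h)
        clear_new = np.cos(y_new[0]) - np.cos(y_new[1])
        if (clear_old > 0 >= clear_new and y_new[0] < -scuff_angle
                and y_new[1] > 0):
            lo, hi = 0.0, h
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                ym = rk4(t, y, mid)
                if np.cos(ym[0]) - np.cos(ym[1]) > 0:
                    lo = mid
                else:
                    hi = mid
            y = rk4(t, y, hi)
            t += hi
            w1p, w2p = _core.collision(y[0], y[1], y[2], y[3], pp)
            y[0:4] = (y[1], y[0], w1p, w2p)
            wh1p, wh2p = _core.collision(y[4], y[5], y[6], y[7], pp)
            y[4:8] = (y[5], y[4], wh1p, wh2p)
            steps += 1
        else:
            y = y_new
            t += h
        if record_dt and (len(ts) == 0 or t - ts[-1] >= record_dt - 1e-12):
            ts.append(t)
            ys.append(y.copy())
    return np.array(ts), np.array(ys)


def equivalence_check(params: WalkerParams, control: ControlParams,
                      q0: np.ndarray, scuff_angle: float, L: np.ndarray,
                      n_strides: int = 10, tolerance: float = 1e-6,
                      h: float = 1e-3) -> dict:
    """Integrate the estimator form and the neural form side by side in
    closed loop and report the maximum trajectory discrepancy
    max(|u - thetadot_hat|, |v - theta_hat|) over the run."""
    n_steps = 2 * n_strides
    t1, y1 = _closed_loop_python(params, control, q0, scuff_angle, L,
                                 n_steps, "estimator", h=h)
    t2, y2 = _closed_loop_python(params, control, q0, scuff_angle, L,
                                 n_steps, "oscillator", h=h)
    n = min(len(t1), len(t2))
    diff = np.abs(y1[:n, 4:8] - y2[:n, 4:8])
    max_disc = float(diff.max())
    result = {"max_discrepancy": max_disc, "passed": max_disc < tolerance,
              "n_samples": n}
    if not result["passed"]:
        first = np.argmax(diff.max(axis=1) > tolerance)
        result["first_divergence_time"] = float(t1[first])
    return result


# ---------------------------------------------------------------------------
# Poisson spike rendering
# ---------------------------------------------------------------------------

def spike_render(times: np.ndarray, torques: np.ndarray,
                 rate_scale: float = 500.0, bin_width: float = 1e-3,
                 seed: int = 0) -> list[np.ndarray]:
    """Render motor commands as motoneuron spike trains.

    Inhomogeneous Poisson process with instantaneous rate
    ``rate_scale * |T_i(t)|`` (a single motoneuron per leg carries both
    torque signs).  Returns one array of spike times per torque column.
    """
    if rate_scale < 0:
        raise ValueError("rate scale must be non-negative")
    times = np.asarray(times, float)
    torques = np.atleast_2d(np.asarray(torques, float))
    if torques.shape[0] == len(times):
        torques = torques.T
    if not np.all(np.isfinite(torques)):
        raise ValueError("torque trace must be finite")
    rng = np.random.default_rng(seed)
    t0, t1 = times[0], times[-1]
    edges = np.arange(t0, t1, bin_width)
    out = []
    for i in range(torques.shape[0]):
        rate = rate_scale * np.abs(np.interp(edges, times, torques[i]))
        counts = rng.poisson(rate * bin_width)
        spikes = np.repeat(edges, counts) + rng.uniform(
            0.0, bin_width, size=int(counts.sum()))
        out.append(np.sort(spikes))
    return out
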