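"""Numba kernels for the walker dynamics and the closed-loop hybrid integrator.

Everything here works in *role coordinates*: index 0 is the stance-role leg
(the one in ground contact), index 1 the swing-role leg.  Leg identity is
bookkept by the callers.  Angles are measured from vertical, positive when the
foot is forward (direction of travel) of the hip; with that convention the
stance angle decreases from +alpha to -alpha over a step and the constant
extensor stance torque is negative while performing positive work.

Model constants are passed as a 12-vector ``pp``:
``[m_l, m_p, c, r_gyr, R, l, g, K, J1, J2, b1, b2]`` where the derived
constants are

    K  = m_l (c + l) + m_p l - R (2 m_l + m_p)
    J1 = m_l (r_gyr^2 + c^2) + (m_l + m_p) l^2     (stance inertia at q1 = 0)
    J2 = m_l (r_gyr^2 + (l - c)^2)                 (swing inertia about hip)
    b1 = l - R                                     (hip height above arc centre)
    b2 = l - c                                     (swing COM distance from hip)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the parameter pack
_ML, _MP, _C, _RG, _R, _L, _G, _K, _J1, _J2, _B1, _B2 = range(12)


# ---------------------------------------------------------------------------
# continuous dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def mcg(q1, q2, w1, w2, pp):
    """Mass matrix, velocity-coupling matrix and gravity moments.

    Returns (m11, m12, m22, c11, c12, c21, g1, g2); C is not symmetric and
    c22 = 0.  Derived from the Lagrangian of the rolling-foot stance leg +
    hip point mass + hanging swing leg.
    """
    ml = pp[_ML]
    R = pp[_R]
    g = pp[_G]
    K = pp[_K]
    J1 = pp[_J1]
    J2 = pp[_J2]
    b1 = pp[_B1]
    b2 = pp[_B2]
    s1 = math.sin(q1)
    s2 = math.sin(q2)
    c1 = math.cos(q1)
    c2 = math.cos(q2)
    c12 = math.cos(q1 - q2)
    s12 = math.sin(q1 - q2)
    m11 = J1 - 2.0 * R * K * (1.0 - c1)
    m12 = -ml * b2 * (R * c2 + b1 * c12)
    m22 = J2
    cc11 = -R * K * s1 * w1
    cc12 = ml * b2 * w2 * (R * s2 - b1 * s12)
    cc21 = ml * b1 * b2 * w1 * s12
    g1 = -g * K * s1
    g2 = g * ml * b2 * s2
    return m11, m12, m22, cc11, cc12, cc21, g1, g2


@njit(cache=True)
def accel(q1, q2, w1, w2, t1, t2, d1, d2, pp):
    """Angular accelerations M^-1 (T - C w - G) plus additive disturbance."""
    m11, m12, m22, c11, c12, c21, g1, g2 = mcg(q1, q2, w1, w2, pp)
    r1 = t1 - c11 * w1 - c12 * w2 - g1
    r2 = t2 - c21 * w1 - g2
    det = m11 * m22 - m12 * m12
    a1 = (m22 * r1 - m12 * r2) / det
    a2 = (m11 * r2 - m12 * r1) / det
    return a1 + d1, a2 + d2


@njit(cache=True)
def energies(q1, q2, w1, w2, pp):
    """Kinetic and potential energy of the stance-constrained system."""
    ml = pp[_ML]
    mp = pp[_MP]
    R = pp[_R]
    g = pp[_G]
    K = pp[_K]
    b2 = pp[_B2]
    m11, m12, m22, _, _, _, _, _ = mcg(q1, q2, w1, w2, pp)
    ke = 0.5 * (m11 * w1 * w1 + 2.0 * m12 * w1 * w2 + m22 * w2 * w2)
    mt = mp + 2.0 * ml
    pe = g * (R * mt + K * math.cos(q1) - ml * b2 * math.cos(q2))
    return ke, pe


# ---------------------------------------------------------------------------
# heelstrike collision (impulse-momentum projection)
# ---------------------------------------------------------------------------

@njit(cache=True)
def floating_mass_matrix(q1, q2, pp):
    """4x4 mass matrix in floating coordinates (x_hip, y_hip, theta1, theta2)."""
    ml = pp[_ML]
    mp = pp[_MP]
    J2 = pp[_J2]
    b2 = pp[_B2]
    mt = mp + 2.0 * ml
    mf = np.zeros((4, 4))
    mf[0, 0] = mt
    mf[1, 1] = mt
    mf[2, 2] = J2
    mf[3, 3] = J2
    mf[0, 2] = ml * b2 * math.cos(q1)
    mf[2, 0] = mf[0, 2]
    mf[0, 3] = ml * b2 * math.cos(q2)
    mf[3, 0] = mf[0, 3]
    mf[1, 2] = ml * b2 * math.sin(q1)
    mf[2, 1] = mf[1, 2]
    mf[1, 3] = ml * b2 * math.sin(q2)
    mf[3, 1] = mf[1, 3]
    return mf


@njit(cache=True)
def floating_velocity(q1, w1, w2, pp):
    """Full velocity (xdot, ydot, w1, w2) under the leg-1 rolling constraint."""
    R = pp[_R]
    b1 = pp[_B1]
    v = np.empty(4)
    v[0] = -(b1 * math.cos(q1) + R) * w1
    v[1] = -b1 * math.sin(q1) * w1
    v[2] = w1
    v[3] = w2
    return v


@njit(cache=True)
def collision(q1, q2, w1, w2, pp):
    """Perfectly inelastic heelstrike of the swing (role-2) foot.

    Momentum is projected onto the rolling constraint of the new contact
    foot; the impulse acts through that contact point only.  Returns the
    post-impact angular velocities in the *new* role ordering
    (new stance = old swing leg).
    """
    R = pp[_R]
    b1 = pp[_B1]
    mf = floating_mass_matrix(q1, q2, pp)
    vm = floating_velocity(q1, w1, w2, pp)
    jac = np.zeros((2, 4))
    jac[0, 0] = 1.0
    jac[0, 3] = b1 * math.cos(q2) + R
    jac[1, 1] = 1.0
    jac[1, 3] = b1 * math.sin(q2)
    minv_jt = np.linalg.solve(mf, jac.T)
    a = jac @ minv_jt            # J M^-1 J^T  (2x2)
    jv = jac @ vm
    lam = np.linalg.solve(a, jv)
    vp = vm - minv_jt @ lam
    # role swap: old swing becomes stance
    return vp[3], vp[2]


# ---------------------------------------------------------------------------
# noise interpolant (cubic-spline piecewise polynomial on a uniform grid)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _ppoly_eval(coef, dt, t, chan):
    """Evaluate channel `chan` of a cubic piecewise polynomial.

    `coef` has shape (4, nseg, nchan) (scipy CubicSpline layout, highest
    order first); breakpoints are i*dt.
    """
    nseg = coef.shape[1]
    i = int(t / dt)
    if i < 0:
        i = 0
    if i > nseg - 1:
        i = nseg - 1
    x = t - i * dt
    return ((coef[0, i, chan] * x + coef[1, i, chan]) * x + coef[2, i, chan]) * x + coef[3, i, chan]


# ---------------------------------------------------------------------------
# closed-loop right-hand side
#
# state vector (11,):
#   0..3  plant      q1, q2, w1, w2        (role coords)
#   4..7  estimator  qh1, qh2, wh1, wh2    (role coords of the estimator)
#   8     positive actuator work integral
#   9     negative actuator work integral
#   10    integral of squared 4-state estimation error
# ---------------------------------------------------------------------------

@njit(cache=True)
def closed_loop_rhs(t, y, pp, stance_torque, k_sw, lmat, feedback_on,
                    plant_on, y_mode, roles_aligned,
                    proc_coef, proc_dt, sens_coef, sens_dt, has_noise,
                    imp_t0, imp_t1, imp_amp):
    """Time derivative of the combined plant + estimator + integral state.

    y_mode: 0 normal (y = theta + sensor noise), 1 afferents cut (y = 0),
    2 error cut (innovation identically zero).
    `roles_aligned` is +1 when the estimator's stance role is the same
    physical leg as the plant's, -1 otherwise (possible in pure-feedforward
    mode where the estimator keeps its own contact bookkeeping).
    """
    dy = np.zeros(11)
    qh1 = y[4]
    qh2 = y[5]
    wh1 = y[6]
    wh2 = y[7]

    # motor command from the estimate (role coords of the estimator)
    th1 = -stance_torque
    th2 = -k_sw * qh2

    # innovation e = y - theta_hat, in estimator role coordinates
    e1 = 0.0
    e2 = 0.0
    if feedback_on == 1 and y_mode != 2:
        if y_mode == 0:
            if roles_aligned == 1:
                y1 = y[0]
                y2 = y[1]
            else:
                y1 = y[1]
                y2 = y[0]
            if has_noise == 1:
                y1 += _ppoly_eval(sens_coef, sens_dt, t, 0)
                y2 += _ppoly_eval(sens_coef, sens_dt, t, 1)
            e1 = y1 - qh1
            e2 = y2 - qh2
        else:  # y == 0
            e1 = -qh1
            e2 = -qh2

    # estimator internal model + correction
    ah1, ah2 = accel(qh1, qh2, wh1, wh2, th1, th2, 0.0, 0.0, pp)
    dy[4] = wh1 + lmat[0, 0] * e1 + lmat[0, 1] * e2
    dy[5] = wh2 + lmat[1, 0] * e1 + lmat[1, 1] * e2
    dy[6] = ah1 + lmat[2, 0] * e1 + lmat[2, 1] * e2
    dy[7] = ah2 + lmat[3, 0] * e1 + lmat[3, 1] * e2

    if plant_on == 1:
        q1 = y[0]
        q2 = y[1]
        w1 = y[2]
        w2 = y[3]
        # torque on the plant legs: map estimator roles to plant roles
        if roles_aligned == 1:
            tp1 = th1
            tp2 = th2
        else:
            tp1 = th2
            tp2 = th1
        d1 = 0.0
        d2 = 0.0
        if has_noise == 1:
            d1 = _ppoly_eval(proc_coef, proc_dt, t, 0)
            d2 = _ppoly_eval(proc_coef, proc_dt, t, 1)
        if imp_amp != 0.0 and imp_t0 <= t < imp_t1:
            d2 += imp_amp
        a1, a2 = accel(q1, q2, w1, w2, tp1, tp2, d1, d2, pp)
        dy[0] = w1
        dy[1] = w2
        dy[2] = a1
        dy[3] = a2
        # actuator work rate, split by sign
        p1 = tp1 * w1
        p2 = tp2 * w2
        if p1 > 0.0:
            dy[8] += p1
        else:
            dy[9] -= p1
        if p2 > 0.0:
            dy[8] += p2
        else:
            dy[9] -= p2
        # squared estimation error (plant roles vs estimator roles)
        if roles_aligned == 1:
            de1 = q1 - qh1
            de2 = q2 - qh2
            dw1 = w1 - wh1
            dw2 = w2 - wh2
        else:
            de1 = q1 - qh2
            de2 = q2 - qh1
            dw1 = w1 - wh2
            dw2 = w2 - wh1
        dy[10] = de1 * de1 + de2 * de2 + dw1 * dw1 + dw2 * dw2
    return dy


@njit(cache=True)
def _rk4_step(t, y, h, pp, stance_torque, k_sw, lmat, feedback_on,
              plant_on, y_mode, roles_aligned,
              proc_coef, proc_dt, sens_coef, sens_dt, has_noise,
              imp_t0, imp_t1, imp_amp):
    k1 = closed_loop_rhs(t, y, pp, stance_torque, k_sw, lmat, feedback_on,
                         plant_on, y_mode, roles_aligned, proc_coef, proc_dt,
                         sens_coef, sens_dt, has_noise, imp_t0, imp_t1, imp_amp)
    k2 = closed_loop_rhs(t + 0.5 * h, y + 0.5 * h * k1, pp, stance_torque,
                         k_sw, lmat, feedback_on, plant_on, y_mode,
                         roles_aligned, proc_coef, proc_dt, sens_coef,
                         sens_dt, has_noise, imp_t0, imp_t1, imp_amp)
    k3 = closed_loop_rhs(t + 0.5 * h, y + 0.5 * h * k2, pp, stance_torque,
                         k_sw, lmat, feedback_on, plant_on, y_mode,
                         roles_aligned, proc_coef, proc_dt, sens_coef,
                         sens_dt, has_noise, imp_t0, imp_t1, imp_amp)
    k4 = closed_loop_rhs(t + h, y + h * k3, pp, stance_torque, k_sw, lmat,
                         feedback_on, plant_on, y_mode, roles_aligned,
                         proc_coef, proc_dt, sens_coef, sens_dt, has_noise,
                         imp_t0, imp_t1, imp_amp)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


# event codes
EV_NONE = 0
EV_HEELSTRIKE = 1
EV_FALL = 2
EV_EST_HEELSTRIKE = 3
EV_BLOWUP = 4


@njit(cache=True)
def _plant_clearance(y):
    """Swing-foot height proxy: cos(q1) - cos(q2); zero at touchdown."""
    return math.cos(y[0]) - math.cos(y[1])


@njit(cache=True)
def _est_clearance(y):
    return math.cos(y[4]) - math.cos(y[5])


@njit(cache=True)
def _plant_heelstrike_armed(y, scuff_angle):
    """Touchdown only counts once the stance leg has tipped past the scuff
    threshold and the swing foot is in front."""
    return (y[0] < -scuff_angle) and (y[1] > 0.0)


@njit(cache=True)
def _est_heelstrike_armed(y, scuff_angle):
    return (y[4] < -scuff_angle) and (y[5] > 0.0)


@njit(cache=True)
def integrate_segment(t0, y0, t_end, h, pp, stance_torque, k_sw, lmat,
                      feedback_on, plant_on, y_mode, roles_aligned,
                      proc_coef, proc_dt, sens_coef, sens_dt, has_noise,
                      imp_t0, imp_t1, imp_amp, scuff_angle,
                      watch_plant_events, watch_est_events,
                      rec_t, rec_y, rec_dt, rec_n0):
    """Integrate with fixed-step RK4 until an event or t_end.

    Events are located by bisection on the step size to ~1e-12 in time.
    Optional trace recording at a fixed output interval `rec_dt` into the
    preallocated buffers (rec_n0 = entries already used).  Returns
    (t, y, event_code, rec_n).
    """
    t = t0
    y = y0.copy()
    rec_n = rec_n0
    cl_old = _plant_clearance(y)
    est_cl_old = _est_clearance(y)
    est_armed_old = _est_heelstrike_armed(y, scuff_angle)
    while t < t_end - 1e-14:
        step = min(h, t_end - t)
        y_new = _rk4_step(t, y, step, pp, stance_torque, k_sw, lmat,
                          feedback_on, plant_on, y_mode, roles_aligned,
                          proc_coef, proc_dt, sens_coef, sens_dt, has_noise,
                          imp_t0, imp_t1, imp_amp)
        t_new = t + step

        blow = False
        for i in range(8):
            if not math.isfinite(y_new[i]) or abs(y_new[i]) > 50.0:
                blow = True
        if blow:
            return t_new, y_new, EV_BLOWUP, rec_n

        # Plant heelstrikes fire on a downward clearance crossing while
        # armed; unarmed contacts are scuffs and are ignored entirely.  The
        # estimator's internal-model contact additionally fires when arming
        # occurs with the estimated foot already at/below ground (the
        # internal model predicts contact whenever its geometry says so);
        # only genuine crossings have a bracketable sign change to bisect.
        ev = EV_NONE
        bisectable = True
        if watch_plant_events == 1 and plant_on == 1:
            if abs(y_new[0]) >= 0.5 * math.pi:
                ev = EV_FALL
            else:
                cl_new = _plant_clearance(y_new)
                if (cl_old > 0.0 and cl_new <= 0.0
                        and _plant_heelstrike_armed(y_new, scuff_angle)):
                    ev = EV_HEELSTRIKE
        if ev == EV_NONE and watch_est_events == 1:
            est_cl_new = _est_clearance(y_new)
            est_armed_new = _est_heelstrike_armed(y_new, scuff_angle)
            if est_armed_new and est_cl_new <= 0.0 \
                    and not (est_armed_old and est_cl_old <= 0.0):
                ev = EV_EST_HEELSTRIKE
                bisectable = est_cl_old > 0.0

        if ev != EV_NONE and not bisectable:
            return t_new, y_new, ev, rec_n

        if ev != EV_NONE:
            # bisection on the sub-step size
            lo = 0.0
            hi = step
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                y_mid = _rk4_step(t, y, mid, pp, stance_torque, k_sw, lmat,
                                  feedback_on, plant_on, y_mode,
                                  roles_aligned, proc_coef, proc_dt,
                                  sens_coef, sens_dt, has_noise,
                                  imp_t0, imp_t1, imp_amp)
                if ev == EV_FALL:
                    val = 0.5 * math.pi - abs(y_mid[0])
                elif ev == EV_HEELSTRIKE:
                    val = _plant_clearance(y_mid)
                else:
                    val = _est_clearance(y_mid)
                if val > 0.0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-13:
                    break
            y_ev = _rk4_step(t, y, hi, pp, stance_torque, k_sw, lmat,
                             feedback_on, plant_on, y_mode, roles_aligned,
                             proc_coef, proc_dt, sens_coef, sens_dt,
                             has_noise, imp_t0, imp_t1, imp_amp)
            t_ev = t + hi
            return t_ev, y_ev, ev, rec_n

        t = t_new
        y = y_new
        cl_old = _plant_clearance(y)
        est_cl_old = _est_clearance(y)
        est_armed_old = _est_heelstrike_armed(y, scuff_angle)
        if rec_dt > 0.0:
            # record at global-time multiples of rec_dt that were just passed
            while rec_n < rec_t.shape[0] and rec_n * rec_dt <= t + 1e-14:
                rec_t[rec_n] = t
                for i in range(11):
                    rec_y[rec_n, i] = y[i]
                rec_n += 1
    return t, y, EV_NONE, rec_n
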