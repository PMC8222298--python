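"""Walker dynamics: Lagrangian oracle, structural invariants, collision laws,
and gait-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgwalk import _core
from cpgwalk.walker import (DynamicsTerms, WalkerParams, WalkerState, accel,
                            detect_events, dynamics_terms, heelstrike_map,
                            kinetic_energy, mechanical_energy,
                            step_displacement, swing_foot_clearance)

PP = WalkerParams().pack()
ML, MP, C, RG, R, L, G = PP[:7]
I_LEG = ML * RG ** 2


def role_state(q1, q2, w1, w2, stance_leg=0, fwd=0.0):
    return WalkerState.from_role(np.array([q1, q2, w1, w2]), stance_leg, fwd)


# ---------------------------------------------------------------------------
# independently coded kinematics -> energies (the test oracle)
# ---------------------------------------------------------------------------

def _positions(q1, q2):
    hipx = -R * q1 - (L - R) * np.sin(q1)
    hipy = R + (L - R) * np.cos(q1)
    p1 = np.array([hipx + (L - C) * np.sin(q1), hipy - (L - C) * np.cos(q1)])
    p2 = np.array([hipx + (L - C) * np.sin(q2), hipy - (L - C) * np.cos(q2)])
    return np.array([hipx, hipy]), p1, p2


def _velocities(q, w, eps=1e-6):
    vh = np.zeros(2)
    v1 = np.zeros(2)
    v2 = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = eps
        hp, p1p, p2p = _positions(*(q + e))
        hm, p1m, p2m = _positions(*(q - e))
        vh += (hp - hm) / (2 * eps) * w[i]
        v1 += (p1p - p1m) / (2 * eps) * w[i]
        v2 += (p2p - p2m) / (2 * eps) * w[i]
    return vh, v1, v2


def _lagrangian(q, w):
    hip, p1, p2 = _positions(*q)
    vh, v1, v2 = _velocities(q, w)
    ke = 0.5 * (MP * vh @ vh + ML * v1 @ v1 + ML * v2 @ v2
                + I_LEG * (w @ w))
    pe = G * (MP * hip[1] + ML * p1[1] + ML * p2[1])
    return ke - pe


def test_dynamics_match_independent_lagrangian(rng):
    """Closed-form M, C, G reproduce Lagrange's equations evaluated by
    finite differences of independently coded energy functions."""
    h = 1e-5
    for _ in range(20):
        q = rng.uniform(-0.5, 0.5, 2)
        w = rng.uniform(-1.0, 1.0, 2)
        T = rng.uniform(-0.5, 0.5, 2)
        state = role_state(*q, *w)
        qdd = accel(WalkerParams(), state, T)

        def dl_dw(qq, ww):
            out = np.zeros(2)
            for i in range(2):
                e = np.zeros(2)
                e[i] = h
                out[i] = (_lagrangian(qq, ww + e)
                          - _lagrangian(qq, ww - e)) / (2 * h)
            return out

        dl_dq = np.zeros(2)
        hww = np.zeros((2, 2))
        hwq = np.zeros((2, 2))
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            dl_dq[j] = (_lagrangian(q + e, w) - _lagrangian(q - e, w)) / (2 * h)
            hww[:, j] = (dl_dw(q, w + e) - dl_dw(q, w - e)) / (2 * h)
            hwq[:, j] = (dl_dw(q + e, w) - dl_dw(q - e, w)) / (2 * h)
        residual = hww @ qdd + hwq @ w - dl_dq - T
        assert np.abs(residual).max() < 1e-4


@given(q1=st.floats(-0.6, 0.6), q2=st.floats(-0.6, 0.6),
       w1=st.floats(-1.5, 1.5), w2=st.floats(-1.5, 1.5))
@settings(max_examples=50, deadline=None)
def test_mass_matrix_symmetric_positive_definite(q1, q2, w1, w2):
    terms = dynamics_terms(WalkerParams(), role_state(q1, q2, w1, w2))
    assert np.allclose(terms.M, terms.M.T)
    assert np.all(np.linalg.eigvalsh(terms.M) > 0)


def test_anthropomorphic_parameters_accepted():
    p = WalkerParams(leg_mass_fraction=0.16, pelvis_mass_fraction=0.68,
                     leg_com_distance=0.645, leg_gyration_radius=0.326,
                     foot_radius=0.3)
    assert np.isclose(2 * p.leg_mass_fraction + p.pelvis_mass_fraction, 1.0)
    with pytest.raises(ValueError):
        WalkerParams(leg_mass_fraction=0.2)
    with pytest.raises(ValueError):
        WalkerParams(foot_radius=1.5)


def test_hanging_equilibrium_has_zero_acceleration():
    state = role_state(0.0, 0.0, 0.0, 0.0)
    a = accel(WalkerParams(), state, np.zeros(2))
    assert np.allclose(a, 0.0, atol=1e-12)


def test_disturbance_is_additive(rng):
    p = WalkerParams()
    state = role_state(0.1, -0.2, -0.4, 0.3)
    T = np.array([-0.03, 0.01])
    base = accel(p, state, T)
    d = np.array([0.0, 0.7])
    assert np.allclose(accel(p, state, T, d) - base, d, atol=1e-14)


def test_passive_energy_conservation():
    """With zero torque and no noise, mechanical energy is constant along a
    swing to well below integrator tolerance."""
    y = np.zeros(11)
    y[0:4] = (0.2, -0.3, -0.4, 0.1)
    y[4:8] = y[0:4]
    e0 = sum(_core.energies(*y[0:4], PP))
    zero3 = np.zeros((4, 1, 2))
    t, yf, ev, _ = _core.integrate_segment(
        0.0, y, 1.2, 1e-3, PP, 0.0, 0.0, np.zeros((4, 2)), 0, 1, 0, 1,
        zero3, 1.0, zero3, 1.0, 0, 0.0, 0.0, 0.0, 0.03, 0, 0,
        np.zeros(0), np.zeros((0, 11)), 0.0, 0)
    e1 = sum(_core.energies(*yf[0:4], PP))
    assert abs(e1 - e0) / abs(e0) < 1e-9


def _angular_momentum_about(q1, q2, vfull, about):
    hip, p1, p2 = _positions(q1, q2)
    vh = vfull[0:2]
    vp1 = vh + (L - C) * np.array([np.cos(q1), np.sin(q1)]) * vfull[2]
    vp2 = vh + (L - C) * np.array([np.cos(q2), np.sin(q2)]) * vfull[3]
    lz = 0.0
    for pos, vel, m in ((hip, vh, MP), (p1, vp1, ML), (p2, vp2, ML)):
        r = pos - about
        lz += m * (r[0] * vel[1] - r[1] * vel[0])
    return lz + I_LEG * (vfull[2] + vfull[3])


def test_heelstrike_dissipates_energy_and_conserves_angular_momentum(rng):
    """KE never increases across the impact, and angular momentum about the
    new contact point is conserved (impulse acts through that point)."""
    p = WalkerParams()
    for _ in range(20):
        a = rng.uniform(0.15, 0.45)
        w1, w2 = rng.uniform(-1.0, 0.5, 2)
        pre = role_state(-a, a, w1, w2)
        post = heelstrike_map(p, pre)
        assert kinetic_energy(p, post) <= kinetic_energy(p, pre) + 1e-12
        # momentum oracle from the raw mass distribution
        vm = np.array(_core.floating_velocity(-a, w1, w2, PP))
        hip, _, _ = _positions(-a, a)
        new_contact = np.array([hip[0] + (L - R) * np.sin(a), 0.0])
        l_pre = _angular_momentum_about(-a, a, vm, new_contact)
        qpost = post.role_view()
        # post velocities in leg-identity order: leg1 (old stance) swings
        vfull_post = np.array(_core.floating_velocity(a, qpost[2], 0.0, PP))
        vfull_post[2] = qpost[3]
        vfull_post[3] = qpost[2]
        l_post = _angular_momentum_about(-a, a, vfull_post, new_contact)
        assert abs(l_post - l_pre) < 1e-8


def test_heelstrike_swaps_roles_and_is_linear_in_velocity():
    p = WalkerParams()
    pre = role_state(-0.3, 0.3, -0.5, -0.2, stance_leg=0)
    post = heelstrike_map(p, pre)
    assert post.stance_leg == 1
    assert np.array_equal(post.contact, [False, True])
    # linearity: zero pre-impact velocity -> zero post-impact velocity
    rest = role_state(-0.3, 0.3, 0.0, 0.0)
    assert np.allclose(heelstrike_map(p, rest).thetadot, 0.0, atol=1e-14)
    # and scaling velocities scales the outcome
    double = heelstrike_map(p, role_state(-0.3, 0.3, -1.0, -0.4))
    assert np.allclose(double.thetadot, 2 * post.thetadot, atol=1e-12)


def test_heelstrike_map_rejects_bad_geometry():
    with pytest.raises(ValueError):
        heelstrike_map(WalkerParams(), role_state(-0.3, 0.2, -0.5, 0.0))


def test_mirror_symmetry(rng):
    """Negating angles, velocities and torques negates the accelerations."""
    p = WalkerParams()
    for _ in range(10):
        q = rng.uniform(-0.4, 0.4, 2)
        w = rng.uniform(-1.0, 1.0, 2)
        T = rng.uniform(-0.1, 0.1, 2)
        a_fwd = accel(p, role_state(*q, *w), T)
        a_mir = accel(p, role_state(*(-q), *(-w)), -T)
        assert np.allclose(a_mir, -a_fwd, atol=1e-12)


def test_forward_position_advances_by_step_displacement():
    p = WalkerParams()
    pre = role_state(-0.3, 0.3, -0.5, -0.1, fwd=2.0)
    post = heelstrike_map(p, pre)
    expected = 2.0 + 2 * (L - R) * np.sin(0.3)
    assert np.isclose(post.forward_position, expected)
    assert np.isclose(step_displacement(p, pre), 2 * (L - R) * np.sin(0.3))


def test_detect_events_scuff_exemption_and_fall(gait, system):
    p = system.params
    # synthetic segment: near-vertical crossing below the scuff threshold
    t = np.linspace(0, 0.5, 200)
    q1 = -0.01 - 0.01 * t          # stance barely past vertical
    q2 = 0.011 + 0.008 * t         # swing slightly larger -> clearance < 0
    states = np.column_stack([q1, q2, np.gradient(q1, t), np.gradient(q2, t)])
    ev = detect_events(p, t, states, 0, gait.alpha)
    assert ev.kind == "none"       # scuffing is exempt
    # fall: stance angle reaches pi/2 inside the segment
    q1 = np.linspace(1.2, 1.8, 200)
    states = np.column_stack([q1, -0.2 * np.ones_like(q1),
                              np.ones_like(q1), np.zeros_like(q1)])
    ev = detect_events(p, t, states, 0, gait.alpha)
    assert ev.kind == "fall"
    assert abs(abs(ev.state.theta[0]) - np.pi / 2) < 1e-6


def test_detect_events_heelstrike_on_nominal_segment(system, gait):
    """A genuine touchdown geometry is detected with a tight crossing time."""
    p = system.params
    t = np.linspace(0, 1.0, 400)
    a = gait.alpha
    # stance tips further forward while the swing foot descends: clearance
    # (|q2| - |q1| in cosine form) crosses zero from above while armed
    q1 = -(a - 0.02) - 0.05 * t
    q2 = (a + 0.01) - 0.02 * t
    states = np.column_stack([q1, q2, np.gradient(q1, t), np.gradient(q2, t)])
    ev = detect_events(p, t, states, 0, a)
    assert ev.kind == "heelstrike"
    qc = ev.state.role_view()
    assert abs(np.cos(qc[0]) - np.cos(qc[1])) < 1e-8
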