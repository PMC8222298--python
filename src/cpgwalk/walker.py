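"""Rigid-body dynamics of a 2-DOF curved-foot biped.

The model is the planar "anthropomorphic" walker: two straight legs of
length ``l`` with curved feet of radius ``foot_radius`` rolling on flat
ground, a point-mass pelvis at the hip, and distributed leg mass.  One leg
is in ground contact at any time (single support); the step-to-step
transition is a perfectly inelastic heelstrike collision that swaps the
stance and swing roles.

Sign convention (used everywhere in this package): leg angles are measured
from vertical and are *positive when the foot is forward of the hip* in the
direction of travel.  The stance angle therefore decreases from ``+alpha``
to ``-alpha`` during a step while the swing angle rises from ``-alpha`` to
``+alpha``; heelstrike occurs when the two angles are opposite
(``theta_sw = -theta_st``).  Torques are generalized forces conjugate to the
leg angles (hip torque reacting against an inertially anchored torso), so a
negative constant stance torque performs positive work along the gait.

Units are normalized: ``g = l = total mass = 1``; time in ``(l/g)^0.5``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core


@dataclass(frozen=True)
class WalkerParams:
    """Mass distribution and geometry of the biped, in units of l, g, M."""

    leg_mass_fraction: float = 0.16
    pelvis_mass_fraction: float = 0.68
    leg_com_distance: float = 0.645   # from the foot end
    leg_gyration_radius: float = 0.326
    foot_radius: float = 0.3
    leg_length: float = 1.0
    gravity: float = 1.0
    total_mass: float = 1.0
    scuff_threshold_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not np.isclose(2 * self.leg_mass_fraction + self.pelvis_mass_fraction,
                          1.0, atol=1e-12):
            raise ValueError("leg and pelvis mass fractions must sum to 1")
        if not (0 < self.foot_radius < self.leg_length):
            raise ValueError("foot radius must lie in (0, l)")
        if not (0 < self.leg_com_distance < self.leg_length):
            raise ValueError("leg COM distance must lie in (0, l)")
        if self.leg_gyration_radius <= 0:
            raise ValueError("gyration radius must be positive")

    def pack(self) -> np.ndarray:
        """Constant pack consumed by the numba kernels."""
        ml = self.leg_mass_fraction * self.total_mass
        mp = self.pelvis_mass_fraction * self.total_mass
        c = self.leg_com_distance
        rg = self.leg_gyration_radius
        R = self.foot_radius
        l = self.leg_length
        g = self.gravity
        K = ml * (c + l) + mp * l - R * (2 * ml + mp)
        J1 = ml * (rg ** 2 + c ** 2) + (ml + mp) * l ** 2
        J2 = ml * (rg ** 2 + (l - c) ** 2)
        return np.array([ml, mp, c, rg, R, l, g, K, J1, J2, l - R, l - c])


@dataclass
class WalkerState:
    """Hybrid state of the walker, indexed by leg identity (0 left, 1 right)."""

    theta: np.ndarray
    thetadot: np.ndarray
    contact: np.ndarray
    forward_position: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.thetadot = np.asarray(self.thetadot, dtype=float)
        self.contact = np.asarray(self.contact, dtype=bool)
        if not (np.all(np.isfinite(self.theta))
                and np.all(np.isfinite(self.thetadot))):
            raise ValueError("non-finite walker state")
        if int(self.contact.sum()) != 1:
            raise ValueError("exactly one leg must be in ground contact")

    @property
    def stance_leg(self) -> int:
        return int(np.argmax(self.contact))

    def role_view(self) -> np.ndarray:
        """(theta_st, theta_sw, w_st, w_sw) — stance role first."""
        st = self.stance_leg
        sw = 1 - st
        return np.array([self.theta[st], self.theta[sw],
                         self.thetadot[st], self.thetadot[sw]])

    @classmethod
    def from_role(cls, q: np.ndarray, stance_leg: int,
                  forward_position: float = 0.0) -> "WalkerState":
        theta = np.empty(2)
        thetadot = np.empty(2)
        sw = 1 - stance_leg
        theta[stance_leg], theta[sw] = q[0], q[1]
        thetadot[stance_leg], thetadot[sw] = q[2], q[3]
        contact = np.zeros(2, dtype=bool)
        contact[stance_leg] = True
        return cls(theta, thetadot, contact, forward_position)


@dataclass(frozen=True)
class DynamicsTerms:
    """Role-ordered equation-of-motion matrices M qdd + C qd + G = T."""

    M: np.ndarray
    C: np.ndarray
    G: np.ndarray


def dynamics_terms(params: WalkerParams, state: WalkerState) -> DynamicsTerms:
    """M, C, G of the stance-rolling system at the given state."""
    q = state.role_view()
    m11, m12, m22, c11, c12, c21, g1, g2 = _core.mcg(
        q[0], q[1], q[2], q[3], params.pack())
    M = np.array([[m11, m12], [m12, m22]])
    if np.linalg.det(M) <= 0:
        raise ValueError("mass matrix is singular or indefinite")
    return DynamicsTerms(M=M, C=np.array([[c11, c12], [c21, 0.0]]),
                         G=np.array([g1, g2]))


def accel(params: WalkerParams, state: WalkerState, torque: np.ndarray,
          process_disturbance: np.ndarray | None = None) -> np.ndarray:
    """Angular accelerations M^-1 (T - C qd - G) + disturbance (role order)."""
    torque = np.asarray(torque, dtype=float)
    if not np.all(np.isfinite(torque)):
        raise ValueError("non-finite torque")
    d = np.zeros(2) if process_disturbance is None else np.asarray(
        process_disturbance, dtype=float)
    q = state.role_view()
    a1, a2 = _core.accel(q[0], q[1], q[2], q[3], torque[0], torque[1],
                         d[0], d[1], params.pack())
    return np.array([a1, a2])


def mechanical_energy(params: WalkerParams, state: WalkerState) -> float:
    """Total mechanical energy (kinetic + potential) in stance coordinates."""
    q = state.role_view()
    ke, pe = _core.energies(q[0], q[1], q[2], q[3], params.pack())
    return ke + pe


def kinetic_energy(params: WalkerParams, state: WalkerState) -> float:
    q = state.role_view()
    ke, _ = _core.energies(q[0], q[1], q[2], q[3], params.pack())
    return ke


def swing_foot_clearance(state: WalkerState) -> float:
    """Height proxy of the swing foot's lowest point: positive above ground.

    Equal to (cos(theta_st) - cos(theta_sw)); with identical foot radii the
    actual height is (l - R) times this value.
    """
    q = state.role_view()
    return float(np.cos(q[0]) - np.cos(q[1]))


def step_displacement(params: WalkerParams, state_pre: WalkerState) -> float:
    """Forward jump of the contact point at heelstrike.

    (l - R) (sin theta_sw - sin theta_st); reduces to 2 (l - R) sin(alpha)
    at a symmetric touchdown.
    """
    q = state_pre.role_view()
    b1 = params.leg_length - params.foot_radius
    return float(b1 * (np.sin(q[1]) - np.sin(q[0])))


def heelstrike_map(params: WalkerParams, state_pre: WalkerState,
                   geometry_tol: float = 1e-6) -> WalkerState:
    """Post-impact state of the perfectly inelastic heelstrike.

    Angular velocities are transformed by projecting the system momentum
    onto the rolling constraint of the new contact foot (impulse through the
    new contact point only); ground-contact roles are swapped; the forward
    position advances by the contact-point jump.
    """
    q = state_pre.role_view()
    if abs(np.cos(q[0]) - np.cos(q[1])) > geometry_tol:
        raise ValueError("heelstrike_map called away from contact geometry")
    w1p, w2p = _core.collision(q[0], q[1], q[2], q[3], params.pack())
    new_stance = 1 - state_pre.stance_leg
    q_post = np.array([q[1], q[0], w1p, w2p])
    fwd = state_pre.forward_position + step_displacement(params, state_pre)
    return WalkerState.from_role(q_post, new_stance, fwd)


@dataclass(frozen=True)
class GaitEvent:
    kind: str          # "heelstrike" | "fall" | "none"
    time: float
    state: WalkerState | None = None


def detect_events(params: WalkerParams, times: np.ndarray,
                  states: np.ndarray, stance_leg: int,
                  nominal_heelstrike_angle: float,
                  time_tol: float = 1e-9) -> GaitEvent:
    """Scan a sampled continuous trajectory segment for the first gait event.

    `states` is (n, 4) role-ordered.  Heelstrike fires at a downward zero
    crossing of the swing-foot clearance while the stance leg is beyond the
    scuff threshold; a fall fires when |theta_st| reaches pi/2 and takes
    precedence on ties.  The crossing time is refined on a cubic interpolant
    to `time_tol`.
    """
    from scipy.interpolate import CubicSpline
    from scipy.optimize import brentq

    times = np.asarray(times, float)
    states = np.asarray(states, float)
    scuff = params.scuff_threshold_fraction * abs(nominal_heelstrike_angle)
    interp = CubicSpline(times, states, axis=0)

    fall_t = np.inf
    fmargin = 0.5 * np.pi - np.abs(states[:, 0])
    for i in range(len(times) - 1):
        if fmargin[i] > 0 >= fmargin[i + 1]:
            fall_t = brentq(lambda t: 0.5 * np.pi - abs(interp(t)[0]),
                            times[i], times[i + 1], xtol=time_tol)
            break

    hs_t = np.inf
    clear = np.cos(states[:, 0]) - np.cos(states[:, 1])
    for i in range(len(times) - 1):
        if clear[i] > 0 >= clear[i + 1]:
            t_cross = brentq(lambda t: np.cos(interp(t)[0]) - np.cos(interp(t)[1]),
                             times[i], times[i + 1], xtol=time_tol)
            qc = interp(t_cross)
            if qc[0] < -scuff and qc[1] > 0:
                hs_t = t_cross
                break

    if np.isinf(fall_t) and np.isinf(hs_t):
        return GaitEvent("none", float(times[-1]))
    if fall_t <= hs_t:
        qf = interp(fall_t)
        return GaitEvent("fall", float(fall_t),
                         WalkerState.from_role(qf, stance_leg))
    qh = interp(hs_t)
    return GaitEvent("heelstrike", float(hs_t),
                     WalkerState.from_role(qh, stance_leg))
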