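"""Mechanical plants: linear two-mass oscillator and planar hopping leg.

Two-mass plant
--------------
Two equal masses, each attached to ground through a muscle spring ``k0``
and coupled to each other by a spring ``k1``, with viscous damping ``d0``:

    phi'' = -(d0/m) phi' - K phi + f/m,
    K = [[(k0+k1)/m, -k1/m], [-k1/m, (k0+k1)/m]].

The stiffness eigenvectors are (1,1) (in-phase, eigenfrequency
``sqrt(k0/m)``) and (-1,1) (anti-phase, ``sqrt((k0+2 k1)/m)``).

Hopping leg
-----------
A trunk of mass ``m0`` constrained to vertical translation carries a thigh
and a shank (uniform rods, mass ``m1``, length ``l``) through revolute hip
and knee joints.  Joint angles ``phi`` are measured from the fully
extended (straight-down) configuration, positive in flexion; with the
thigh tilted forward by ``phi1`` the shank absolute angle is
``phi1 - phi2``, so the symmetric crouch ``phi0 = (pi/6, 2 pi/6)`` places
the foot directly under the trunk.  The trunk coordinate ``h`` is zero
when the fully extended foot touches the ground.  Each joint is driven
through its series elastic element:

    tau_i = k_i (w_NM,i f_z - phi_i + phi0_i) - d_i phi_i',

and the 3-DoF dynamics are ``M(phi) v' + p(phi, v) = Q + J^T F`` with
generalized coordinates ``q = (h, phi1, phi2)``, gravity and Coriolis
terms in ``p``, and a compliant ground contact force ``F`` at the foot
(linear spring-damper normal force clamped at zero -- no adhesion -- plus
viscous tangential friction saturated at ``mu`` times the normal force).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "TwoMassModel",
    "LegModel",
    "ContactParams",
    "two_mass_accel",
    "leg_torques",
    "contact_wrench",
    "leg_dynamics_step",
    "integrate",
]

_G = 9.81


# --------------------------------------------------------------------------
# two-mass plant
# --------------------------------------------------------------------------


@dataclass
class TwoMassModel:
    """Linear two-mass oscillator (SI units)."""

    m: float = 0.5
    k0: float = 8.0
    k1: float = 15.0
    d0: float = 0.3
    phi: np.ndarray = field(default_factory=lambda: np.zeros(2))
    dphi: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float).copy()
        self.dphi = np.asarray(self.dphi, dtype=float).copy()

    def stiffness_matrix(self) -> np.ndarray:
        """The acceleration stiffness matrix K (units 1/s^2)."""
        a = (self.k0 + self.k1) / self.m
        b = -self.k1 / self.m
        return np.array([[a, b], [b, a]])

    def eigenfrequencies(self) -> np.ndarray:
        """Undamped mode frequencies (rad/s): in-phase first."""
        return np.array(
            [np.sqrt(self.k0 / self.m), np.sqrt((self.k0 + 2 * self.k1) / self.m)]
        )

    def energy(self) -> float:
        """Total mechanical energy of the unforced system (J)."""
        K = self.stiffness_matrix() * self.m
        return 0.5 * self.m * float(self.dphi @ self.dphi) + 0.5 * float(
            self.phi @ K @ self.phi
        )

    def accel(self, f=np.zeros(2)) -> np.ndarray:
        return two_mass_accel(self, f)

    def step(self, f, dt: float) -> None:
        """One explicit-Euler step (velocity updated first)."""
        a = self.accel(f)
        self.dphi = self.dphi + a * dt
        self.phi = self.phi + self.dphi * dt


def two_mass_accel(model: TwoMassModel, f) -> np.ndarray:
    """Acceleration of the two masses for applied force vector ``f`` (N)."""
    f = np.asarray(f, dtype=float)
    return (
        -(model.d0 / model.m) * model.dphi
        - model.stiffness_matrix() @ model.phi
        + f / model.m
    )


# --------------------------------------------------------------------------
# hopping leg
# --------------------------------------------------------------------------


@dataclass
class ContactParams:
    """Compliant ground: linear spring-damper normal force, viscous friction.

    The normal force is ``k_g * penetration + d_g * penetration_rate``,
    clamped at zero (the ground cannot pull).  The tangential force is
    viscous (``-d_g * v_x``) but saturated at ``mu`` times the normal
    force.  Defaults keep the landing penetration below ~5 mm.
    """

    stiffness: float = 1.0e5
    damping: float = 300.0
    friction: float = 1.0
    ground_height: float = 0.0


@dataclass
class LegModel:
    """Planar vertical-hopping leg (SI units)."""

    m0: float = 0.5
    m1: float = 0.1
    l: float = 0.106
    k0: float = 0.75
    k1: float = 0.75
    d0: float = 0.01125
    d1: float = 0.01125
    phi0: np.ndarray = field(default_factory=lambda: np.array([np.pi / 6, np.pi / 3]))
    g: float = _G
    #: one-sided joint limit stop just past full extension: a stiff
    #: torsional spring-damper engages below ``stop_angle`` so the knee
    #: and hip cannot hyperextend backwards (the small margin keeps the
    #: stop out of the regular gait so the leg cannot lean on it)
    stop_stiffness: float = 25.0
    stop_damping: float = 0.05
    stop_angle: float = -0.11
    contact: ContactParams = field(default_factory=ContactParams)
    h: float = 0.0
    phi: np.ndarray = field(default_factory=lambda: np.array([np.pi / 6, np.pi / 3]))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.phi0 = np.asarray(self.phi0, dtype=float).copy()
        self.phi = np.asarray(self.phi, dtype=float).copy()
        self.v = np.asarray(self.v, dtype=float).copy()

    # -- kinematics --------------------------------------------------------
    def foot_position(self) -> np.ndarray:
        """Foot (x, z) in world coordinates; ground is at z = ground_height."""
        return np.array(
            _foot_pos(self.h, self.phi[0], self.phi[1], self.l)
        )

    def foot_jacobian(self) -> np.ndarray:
        return np.array(_foot_jac(self.phi[0], self.phi[1], self.l)).reshape(2, 3)

    def mass_matrix(self) -> np.ndarray:
        return np.array(_leg_M(self.phi[0], self.phi[1], self.m0, self.m1, self.l)).reshape(
            3, 3
        )

    def bias_forces(self) -> np.ndarray:
        return np.array(
            _leg_bias(
                self.phi[0],
                self.phi[1],
                self.v[0],
                self.v[1],
                self.v[2],
                self.m0,
                self.m1,
                self.l,
                self.g,
            )
        )

    def energy(self, include_contact: bool = False) -> float:
        """Kinetic + gravitational + joint-spring energy (J)."""
        M = self.mass_matrix()
        T = 0.5 * float(self.v @ M @ self.v)
        zs = _segment_com_heights(self.h, self.phi[0], self.phi[1], self.l)
        V = self.g * (self.m0 * (self.h + 2 * self.l) + self.m1 * zs[0] + self.m1 * zs[1])
        dphi = self.phi - self.phi0
        V += 0.5 * self.k0 * dphi[0] ** 2 + 0.5 * self.k1 * dphi[1] ** 2
        return T + V

    def in_contact(self) -> bool:
        return self.foot_position()[1] < self.contact.ground_height

    def step(self, tau, dt: float, scheme: str = "rk4") -> None:
        leg_dynamics_step(self, tau, dt, scheme=scheme)


def _segment_com_heights(h, q1, q2, l):
    zh = h + 2 * l
    zt = zh - 0.5 * l * np.cos(q1)
    zs = zh - l * np.cos(q1) - 0.5 * l * np.cos(q1 - q2)
    return zt, zs


@njit(cache=True)
def _foot_pos(h, q1, q2, l):
    x = l * (np.sin(q1) + np.sin(q1 - q2))
    z = h + 2.0 * l - l * np.cos(q1) - l * np.cos(q1 - q2)
    return x, z


@njit(cache=True)
def _foot_jac(q1, q2, l):
    c1 = np.cos(q1)
    c12 = np.cos(q1 - q2)
    s1 = np.sin(q1)
    s12 = np.sin(q1 - q2)
    # rows: (x, z), columns: (h, phi1, phi2)
    return (0.0, l * (c1 + c12), -l * c12, 1.0, l * (s1 + s12), -l * s12)


@njit(cache=True)
def _leg_M(q1, q2, m0, m1, l):
    s1 = np.sin(q1)
    s12 = np.sin(q1 - q2)
    c2 = np.cos(q2)
    M00 = m0 + 2.0 * m1
    M01 = l * m1 * (3.0 * s1 + s12) / 2.0
    M02 = -l * m1 * s12 / 2.0
    M11 = l * l * m1 * (3.0 * c2 + 5.0) / 3.0
    M12 = -l * l * m1 * (3.0 * c2 + 2.0) / 6.0
    M22 = l * l * m1 / 3.0
    return (M00, M01, M02, M01, M11, M12, M02, M12, M22)


@njit(cache=True)
def _leg_bias(q1, q2, dh, w1, w2, m0, m1, l, g):
    s1 = np.sin(q1)
    s12 = np.sin(q1 - q2)
    s2 = np.sin(q2)
    c1 = np.cos(q1)
    c12 = np.cos(q1 - q2)
    p0 = (
        g * (m0 + 2.0 * m1)
        + 1.5 * l * m1 * w1 * w1 * c1
        + 0.5 * l * m1 * (w1 - w2) * (w1 - w2) * c12
    )
    p1 = (
        l
        * m1
        * (3.0 * g * s1 + g * s12 - 2.0 * l * w1 * w2 * s2 + l * w2 * w2 * s2)
        / 2.0
    )
    p2 = l * m1 * (-g * s12 + l * w1 * w1 * s2) / 2.0
    return p0, p1, p2


@njit(cache=True)
def _contact_force(xf, zf, vxf, vzf, kg, dg, mu, zg):
    """Compliant ground force (Fx, Fz) on the foot; zero above ground."""
    pen = zg - zf
    if pen <= 0.0:
        return 0.0, 0.0
    fz = kg * pen - dg * vzf
    if fz < 0.0:
        fz = 0.0
    fx = -dg * vxf
    lim = mu * fz
    if fx > lim:
        fx = lim
    elif fx < -lim:
        fx = -lim
    return fx, fz


@njit(cache=True)
def _leg_accel(h, q1, q2, dh, w1, w2, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs):
    """Generalized accelerations of the 3-DoF leg (solves M a = Q - p)."""
    M = _leg_M(q1, q2, m0, m1, l)
    p = _leg_bias(q1, q2, dh, w1, w2, m0, m1, l, g)
    # one-sided limit stops just past full extension
    if q1 < qs:
        tau1 += ks * (qs - q1) - ds * w1
    if q2 < qs:
        tau2 += ks * (qs - q2) - ds * w2
    xf, zf = _foot_pos(h, q1, q2, l)
    J = _foot_jac(q1, q2, l)
    vxf = J[0] * dh + J[1] * w1 + J[2] * w2
    vzf = J[3] * dh + J[4] * w1 + J[5] * w2
    fx, fz = _contact_force(xf, zf, vxf, vzf, kg, dg, mu, zg)
    b0 = -p[0] + J[0] * fx + J[3] * fz
    b1 = tau1 - p[1] + J[1] * fx + J[4] * fz
    b2 = tau2 - p[2] + J[2] * fx + J[5] * fz
    # 3x3 symmetric solve via adjugate
    a, b, c = M[0], M[1], M[2]
    d, e, f = M[4], M[5], M[8]
    A = d * f - e * e
    B = c * e - b * f
    C = b * e - c * d
    det = a * A + b * B + c * C
    D = a * f - c * c
    E = b * c - a * e
    F = a * d - b * b
    inv_det = 1.0 / det
    acc0 = (A * b0 + B * b1 + C * b2) * inv_det
    acc1 = (B * b0 + D * b1 + E * b2) * inv_det
    acc2 = (C * b0 + E * b1 + F * b2) * inv_det
    return acc0, acc1, acc2


@njit(cache=True)
def _leg_deriv(y, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs):
    h, q1, q2, dh, w1, w2 = y
    a0, a1, a2 = _leg_accel(
        h, q1, q2, dh, w1, w2, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs
    )
    return np.array([dh, w1, w2, a0, a1, a2])


@njit(cache=True)
def _leg_rk4(y, tau1, tau2, dt, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs):
    k1 = _leg_deriv(y, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs)
    k2 = _leg_deriv(y + 0.5 * dt * k1, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs)
    k3 = _leg_deriv(y + 0.5 * dt * k2, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs)
    k4 = _leg_deriv(y + dt * k3, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def _leg_deriv_act(y, u1, u2, m0, m1, l, g, k0, k1, d0, d1, f01, f02, kg, dg, mu, zg, ks, ds, qs):
    """Leg derivative with series-elastic actuation, motor set points u (ZOH)."""
    h, q1, q2, dh, w1, w2 = y
    tau1 = k0 * (u1 - q1 + f01) - d0 * w1
    tau2 = k1 * (u2 - q2 + f02) - d1 * w2
    a0, a1, a2 = _leg_accel(
        h, q1, q2, dh, w1, w2, tau1, tau2, m0, m1, l, g, kg, dg, mu, zg, ks, ds, qs
    )
    return np.array([dh, w1, w2, a0, a1, a2])


@njit(cache=True)
def _leg_rk4_act(y, u1, u2, dt, m0, m1, l, g, k0, k1, d0, d1, f01, f02, kg, dg, mu, zg, ks, ds, qs):
    k1_ = _leg_deriv_act(y, u1, u2, m0, m1, l, g, k0, k1, d0, d1, f01, f02, kg, dg, mu, zg, ks, ds, qs)
    k2_ = _leg_deriv_act(y + 0.5 * dt * k1_, u1, u2, m0, m1, l, g, k0, k1, d0, d1, f01, f02, kg, dg, mu, zg, ks, ds, qs)
    k3_ = _leg_deriv_act(y + 0.5 * dt * k2_, u1, u2, m0, m1, l, g, k0, k1, d0, d1, f01, f02, kg, dg, mu, zg, ks, ds, qs)
    k4_ = _leg_deriv_act(y + dt * k3_, u1, u2, m0, m1, l, g, k0, k1, d0, d1, f01, f02, kg, dg, mu, zg, ks, ds, qs)
    return y + (dt / 6.0) * (k1_ + 2.0 * k2_ + 2.0 * k3_ + k4_)


def leg_torques(model: LegModel, w_nm, f_z: float) -> np.ndarray:
    """Series-elastic actuation torque at the two joints.

    ``tau = diag(k0, k1) (w_NM f_z - phi + phi0) - diag(d0, d1) dphi``.
    The motor signal shifts the spring set point by ``w_NM,i * f_z``.
    """
    w_nm = np.asarray(w_nm, dtype=float)
    k = np.array([model.k0, model.k1])
    d = np.array([model.d0, model.d1])
    return k * (w_nm * float(f_z) - model.phi + model.phi0) - d * model.v[1:]


def contact_wrench(model: LegModel) -> np.ndarray:
    """Generalized contact force ``J^T F`` for the current leg state."""
    J = model.foot_jacobian()
    vf = J @ model.v
    xf, zf = model.foot_position()
    c = model.contact
    fx, fz = _contact_force(
        xf, zf, vf[0], vf[1], c.stiffness, c.damping, c.friction, c.ground_height
    )
    return J.T @ np.array([fx, fz])


def leg_dynamics_step(model: LegModel, tau, dt: float, scheme: str = "rk4") -> None:
    """Advance the leg one step under constant joint torques ``tau``.

    ``scheme`` is ``"rk4"`` (default; classical Runge-Kutta, robust through
    the stiff contact phase at dt = 1e-4 s) or ``"euler"``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = np.asarray(tau, dtype=float)
    y = np.array([model.h, model.phi[0], model.phi[1], *model.v])
    c = model.contact
    args = (
        tau[0],
        tau[1],
        model.m0,
        model.m1,
        model.l,
        model.g,
        c.stiffness,
        c.damping,
        c.friction,
        c.ground_height,
        model.stop_stiffness,
        model.stop_damping,
        model.stop_angle,
    )
    if scheme == "rk4":
        y = _leg_rk4(y, args[0], args[1], dt, *args[2:])
    elif scheme == "euler":
        y = y + dt * _leg_deriv(y, *args)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("leg integration diverged")
    model.h = float(y[0])
    model.phi = y[1:3].copy()
    model.v = y[3:6].copy()


def integrate(model, forces, scheme: str, dt: float, duration: float) -> dict:
    """Integrate a plant under a zero-order-hold force program.

    Parameters
    ----------
    model
        A :class:`TwoMassModel` or :class:`LegModel` (advanced in place).
    forces
        Array of shape ``(n_steps, 2)`` (force per joint, held constant
        over each step) or ``None`` for the unforced plant.
    scheme
        ``"euler"``, ``"rk4"`` (leg only) or ``"adaptive"`` (embedded
        Runge-Kutta via :func:`scipy.integrate.solve_ivp`, sampled on the
        ``dt`` grid).
    dt, duration
        Step width and total time (s).

    Returns a dict of time-series arrays (``t`` plus plant coordinates).
    """
    n = int(round(duration / dt))
    if forces is None:
        forces = np.zeros((n, 2))
    forces = np.asarray(forces, dtype=float)
    if forces.shape[0] < n:
        raise ValueError("force program shorter than duration")
    t = np.arange(1, n + 1) * dt

    if isinstance(model, TwoMassModel):
        if scheme == "adaptive":
            return _integrate_adaptive_two_mass(model, forces, dt, n, t)
        phi = np.empty((n, 2))
        dphi = np.empty((n, 2))
        for k in range(n):
            model.step(forces[k], dt)
            phi[k] = model.phi
            dphi[k] = model.dphi
        return {"t": t, "phi": phi, "dphi": dphi}

    if isinstance(model, LegModel):
        # for the leg the force program is the pair of motor set-point
        # inputs u_i = w_NM,i * f_z (ZOH); springs, dampers, limit stops,
        # gravity and contact are part of the plant and evaluated
        # continuously inside each step
        if scheme == "adaptive":
            return _integrate_adaptive_leg(model, forces, dt, n, t)
        if scheme not in ("euler", "rk4"):
            raise ValueError(f"unknown scheme {scheme!r}")
        args = _leg_args(model)
        y = np.array([model.h, model.phi[0], model.phi[1], *model.v])
        h = np.empty(n)
        phi = np.empty((n, 2))
        v = np.empty((n, 3))
        contact = np.empty(n, dtype=bool)
        for k in range(n):
            if scheme == "rk4":
                y = _leg_rk4_act(y, forces[k, 0], forces[k, 1], dt, *args)
            else:
                y = y + dt * _leg_deriv_act(y, forces[k, 0], forces[k, 1], *args)
            if not np.all(np.isfinite(y)):
                raise FloatingPointError("leg integration diverged")
            h[k] = y[0]
            phi[k] = y[1:3]
            v[k] = y[3:6]
            contact[k] = _foot_pos(y[0], y[1], y[2], model.l)[1] < model.contact.ground_height
        model.h = float(y[0])
        model.phi = y[1:3].copy()
        model.v = y[3:6].copy()
        return {"t": t, "h": h, "phi": phi, "v": v, "contact": contact}

    raise TypeError(f"unsupported plant type {type(model)!r}")


def _leg_args(model: LegModel) -> tuple:
    c = model.contact
    return (
        model.m0, model.m1, model.l, model.g, model.k0, model.k1,
        model.d0, model.d1, model.phi0[0], model.phi0[1],
        c.stiffness, c.damping, c.friction, c.ground_height,
        model.stop_stiffness, model.stop_damping, model.stop_angle,
    )


def _integrate_adaptive_two_mass(model, forces, dt, n, t):
    def rhs(tt, y):
        k = min(int(tt / dt), n - 1)
        m = TwoMassModel(model.m, model.k0, model.k1, model.d0, y[:2], y[2:])
        return np.concatenate([y[2:], two_mass_accel(m, forces[k])])

    y0 = np.concatenate([model.phi, model.dphi])
    sol = solve_ivp(
        rhs, (0, n * dt), y0, t_eval=t, rtol=1e-8, atol=1e-10, max_step=dt * 10
    )
    if not sol.success:
        raise RuntimeError(f"adaptive integration failed: {sol.message}")
    model.phi = sol.y[:2, -1].copy()
    model.dphi = sol.y[2:, -1].copy()
    return {"t": t, "phi": sol.y[:2].T.copy(), "dphi": sol.y[2:].T.copy()}


def _integrate_adaptive_leg(model, forces, dt, n, t):
    args = _leg_args(model)

    def rhs(tt, y):
        k = min(int(tt / dt), n - 1)
        return _leg_deriv_act(y, forces[k, 0], forces[k, 1], *args)

    y0 = np.array([model.h, model.phi[0], model.phi[1], *model.v])
    sol = solve_ivp(rhs, (0, n * dt), y0, t_eval=t, rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"adaptive integration failed: {sol.message}")
    model.h = float(sol.y[0, -1])
    model.phi = sol.y[1:3, -1].copy()
    model.v = sol.y[3:6, -1].copy()
    zf = np.array(
        [_foot_pos(sol.y[0, k], sol.y[1, k], sol.y[2, k], model.l)[1] for k in range(n)]
    )
    return {
        "t": t,
        "h": sol.y[0].copy(),
        "phi": sol.y[1:3].T.copy(),
        "v": sol.y[3:6].T.copy(),
        "contact": zf < model.contact.ground_height,
    }
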