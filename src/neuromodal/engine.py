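"""Closed-loop co-simulation of the spiking controller and its plants.

The engine wires the modules together for the three experiment protocols:

* ``run_feedforward`` -- sinusoidal Poisson drive into the plastic synapse
  and the serotonergic pathway, no mechanics;
* ``run_two_mass`` -- full loop around the linear two-mass oscillator;
* ``run_leg`` -- full loop around the hopping leg, with sensory (30 ms)
  and serotonergic (200 ms) conduction delays.

All per-step dynamics run inside numba-compiled kernels that reuse the
LIF and triplet-STDP kernels of :mod:`neuromodal.neurons` and
:mod:`neuromodal.plasticity`, so the engine and the unit-level APIs share
one implementation of the update equations.  Randomness flows from a
single ``numpy.random.Generator`` seeded by the experiment configuration;
identical seeds and configurations give bit-identical recordings.

Signal plumbing
---------------
The pool motor signal is the low-pass filtered (time constant ``tau_f``)
pooled spike train of the LIF pool, converted to a generalized force by
``f_z = m_f * nu_bar_post``.  The pooled (summed) convention is used --
enlarging the LIF pool at fixed per-neuron rate increases ``nu_bar_post``
proportionally, which is why the enlarged-network protocol scales ``c_NM``
down by the pool-size factor to keep the motor signal comparable.
Conduction delays are exact integer-step ring buffers.  Serotonin is
stepped on its own (coarser) grid; mechanics advance with one classical
Runge-Kutta step per neural step under a zero-order-hold motor signal.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .config import ExperimentConfig
from .mechanics import _foot_pos, _leg_rk4_act
from .neurons import _lif_kernel
from .plasticity import _triplet_kernel

__all__ = [
    "DelayLine",
    "Recording",
    "build_topology",
    "motor_signal",
    "run_feedforward",
    "run_two_mass",
    "run_leg",
]


# --------------------------------------------------------------------------
# plumbing
# --------------------------------------------------------------------------


def motor_signal(nu_bar_post: float, m_f: float) -> float:
    """Convert the filtered pool rate (Hz) to a generalized force/torque."""
    if nu_bar_post < 0:
        raise ValueError("nu_bar_post must be non-negative")
    return m_f * nu_bar_post


class DelayLine:
    """Exact integer-step delay of spike/value frames.

    The delay must be a whole multiple of the step width; the output at
    step ``k`` is the input of step ``k - delay/dt`` (zeros before that).
    """

    def __init__(self, delay: float, dt: float, shape: tuple = ()):
        steps = delay / dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("delay must be an integer multiple of dt")
        self.steps = int(round(steps))
        self.dt = dt
        self._buf = np.zeros((self.steps + 1,) + shape)
        self._k = 0

    def step(self, frame) -> np.ndarray:
        """Push one frame, return the frame from ``delay/dt`` steps ago."""
        L = self.steps + 1
        self._buf[self._k % L] = frame
        out = self._buf[(self._k - self.steps) % L].copy()
        self._k += 1
        return out


def build_topology(
    n_sens: int,
    n_tim: int,
    p_con: float,
    w0: tuple[float, float],
    rng: np.random.Generator,
    n_joints: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Random bipartite sensory->timing connectivity with initial weights.

    Each of the ``n_joints * n_sens`` sensory neurons connects to each of
    the ``n_tim`` timing neurons independently with probability ``p_con``.
    Initial weights are ``w0[j]`` for synapses from joint ``j``.  Returns
    ``(conn, w)`` of shape ``(n_joints*n_sens, n_tim)``.
    """
    n_pre = n_joints * n_sens
    conn = rng.random((n_pre, n_tim)) < p_con
    w = np.zeros((n_pre, n_tim))
    for j in range(n_joints):
        w[j * n_sens : (j + 1) * n_sens, :] = w0[j]
    w[~conn] = 0.0
    return conn, w


@dataclass
class Recording:
    """Named time-series recorded during a run, with units and a manifest."""

    series: dict[str, pd.DataFrame] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.series[name]

    def add(self, name: str, t: np.ndarray, units: str = "", **columns) -> None:
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be monotone")
        self.series[name] = pd.DataFrame({"t": t, **columns})
        self.units[name] = units

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.series.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        manifest = {"units": self.units, **self.meta}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return outdir


# --------------------------------------------------------------------------
# feed-forward protocol
# --------------------------------------------------------------------------


@njit(cache=True)
def _ff_loop(
    rng,
    n_steps,
    dt,
    a1,
    a2,
    minor_amp,
    om0,
    om1,
    sigma,
    rate_scale,
    w,
    conn,
    A_plus,
    A_minus,
    eta,
    tau_plus,
    tau_minus,
    tau_slow,
    tau_s,
    nu_tar,
    tau_rs,
    scal_mult,
    conc,
    c_ser,
    v_max,
    k_m,
    rec_every,
    out_w,
    out_conc,
):
    z_plus = np.zeros(2)
    z_slow = np.zeros(1)
    z_minus = np.zeros(1)
    nu_bar = np.zeros(1)
    pre = np.zeros(2, np.bool_)
    post = np.zeros(1, np.bool_)
    r = 0
    for k in range(n_steps):
        t = (k + 1) * dt
        s0 = np.sin(om0 * t)
        s1 = np.sin(om1 * t)
        nu0 = rate_scale * (a1 * s0 + minor_amp * s1 + sigma * rng.normal())
        nu1 = rate_scale * (a2 * s0 + minor_amp * s1 + sigma * rng.normal())
        if nu0 < 0.0:
            nu0 = 0.0
        if nu1 < 0.0:
            nu1 = 0.0
        pre[0] = rng.random() < nu0 * dt
        pre[1] = rng.random() < nu1 * dt
        nu_post = w[0, 0] * nu0 + w[1, 0] * nu1
        post[0] = rng.random() < nu_post * dt
        _triplet_kernel(
            w, conn, z_plus, z_slow, z_minus, nu_bar, pre, post, dt,
            A_plus, A_minus, eta, tau_plus, tau_minus, tau_slow, tau_s, nu_tar, tau_rs,
            scal_mult,
        )
        # raphe pathway: separate Poisson pools with the same rate program
        nr0 = rate_scale * (a1 * s0 + minor_amp * s1 + sigma * rng.normal())
        nr1 = rate_scale * (a2 * s0 + minor_amp * s1 + sigma * rng.normal())
        for j in range(2):
            nr = nr0 if j == 0 else nr1
            if nr < 0.0:
                nr = 0.0
            if rng.random() < nr * dt:
                conc[j] += c_ser
            if conc[j] > 0.0:
                conc[j] -= dt * v_max / (k_m / conc[j] + 1.0)
                if conc[j] < 0.0:
                    conc[j] = 0.0
        if (k + 1) % rec_every == 0:
            out_w[r, 0] = w[0, 0]
            out_w[r, 1] = w[1, 0]
            out_conc[r, 0] = conc[0]
            out_conc[r, 1] = conc[1]
            r += 1


def run_feedforward(cfg: ExperimentConfig) -> Recording:
    """Run the open-loop protocol; returns weight and 5-HT recordings."""
    if cfg.kind != "feedforward":
        raise ValueError("config kind must be 'feedforward'")
    rng = np.random.default_rng(cfg.seed)
    drive = cfg.drive
    a = drive.amplitudes()
    dt = cfg.dt_neural
    n_steps = int(round(cfg.duration / dt))
    rec_every = max(int(round(cfg.record_weights_every / dt)), 1)
    n_rec = n_steps // rec_every
    out_w = np.empty((n_rec, 2))
    out_conc = np.empty((n_rec, 2))
    w = np.array([[cfg.w_stdp_0[0]], [cfg.w_stdp_0[1]]])
    conn = np.ones((2, 1), dtype=np.bool_)
    conc = np.array(cfg.serotonin.conc0, dtype=float)
    p = cfg.plasticity
    s = cfg.serotonin
    t0 = time.perf_counter()
    _ff_loop(
        rng, n_steps, dt, a[0], a[1], drive.minor_amp,
        2 * np.pi * drive.f0, 2 * np.pi * drive.f1, drive.sigma, drive.rate_scale,
        w, conn,
        p.A_plus, p.A_minus, p.eta, p.tau_plus, p.tau_minus, p.tau_slow,
        p.tau_s, p.nu_tar, p.tau_rs, p.multiplicative_scaling,
        conc, s.c_ser, s.v_max, s.k_m,
        rec_every, out_w, out_conc,
    )
    t_rec = np.arange(1, n_rec + 1) * rec_every * dt
    rec = Recording(meta={"config": cfg.to_dict(), "wall_time_s": time.perf_counter() - t0})
    rec.add("weights", t_rec, "dimensionless", w1=out_w[:, 0], w2=out_w[:, 1])
    rec.add("serotonin", t_rec, "nM", conc1=out_conc[:, 0], conc2=out_conc[:, 1])
    return rec


# --------------------------------------------------------------------------
# closed-loop protocols
# --------------------------------------------------------------------------


@njit(cache=True)
def _closed_loop(
    rng,
    plant_kind,  # 0 = two-mass, 1 = leg
    n_steps,
    dt,
    ser_every,
    n_sens,
    m_sens,
    phi_ref,
    conn,
    w,
    plast_on,
    A_plus,
    A_minus,
    eta,
    tau_plus,
    tau_minus,
    tau_slow,
    tau_s,
    nu_tar,
    tau_rs,
    scal_mult,
    tau_m,
    U_rest,
    U_exc,
    U_inh,
    theta,
    tau_thr,
    tau_ampa,
    tau_nmda,
    n_inh,
    nu_ext,
    w_ext,
    d_stdp,
    d_nm,
    tau_f,
    m_f,
    motor_sign,
    ser_on,
    conc,
    wnm_fixed,
    c_ser,
    v_max,
    k_m,
    c_NM,
    m_ser,
    b_ser,
    n_ser,
    plant_params,
    plant_state,
    rec_w_every,
    rec_x_every,
    out_w,
    out_conc,
    out_rate,
    out_phi,
    out_h,
    out_contact,
):
    n_pre = conn.shape[0]
    n_tim = conn.shape[1]
    z_plus = np.zeros(n_pre)
    z_slow = np.zeros(n_tim)
    z_minus = np.zeros(n_tim)
    nu_bar = np.zeros(n_tim)
    U = np.full(n_tim, U_rest)
    g_ae = np.zeros(n_tim)
    g_ne = np.zeros(n_tim)
    g_ai = np.zeros(n_tim)
    g_ni = np.zeros(n_tim)
    refrac = np.zeros(n_tim)
    spikes = np.zeros(n_tim, np.bool_)
    exc_in = np.zeros(n_tim)
    inh_in = np.zeros(n_tim)
    L1 = d_stdp + 1
    L2 = d_nm + 1
    pre_buf = np.zeros((L1, n_pre), np.bool_)
    nm_buf = np.zeros((L2, 2))
    ser_acc = np.zeros(2)
    nubar_f = 0.0
    rw = 0
    rx = 0
    for k in range(n_steps):
        if plant_kind == 0:
            ph0 = plant_state[0] - phi_ref[0]
            ph1 = plant_state[1] - phi_ref[1]
        else:
            ph0 = plant_state[1] - phi_ref[0]
            ph1 = plant_state[2] - phi_ref[1]
        # sensory Poisson pools (rectified linear rate code)
        r0 = m_sens * ph0 if ph0 > 0.0 else 0.0
        r1 = m_sens * ph1 if ph1 > 0.0 else 0.0
        p0 = r0 * dt
        p1 = r1 * dt
        row = pre_buf[k % L1]
        for m in range(n_sens):
            row[m] = rng.random() < p0
        for m in range(n_sens, n_pre):
            row[m] = rng.random() < p1
        pre_d = pre_buf[(k - d_stdp) % L1]
        # synaptic input to the LIF pool
        for n in range(n_tim):
            exc_in[n] = 0.0
        for m in range(n_pre):
            if pre_d[m]:
                for n in range(n_tim):
                    if conn[m, n]:
                        exc_in[n] += w[m, n]
        cnt_inh = 0
        p_inh = nu_ext * dt
        for i in range(n_inh):
            if rng.random() < p_inh:
                cnt_inh += 1
        ival = w_ext * cnt_inh
        for n in range(n_tim):
            inh_in[n] = ival
        _lif_kernel(
            U, g_ae, g_ne, g_ai, g_ni, refrac, exc_in, inh_in, spikes, dt,
            tau_m, U_rest, U_exc, U_inh, theta, tau_thr, tau_ampa, tau_nmda,
        )
        if plast_on:
            _triplet_kernel(
                w, conn, z_plus, z_slow, z_minus, nu_bar, pre_d, spikes, dt,
                A_plus, A_minus, eta, tau_plus, tau_minus, tau_slow,
                tau_s, nu_tar, tau_rs, scal_mult,
            )
        cnt = 0
        for n in range(n_tim):
            if spikes[n]:
                cnt += 1
        nubar_f += (-nubar_f * dt + cnt) / tau_f
        fz = motor_sign * m_f * nubar_f
        # raphe pools and serotonin kinetics
        rr0 = b_ser + m_ser * ph0
        rr1 = b_ser + m_ser * ph1
        if rr0 < 0.0:
            rr0 = 0.0
        if rr1 < 0.0:
            rr1 = 0.0
        c0 = 0.0
        c1 = 0.0
        pr0 = rr0 * dt
        pr1 = rr1 * dt
        for i in range(n_ser):
            if rng.random() < pr0:
                c0 += 1.0
            if rng.random() < pr1:
                c1 += 1.0
        nm_buf[k % L2, 0] = c0
        nm_buf[k % L2, 1] = c1
        drow = nm_buf[(k - d_nm) % L2]
        ser_acc[0] += drow[0]
        ser_acc[1] += drow[1]
        if ser_on and (k + 1) % ser_every == 0:
            dts = dt * ser_every
            for j in range(2):
                conc[j] += c_ser * ser_acc[j]
                ser_acc[j] = 0.0
                if conc[j] > 0.0:
                    conc[j] -= dts * v_max / (k_m / conc[j] + 1.0)
                    if conc[j] < 0.0:
                        conc[j] = 0.0
        if ser_on:
            wnm0 = c_NM * conc[0]
            wnm1 = c_NM * conc[1]
        else:
            wnm0 = wnm_fixed[0]
            wnm1 = wnm_fixed[1]
        # plant step under zero-order-hold motor signal
        contact = False
        if plant_kind == 0:
            mm = plant_params[0]
            k0_ = plant_params[1]
            k1_ = plant_params[2]
            d0_ = plant_params[3]
            f0 = wnm0 * fz
            f1 = wnm1 * fz
            q0 = plant_state[0]
            q1 = plant_state[1]
            v0 = plant_state[2]
            v1 = plant_state[3]
            a0 = -(d0_ / mm) * v0 - ((k0_ + k1_) / mm) * q0 + (k1_ / mm) * q1 + f0 / mm
            a1 = -(d0_ / mm) * v1 + (k1_ / mm) * q0 - ((k0_ + k1_) / mm) * q1 + f1 / mm
            v0 += a0 * dt
            v1 += a1 * dt
            plant_state[2] = v0
            plant_state[3] = v1
            plant_state[0] = q0 + v0 * dt
            plant_state[1] = q1 + v1 * dt
        else:
            y = _leg_rk4_act(
                plant_state, wnm0 * fz, wnm1 * fz, dt,
                plant_params[0], plant_params[1], plant_params[2], plant_params[3],
                plant_params[4], plant_params[5], plant_params[6], plant_params[7],
                plant_params[8], plant_params[9], plant_params[10],
                plant_params[11], plant_params[12], plant_params[13],
                plant_params[14], plant_params[15], plant_params[16],
            )
            for i in range(6):
                plant_state[i] = y[i]
            xf, zf = _foot_pos(y[0], y[1], y[2], plant_params[2])
            contact = zf < plant_params[13]
        # recordings
        if (k + 1) % rec_w_every == 0:
            s0 = 0.0
            n0 = 0
            s1 = 0.0
            n1 = 0
            for m in range(n_pre):
                for n in range(n_tim):
                    if conn[m, n]:
                        if m < n_sens:
                            s0 += w[m, n]
                            n0 += 1
                        else:
                            s1 += w[m, n]
                            n1 += 1
            out_w[rw, 0] = s0 / n0 if n0 > 0 else 0.0
            out_w[rw, 1] = s1 / n1 if n1 > 0 else 0.0
            out_conc[rw, 0] = conc[0] if ser_on else wnm_fixed[0] / c_NM
            out_conc[rw, 1] = conc[1] if ser_on else wnm_fixed[1] / c_NM
            out_rate[rw] = nubar_f
            rw += 1
        if (k + 1) % rec_x_every == 0:
            if plant_kind == 0:
                out_phi[rx, 0] = plant_state[0]
                out_phi[rx, 1] = plant_state[1]
                out_h[rx] = 0.0
                out_contact[rx] = 0
            else:
                out_phi[rx, 0] = plant_state[1]
                out_phi[rx, 1] = plant_state[2]
                out_h[rx] = plant_state[0]
                out_contact[rx] = 1 if contact else 0
            rx += 1
    if not (np.isfinite(plant_state[0]) and np.isfinite(nubar_f)):
        raise FloatingPointError("closed-loop simulation diverged")


def _run_closed(
    cfg: ExperimentConfig,
    plant_kind: int,
    plant_params: np.ndarray,
    plant_state: np.ndarray,
    phi_ref: np.ndarray,
    freeze_nm: bool = False,
    fixed_weights: tuple[float, float] | None = None,
    fixed_nm: tuple[float, float] | None = None,
) -> Recording:
    rng = np.random.default_rng(cfg.seed)
    net = cfg.network
    conn, w = build_topology(net.n_sens, net.n_tim, net.p_con, cfg.w_stdp_0, rng)
    plast_on = True
    if fixed_weights is not None:
        for j, val in enumerate(fixed_weights):
            w[j * net.n_sens : (j + 1) * net.n_sens, :] = val
        w[~conn] = 0.0
        plast_on = False
    dt = cfg.dt_neural
    ser_every = int(round(cfg.dt_ser / dt))
    n_steps = int(round(cfg.duration / dt))
    rec_w_every = max(int(round(cfg.record_weights_every / dt)), 1)
    rec_x_every = max(int(round(cfg.record_state_every / dt)), 1)
    n_rw = n_steps // rec_w_every
    n_rx = n_steps // rec_x_every
    out_w = np.empty((n_rw, 2))
    out_conc = np.empty((n_rw, 2))
    out_rate = np.empty(n_rw)
    out_phi = np.empty((n_rx, 2))
    out_h = np.empty(n_rx)
    out_contact = np.empty(n_rx, np.uint8)
    s = cfg.serotonin
    conc = np.array(s.conc0, dtype=float)
    ser_on = not (freeze_nm or fixed_nm is not None)
    if fixed_nm is not None:
        wnm_fixed = np.array(fixed_nm, dtype=float)
    else:
        wnm_fixed = s.c_NM * conc
    p = cfg.plasticity
    lif = cfg.lif
    d_stdp = int(round(net.tau_del_stdp / dt))
    d_nm = int(round(net.tau_del_nm / dt))
    t0 = time.perf_counter()
    _closed_loop(
        rng, plant_kind, n_steps, dt, ser_every,
        net.n_sens, net.m_sens, phi_ref,
        conn, w, plast_on,
        p.A_plus, p.A_minus, p.eta, p.tau_plus, p.tau_minus, p.tau_slow,
        p.tau_s, p.nu_tar, p.tau_rs, p.multiplicative_scaling,
        lif.tau_m, lif.U_rest, lif.U_exc, lif.U_inh, lif.theta, lif.tau_thr,
        lif.tau_ampa, lif.tau_nmda,
        net.n_inh, net.nu_ext, net.w_ext,
        d_stdp, d_nm,
        cfg.tau_f, cfg.m_f, cfg.motor_sign,
        ser_on, conc, wnm_fixed,
        s.c_ser, s.v_max, s.k_m, s.c_NM, s.m_ser, s.b_ser, net.n_ser,
        plant_params, plant_state,
        rec_w_every, rec_x_every,
        out_w, out_conc, out_rate, out_phi, out_h, out_contact,
    )
    t_w = np.arange(1, n_rw + 1) * rec_w_every * dt
    t_x = np.arange(1, n_rx + 1) * rec_x_every * dt
    rec = Recording(
        meta={"config": cfg.to_dict(), "wall_time_s": time.perf_counter() - t0}
    )
    rec.add("weights", t_w, "dimensionless", w1=out_w[:, 0], w2=out_w[:, 1])
    rec.add("serotonin", t_w, "nM", conc1=out_conc[:, 0], conc2=out_conc[:, 1])
    rec.add("rate", t_w, "Hz", nu_bar_post=out_rate)
    if plant_kind == 0:
        rec.add("trajectory", t_x, "m", phi1=out_phi[:, 0], phi2=out_phi[:, 1])
    else:
        rec.add("trajectory", t_x, "rad", phi1=out_phi[:, 0], phi2=out_phi[:, 1])
        rec.add("trunk", t_x, "m", h=out_h, contact=out_contact.astype(bool))
    return rec


def run_two_mass(cfg: ExperimentConfig, freeze_nm: bool = False) -> Recording:
    """Run the closed loop around the two-mass plant.

    ``freeze_nm=True`` holds the neuromodulatory gains at their initial
    values (the serotonergic negative control).
    """
    if cfg.kind != "two_mass":
        raise ValueError("config kind must be 'two_mass'")
    tm = cfg.two_mass
    params = np.array([tm.m, tm.k0, tm.k1, tm.d0])
    state = np.array([tm.phi[0], tm.phi[1], tm.dphi[0], tm.dphi[1]])
    return _run_closed(cfg, 0, params, state, np.zeros(2), freeze_nm=freeze_nm)


def run_leg(
    cfg: ExperimentConfig,
    fixed_weights: tuple[float, float] | None = None,
    fixed_nm: tuple[float, float] | None = None,
) -> Recording:
    """Run the closed loop around the hopping leg.

    ``fixed_weights``/``fixed_nm`` freeze the synaptic weights (per-joint
    values, plasticity off) and the neuromodulatory gains, as used in the
    fixed-ratio energy-efficiency sweep.
    """
    if cfg.kind != "leg":
        raise ValueError("config kind must be 'leg'")
    leg = cfg.leg
    c = leg.contact
    params = np.array(
        [
            leg.m0, leg.m1, leg.l, leg.g, leg.k0, leg.k1, leg.d0, leg.d1,
            leg.phi0[0], leg.phi0[1],
            c.stiffness, c.damping, c.friction, c.ground_height,
            leg.stop_stiffness, leg.stop_damping, leg.stop_angle,
        ]
    )
    state = np.array([leg.h, leg.phi[0], leg.phi[1], *leg.v])
    # proprioceptors encode the elastic deflection phi - phi0 (spring
    # stretch), the analogue of the two-mass deviation from equilibrium
    return _run_closed(
        cfg, 1, params, state, leg.phi0.copy(),
        fixed_weights=fixed_weights, fixed_nm=fixed_nm,
    )
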