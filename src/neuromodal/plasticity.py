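"""Triplet spike-timing-dependent plasticity with synaptic scaling.

The sensory->interneuron weights follow the minimal triplet rule of
Pfister & Gerstner (2006) in the formulation of Zenke, Agnes & Gerstner
(2015): potentiation is gated by postsynaptic spikes and proportional to
the presynaptic fast trace ``z_plus`` times the postsynaptic slow trace
``z_slow`` evaluated just before the triggering spike (offset ``eps``);
depression is gated by presynaptic spikes and proportional to the
postsynaptic trace ``z_minus``.  The triplet dependence on ``z_slow``
makes potentiation grow with pairing frequency.  A homeostatic synaptic
scaling term with quadratic rate dependence,

    dw_scal/dt = (1 / (tau_s * nu_tar)) * (nu_tar - nu_bar**2 / nu_tar),

drifts all weights of a postsynaptic neuron so its low-pass filtered rate
``nu_bar`` (time constant ``tau_rs``) approaches the target ``nu_tar``;
the term vanishes identically at ``nu_bar == nu_tar``, is positive below
and negative above.  Weights are clipped at zero.

Trace time constants default to the published triplet-model values
(tau_plus = 16.8 ms, tau_minus = 33.7 ms, tau_slow = 114 ms); amplitudes
default to the reduced values used for slow in-vivo-like learning.  The
conversion factor ``eta`` is unity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "TripletParams",
    "TripletSynapses",
    "trace_step",
    "stdp_step",
    "scaling_term",
]


@dataclass
class TripletParams:
    """Constants of the triplet STDP rule and the homeostatic scaling term."""

    A_plus: float = 6.5e-5
    A_minus: float = 1.1e-5
    eta: float = 1.0
    tau_plus: float = 16.8e-3
    tau_minus: float = 33.7e-3
    tau_slow: float = 114e-3
    eps: float = 1e-3
    tau_s: float = 50.0
    nu_tar: float = 8.0
    tau_rs: float = 5.0
    multiplicative_scaling: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_plus", "tau_minus", "tau_slow", "tau_s", "nu_tar", "tau_rs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "TripletParams":
        """Speed the rule up by ``factor`` by raising the STDP amplitudes.

        The default amplitudes are reduced by two orders of magnitude from
        the cited triplet model to reproduce in-vivo learning time scales
        of hours; multiplying them back up (``factor`` = 100 restores the
        original model values) compresses the synaptic convergence time by
        the same factor so that protocols fit desk-scale runs.  The
        homeostatic constants are deliberately untouched: they set the
        stable operating rate of the postsynaptic pool, not the learning
        time scale.
        """
        return replace(
            self,
            A_plus=self.A_plus * factor,
            A_minus=self.A_minus * factor,
        )


def scaling_term(nu_bar, params: TripletParams):
    """Homeostatic weight drift (1/s) for a filtered postsynaptic rate."""
    nu_bar = np.asarray(nu_bar, dtype=float)
    out = (params.nu_tar - nu_bar**2 / params.nu_tar) / (params.tau_s * params.nu_tar)
    return float(out) if out.ndim == 0 else out


def trace_step(traces: np.ndarray, spikes, tau: float, dt: float) -> np.ndarray:
    """Advance exponential spike traces in place: decay then unit increments."""
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    traces -= traces * dt / tau
    traces += np.asarray(spikes, dtype=float)
    return traces


@njit(cache=True)
def _triplet_kernel(
    w,
    conn,
    z_plus,
    z_slow,
    z_minus,
    nu_bar,
    pre_spikes,
    post_spikes,
    dt,
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
):
    n_pre = w.shape[0]
    n_post = w.shape[1]
    # decay traces
    for m in range(n_pre):
        z_plus[m] -= z_plus[m] * dt / tau_plus
    for n in range(n_post):
        z_slow[n] -= z_slow[n] * dt / tau_slow
        z_minus[n] -= z_minus[n] * dt / tau_minus
    # presynaptic traces include same-step spikes before LTP is evaluated;
    # postsynaptic traces are incremented afterwards, which realizes the
    # eps-offset exclusion of the triggering spike from z_slow.
    for m in range(n_pre):
        if pre_spikes[m]:
            z_plus[m] += 1.0
    # LTD at presynaptic spikes, LTP at postsynaptic spikes
    for m in range(n_pre):
        if pre_spikes[m]:
            for n in range(n_post):
                if conn[m, n]:
                    w[m, n] -= eta * A_minus * z_minus[n]
    for n in range(n_post):
        if post_spikes[n]:
            ltp = eta * A_plus * z_slow[n]
            for m in range(n_pre):
                if conn[m, n]:
                    w[m, n] += ltp * z_plus[m]
    for n in range(n_post):
        if post_spikes[n]:
            z_slow[n] += 1.0
            z_minus[n] += 1.0
    # continuous synaptic scaling + clip, and the postsynaptic rate filter
    for n in range(n_post):
        drift = (nu_tar - nu_bar[n] * nu_bar[n] / nu_tar) / (tau_s * nu_tar) * dt
        for m in range(n_pre):
            if conn[m, n]:
                wn = w[m, n] + (drift * w[m, n] if scal_mult else drift)
                w[m, n] = wn if wn > 0.0 else 0.0
        s = 1.0 if post_spikes[n] else 0.0
        nu_bar[n] += (-nu_bar[n] * dt + s) / tau_rs


class TripletSynapses:
    """A plastic pre x post weight matrix with its traces and homeostat.

    Parameters
    ----------
    w0
        Initial weight matrix, shape ``(n_pre, n_post)``; entries where
        ``conn`` is False are ignored.
    params
        Rule constants.
    conn
        Boolean connectivity mask (default: fully connected).
    """

    def __init__(
        self,
        w0: np.ndarray,
        params: TripletParams | None = None,
        conn: np.ndarray | None = None,
    ):
        self.w = np.array(w0, dtype=float, ndmin=2)
        if np.any(self.w < 0):
            raise ValueError("initial weights must be non-negative")
        self.params = params if params is not None else TripletParams()
        n_pre, n_post = self.w.shape
        self.conn = (
            np.ones((n_pre, n_post), dtype=np.bool_)
            if conn is None
            else np.asarray(conn, dtype=np.bool_)
        )
        if self.conn.shape != self.w.shape:
            raise ValueError("conn mask shape must match w0")
        self.z_plus = np.zeros(n_pre)
        self.z_slow = np.zeros(n_post)
        self.z_minus = np.zeros(n_post)
        self.nu_bar = np.zeros(n_post)

    @property
    def n_pre(self) -> int:
        return self.w.shape[0]

    @property
    def n_post(self) -> int:
        return self.w.shape[1]

    def step(self, pre_spikes, post_spikes, dt: float) -> None:
        """Advance traces, apply LTP/LTD and scaling for one step."""
        p = self.params
        _triplet_kernel(
            self.w,
            self.conn,
            self.z_plus,
            self.z_slow,
            self.z_minus,
            self.nu_bar,
            np.ascontiguousarray(pre_spikes, dtype=np.bool_),
            np.ascontiguousarray(post_spikes, dtype=np.bool_),
            dt,
            p.A_plus,
            p.A_minus,
            p.eta,
            p.tau_plus,
            p.tau_minus,
            p.tau_slow,
            p.tau_s,
            p.nu_tar,
            p.tau_rs,
            p.multiplicative_scaling,
        )


def stdp_step(syn: TripletSynapses, pre_spikes, post_spikes, dt: float) -> np.ndarray:
    """Advance the synapse object one step and return the weight increments."""
    before = syn.w.copy()
    syn.step(pre_spikes, post_spikes, dt)
    return syn.w - before
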