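"""Poisson and conductance-based leaky integrate-and-fire neuron pools.

Spiking is simulated on a fixed grid of width ``dt``.  A Poisson neuron
with instantaneous rate ``nu`` emits a spike in a step with probability
``nu * dt`` (the Bernoulli approximation of a Poisson count, valid for
``nu * dt`` well below one).  LIF neurons integrate excitatory and
inhibitory conductances, each modeled as a fast (AMPA-like) exponential
stage followed by a slow (NMDA-like) low-pass stage; the effective
conductance is the mean of the two stages.  A spike resets the membrane to
rest and clamps it there for an absolute refractory period ``tau_thr``,
which caps the firing rate at ``1 / tau_thr``.

LIF constants default to the published values of the conductance-based
model of Zenke, Agnes & Gerstner (2015) from which the neuron equations
are adopted; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "LIFParams",
    "LIFPool",
    "PoissonPool",
    "SensoryEncoderParams",
    "poisson_spikes",
    "encode_joint_deflection",
    "conductance_step",
    "lif_step",
    "rate_lowpass",
    "spikes_to_text",
]


@dataclass
class LIFParams:
    """Leaky integrate-and-fire constants (SI units: s, V).

    Invariant: ``U_inh <= U_rest < theta < U_exc`` and all time constants
    positive.
    """

    tau_m: float = 20e-3
    U_rest: float = -60e-3
    U_exc: float = 0.0
    U_inh: float = -80e-3
    theta: float = -50e-3
    tau_thr: float = 5e-3
    tau_ampa: float = 5e-3
    tau_nmda: float = 100e-3

    def __post_init__(self) -> None:
        if not (self.U_inh <= self.U_rest < self.theta < self.U_exc):
            raise ValueError("require U_inh <= U_rest < theta < U_exc")
        for name in ("tau_m", "tau_thr", "tau_ampa", "tau_nmda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SensoryEncoderParams:
    """Rate coding of a joint deflection: ``nu = m_sens * phi`` for ``phi > 0``."""

    m_sens: float
    n_sens: int = 1

    def __post_init__(self) -> None:
        if self.m_sens <= 0:
            raise ValueError("m_sens must be positive")
        if self.n_sens < 1:
            raise ValueError("n_sens must be >= 1")


def encode_joint_deflection(phi, params: SensoryEncoderParams):
    """Half-wave rectified linear rate code, in Hz (zero for ``phi <= 0``)."""
    phi = np.asarray(phi, dtype=float)
    rate = np.where(phi > 0.0, params.m_sens * phi, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def poisson_spikes(rates, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one step of Bernoulli spikes for a pool of Poisson neurons.

    Negative requested rates behave as silence.  Raises ``ValueError`` if
    any ``rate * dt >= 1`` (the per-step Bernoulli discretization is then
    invalid).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = np.clip(np.asarray(rates, dtype=float) * dt, 0.0, None)
    if np.any(p >= 1.0):
        raise ValueError("rate*dt >= 1: decrease dt for this firing rate")
    return rng.random(p.shape) < p


class PoissonPool:
    """A pool of independent Poisson neurons with a shared rate program."""

    def __init__(self, n: int, rate: float | np.ndarray = 0.0):
        if n < 1:
            raise ValueError("pool size must be >= 1")
        self.n = n
        self.rate = np.broadcast_to(np.asarray(rate, dtype=float), (n,)).copy()

    def step(self, dt: float, rng: np.random.Generator) -> np.ndarray:
        return poisson_spikes(self.rate, dt, rng)


@njit(cache=True)
def _conductance_kernel(g_ampa, g_nmda, incoming, dt, tau_ampa, tau_nmda):
    n = g_ampa.shape[0]
    for i in range(n):
        g_ampa[i] += incoming[i]
        g_ampa[i] -= g_ampa[i] * dt / tau_ampa
        g_nmda[i] += (g_ampa[i] - g_nmda[i]) * dt / tau_nmda


@njit(cache=True)
def _lif_kernel(
    U,
    g_ampa_exc,
    g_nmda_exc,
    g_ampa_inh,
    g_nmda_inh,
    refrac,
    exc_in,
    inh_in,
    spikes,
    dt,
    tau_m,
    U_rest,
    U_exc,
    U_inh,
    theta,
    tau_thr,
    tau_ampa,
    tau_nmda,
):
    n = U.shape[0]
    for i in range(n):
        # 1) deliver spikes to conductances, 2) integrate, 3) detect, 4) reset
        g_ampa_exc[i] += exc_in[i]
        g_ampa_exc[i] -= g_ampa_exc[i] * dt / tau_ampa
        g_nmda_exc[i] += (g_ampa_exc[i] - g_nmda_exc[i]) * dt / tau_nmda
        g_ampa_inh[i] += inh_in[i]
        g_ampa_inh[i] -= g_ampa_inh[i] * dt / tau_ampa
        g_nmda_inh[i] += (g_ampa_inh[i] - g_nmda_inh[i]) * dt / tau_nmda
        spikes[i] = False
        if refrac[i] > 0.0:
            refrac[i] -= dt
            U[i] = U_rest
            continue
        g_exc = 0.5 * (g_ampa_exc[i] + g_nmda_exc[i])
        g_inh = 0.5 * (g_ampa_inh[i] + g_nmda_inh[i])
        dU = (
            (U_rest - U[i]) + g_exc * (U_exc - U[i]) + g_inh * (U_inh - U[i])
        ) / tau_m
        U[i] += dU * dt
        if U[i] > theta:
            spikes[i] = True
            U[i] = U_rest
            refrac[i] = tau_thr


class LIFPool:
    """A pool of conductance-based LIF neurons.

    State arrays (membrane voltage, four conductance stages, remaining
    refractory time) are kept per neuron; :meth:`step` advances one Euler
    step and returns the boolean spike indicators.
    """

    def __init__(self, n: int, params: LIFParams | None = None):
        if n < 1:
            raise ValueError("pool size must be >= 1")
        self.n = n
        self.params = params if params is not None else LIFParams()
        self.U = np.full(n, self.params.U_rest)
        self.g_ampa_exc = np.zeros(n)
        self.g_nmda_exc = np.zeros(n)
        self.g_ampa_inh = np.zeros(n)
        self.g_nmda_inh = np.zeros(n)
        self.refractory_remaining = np.zeros(n)
        self._spikes = np.zeros(n, dtype=np.bool_)

    def step(self, exc_in, inh_in, dt: float) -> np.ndarray:
        """Advance one step given per-neuron summed presynaptic weights.

        ``exc_in``/``inh_in`` are the summed synaptic weights of spikes
        arriving at each neuron in this step (conductance jump heights).
        Negative excitatory input is rejected.
        """
        exc_in = np.broadcast_to(np.asarray(exc_in, dtype=float), (self.n,))
        inh_in = np.broadcast_to(np.asarray(inh_in, dtype=float), (self.n,))
        if np.any(exc_in < 0) or np.any(inh_in < 0):
            raise ValueError("negative weight on a conductance channel")
        p = self.params
        _lif_kernel(
            self.U,
            self.g_ampa_exc,
            self.g_nmda_exc,
            self.g_ampa_inh,
            self.g_nmda_inh,
            self.refractory_remaining,
            np.ascontiguousarray(exc_in),
            np.ascontiguousarray(inh_in),
            self._spikes,
            dt,
            p.tau_m,
            p.U_rest,
            p.U_exc,
            p.U_inh,
            p.theta,
            p.tau_thr,
            p.tau_ampa,
            p.tau_nmda,
        )
        return self._spikes.copy()


def conductance_step(
    g_ampa: np.ndarray,
    g_nmda: np.ndarray,
    incoming,
    dt: float,
    tau_ampa: float = 5e-3,
    tau_nmda: float = 100e-3,
) -> np.ndarray:
    """Advance the two-stage conductance cascade in place.

    ``g_ampa`` jumps by the summed presynaptic weights ``incoming`` and
    decays with ``tau_ampa``; ``g_nmda`` is its first-order low-pass with
    ``tau_nmda``.  Returns the effective conductance ``(g_ampa+g_nmda)/2``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    incoming = np.broadcast_to(np.asarray(incoming, dtype=float), g_ampa.shape)
    if np.any(incoming < 0):
        raise ValueError("negative weight on an excitatory channel")
    _conductance_kernel(
        g_ampa, g_nmda, np.ascontiguousarray(incoming), dt, tau_ampa, tau_nmda
    )
    return 0.5 * (g_ampa + g_nmda)


def lif_step(pool: LIFPool, exc_in, inh_in, dt: float) -> np.ndarray:
    """Functional alias for :meth:`LIFPool.step`."""
    return pool.step(exc_in, inh_in, dt)


def rate_lowpass(spikes: np.ndarray, tau: float, dt: float, nu0: float = 0.0):
    """Low-pass filter a spike-count sequence into a rate trace (Hz).

    Implements ``tau * dnu/dt = -nu + S(t)`` where each spike is an
    impulse of unit area, i.e. one spike raises the trace by ``1/tau``
    (up to the Euler factor).  ``spikes`` is a per-step count (or boolean)
    array; returns the filtered trace sampled after each step.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    spikes = np.asarray(spikes, dtype=float)
    out = np.empty_like(spikes)
    nu = float(nu0)
    decay = dt / tau
    for k in range(spikes.shape[0]):
        nu += -nu * decay + spikes[k] / tau
        out[k] = nu
    return out


def spikes_to_text(times, neuron_ids) -> str:
    """Render a spike log as two-column ``time<TAB>neuron`` text."""
    lines = ["time\tneuron"]
    for t, n in zip(np.asarray(times), np.asarray(neuron_ids)):
        lines.append(f"{t:.6f}\t{int(n)}")
    return "\n".join(lines) + "\n"
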