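"""Serotonergic output pathway: raphe rate coding, 5-HT release and clearance.

Each joint has a pool of serotonergic (raphe) Poisson neurons whose rate is
linearly related to the joint deflection, ``nu = b_ser + m_ser * phi``
above the rectification point and zero below.  Every raphe spike releases a
fixed amount ``c_ser`` of serotonin into the motorpool of that joint; the
extracellular concentration is cleared by Michaelis-Menten kinetics,

    d[5-HT]/dt = c_ser * S(t) - v_max / (k_m / [5-HT] + 1).

For concentrations well below the Michaelis constant the clearance is
first order with effective time constant ``tau_eff = k_m / v_max``, which
turns the pathway into a leaky integrator of the sensory rate -- the
Hebb-with-decay rule of :mod:`neuromodal.controller`.  The concentration
multiplicatively scales the motor gain of its joint, ``w_NM = c_NM [5-HT]``.

Units: concentrations are kept in nM, release increments in nM/spike,
``v_max`` in nM/s, ``c_NM`` in 1/nM.  The printed clearance constant for
the modeled system is dimensionally ambiguous; the default ``v_max`` of
100 nM/s (0.1 uM/s) is chosen to match reported in-vivo clearance and to
keep concentrations in the physiological 10-100 nM band.  It is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SerotoninPool", "RapheEncoderParams", "raphe_rate", "serotonin_step", "nm_weights"]


@dataclass
class RapheEncoderParams:
    """Linear rate code of the raphe pool for one joint."""

    m_ser: float
    b_ser: float = 0.0
    n_ser: int = 10

    def __post_init__(self) -> None:
        if self.n_ser < 1:
            raise ValueError("n_ser must be >= 1")


def raphe_rate(phi, params: RapheEncoderParams):
    """Rectified linear raphe rate: ``b_ser + m_ser*phi`` where positive, else 0."""
    phi = np.asarray(phi, dtype=float)
    rate = params.b_ser + params.m_ser * phi
    rate = np.where(rate > 0.0, rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


@dataclass
class SerotoninPool:
    """Extracellular 5-HT concentration per joint with its kinetic constants.

    ``conc`` is the per-joint concentration vector (nM, never negative).
    ``c_ser`` is the release per raphe spike (nM), ``v_max`` the maximal
    clearance rate (nM/s), ``k_m`` the Michaelis constant (nM) and ``c_NM``
    the motor gain per unit concentration (1/nM).
    """

    conc: np.ndarray
    c_ser: float
    v_max: float = 100.0
    k_m: float = 170.0
    c_NM: float = 0.015

    def __post_init__(self) -> None:
        self.conc = np.atleast_1d(np.asarray(self.conc, dtype=float))
        if np.any(self.conc < 0):
            raise ValueError("initial concentrations must be non-negative")
        if self.v_max <= 0 or self.k_m <= 0:
            raise ValueError("v_max and k_m must be positive")

    @property
    def tau_eff(self) -> float:
        """Low-concentration clearance time constant ``k_m / v_max`` (s)."""
        return self.k_m / self.v_max

    def step(self, raphe_spike_counts, dt: float) -> np.ndarray:
        return serotonin_step(self, raphe_spike_counts, dt)

    def gains(self) -> np.ndarray:
        return nm_weights(self)


def serotonin_step(pool: SerotoninPool, raphe_spike_counts, dt: float) -> np.ndarray:
    """Advance the concentration one Euler step.

    ``raphe_spike_counts`` is the number of raphe spikes per joint in this
    step (release happens first, then clearance).  The concentration is
    floored at zero, so the clearance rate never exceeds ``v_max`` and no
    negative concentrations can arise for any spike input.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    counts = np.broadcast_to(
        np.asarray(raphe_spike_counts, dtype=float), pool.conc.shape
    )
    pool.conc = pool.conc + pool.c_ser * counts
    with np.errstate(divide="ignore"):
        clear = np.where(
            pool.conc > 0.0, pool.v_max / (pool.k_m / pool.conc + 1.0), 0.0
        )
    pool.conc = np.maximum(pool.conc - clear * dt, 0.0)
    return pool.conc


def nm_weights(pool: SerotoninPool) -> np.ndarray:
    """Multiplicative per-joint motor gains ``c_NM * [5-HT]``."""
    return pool.c_NM * pool.conc
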