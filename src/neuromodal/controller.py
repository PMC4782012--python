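"""Abstract modal controller: coordinate transformation and weight adaptation.

This module is the rate-level reference ("oracle") for the spiking network.
A multi-joint movement, observed through the joint-deflection vector
``phi``, is projected onto a single controller coordinate

    phi_z = w . phi,

a two-valued (bang-bang) unit produces a timing/force signal from phi_z,
and the scalar output is expanded back into joint space by the same weight
vector.  The weights ``w`` adapt online, either by Oja's rule -- Hebbian
learning with multiplicative normalization, whose fixed point is the
dominant eigenvector of the input covariance -- or by a simplified
Hebb-with-decay rule that aligns with the same direction whenever inputs
and weights are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ControllerWeights",
    "BangBangParams",
    "project_input",
    "bang_bang",
    "expand_output",
    "oja_step",
    "hebb_decay_step",
]


@dataclass
class ControllerWeights:
    """Per-joint transformation weights and their learning constants.

    Parameters
    ----------
    w
        Weight vector, one entry per joint (dimensionless).  Initialized
        strictly positive; the adaptation rules never clip it.
    gamma
        Oja learning rate (1 / (s * input unit^2)).  Must satisfy
        ``gamma * dt << 1`` for the explicit Euler updates used here.
    c_w
        Drive gain of the simplified Hebb-with-decay rule (1/s per input
        unit).
    tau_eff
        Decay time constant of the simplified rule (s).
    """

    w: np.ndarray
    gamma: float = 0.01
    c_w: float = 1.0
    tau_eff: float = 1.0

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if self.w.ndim != 1 or self.w.size < 1:
            raise ValueError("w must be a 1-D vector with at least one joint")


@dataclass
class BangBangParams:
    """Constants of the two-valued switching unit.

    ``c_f_hat`` is the force magnitude emitted while the controller
    coordinate exceeds the switching threshold ``c_eps``; both must be
    positive.  The spiking implementation replaces this unit by an
    integrate-and-fire pool, so these values only parameterize the
    rate-level oracle.
    """

    c_f_hat: float = 1.0
    c_eps: float = 0.01

    def __post_init__(self) -> None:
        if self.c_f_hat <= 0 or self.c_eps <= 0:
            raise ValueError("c_f_hat and c_eps must be positive")


def project_input(weights: ControllerWeights, phi: np.ndarray) -> float:
    """Project joint deflections onto the one-dimensional controller space.

    Returns the inner product ``w . phi``.  Raises ``ValueError`` on a
    dimension mismatch.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != weights.w.shape:
        raise ValueError(
            f"dimension mismatch: w has shape {weights.w.shape}, phi {phi.shape}"
        )
    return float(weights.w @ phi)


def bang_bang(phi_z: float, params: BangBangParams) -> float:
    """Two-valued switching output: ``c_f_hat`` iff ``phi_z > c_eps`` (strict)."""
    return params.c_f_hat if phi_z > params.c_eps else 0.0


def expand_output(weights: ControllerWeights, f_z: float) -> np.ndarray:
    """Expand the scalar drive back into joint space: ``f = w * f_z``."""
    return weights.w * float(f_z)


def oja_step(weights: ControllerWeights, phi: np.ndarray, dt: float) -> np.ndarray:
    """One explicit-Euler step of Oja's principal-component rule.

        dw/dt = gamma * (w.phi) * (phi - (w.phi) w)

    The multiplicative decay keeps ``||w||`` bounded (it converges to 1 for
    stationary input), and the fixed-point direction is the dominant
    eigenvector of the input covariance.  Returns the updated weight vector
    (also stored back on ``weights``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = project_input(weights, phi)
    phi = np.asarray(phi, dtype=float)
    weights.w = weights.w + weights.gamma * y * (phi - y * weights.w) * dt
    if not np.all(np.isfinite(weights.w)):
        raise FloatingPointError("Oja update diverged; reduce gamma*dt")
    return weights.w


def hebb_decay_step(
    weights: ControllerWeights, phi: np.ndarray, dt: float
) -> np.ndarray:
    """One explicit-Euler step of the simplified Hebb-with-decay rule.

        dw/dt = c_w * phi - w / tau_eff

    For non-negative input streams this rule converges to the fixed point
    ``c_w * tau_eff * <phi>`` and therefore aligns with the same direction
    as :func:`oja_step` whenever the input components oscillate in phase.
    This is the rate-level abstraction of the serotonergic output pathway.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    phi = np.asarray(phi, dtype=float)
    if phi.shape != weights.w.shape:
        raise ValueError("dimension mismatch between w and phi")
    weights.w = weights.w + (weights.c_w * phi - weights.w / weights.tau_eff) * dt
    return weights.w
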