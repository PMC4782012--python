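"""Experiment configurations mirroring the three study protocols.

Three protocols are provided as factory functions:

``feedforward_config``
    Two sensory Poisson neurons with in-phase sinusoidal rate programs of
    amplitude ratio ``a1/a2`` drive one plastic postsynaptic Poisson
    neuron (input pathway) and two raphe neurons releasing serotonin into
    separate pools (output pathway).  No mechanics.
``two_mass_config``
    Full closed loop around the linear two-mass oscillator: 290 sensory
    Poisson neurons per joint, one LIF timing neuron, no delays.
``leg_config``
    Full closed loop around the hopping leg: 130 sensory neurons per
    joint, six LIF neurons, 100 external inhibitory Poisson neurons,
    sensory delay 30 ms and serotonergic delay 200 ms.  ``large=True``
    triples the sensory pools and doubles the LIF pool while scaling the
    initial synaptic weights and ``c_NM`` down by the same factors, which
    keeps drive and motor signal comparable.

Desk-scale protocol
-------------------
The full-length protocols span 1.7-17 h of simulated time because the
plasticity amplitudes are reduced to in-vivo learning rates.  The
default configurations compress the synaptic time scale by a documented
``speedup`` factor and divide durations accordingly: the feed-forward
protocol multiplies the STDP amplitudes by 10 (its rate-coupled Poisson
output saturates nowhere, so stronger compression destabilizes it), the
two-mass protocol multiplies them by 100, and the leg protocol
multiplies them by 100 while also dividing its homeostatic time
constants (tau_s, tau_rs) by 100 to preserve the LTP/scaling weight
fixed point (the leg's printed tau_s is two orders of magnitude longer
than the other protocols').  Serotonergic dynamics converge in seconds
and are never scaled.  Pass ``speedup=1`` for the full-length
protocols; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mechanics import ContactParams, LegModel, TwoMassModel
from .neurons import LIFParams
from .plasticity import TripletParams

__all__ = [
    "NetworkConfig",
    "SerotoninConfig",
    "DriveConfig",
    "ExperimentConfig",
    "feedforward_config",
    "two_mass_config",
    "leg_config",
]


@dataclass
class NetworkConfig:
    """Topology and rate-coding constants of the spiking controller."""

    n_sens: int = 1
    n_tim: int = 1
    n_inh: int = 0
    n_ser: int = 1
    p_con: float = 1.0
    w_ext: float = 0.1
    nu_ext: float = 3.0
    tau_del_stdp: float = 0.0
    tau_del_nm: float = 0.0
    m_sens: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_con <= 1.0):
            raise ValueError("p_con must lie in [0, 1]")


@dataclass
class SerotoninConfig:
    """Raphe encoding and 5-HT kinetics (concentrations in nM)."""

    conc0: tuple[float, float] = (17.0, 17.0)
    c_ser: float = 0.3
    v_max: float = 100.0
    k_m: float = 170.0
    c_NM_per_uM: float = 15.0
    m_ser: float = 9.0
    b_ser: float = 0.0

    @property
    def c_NM(self) -> float:
        """Gain per nM of concentration."""
        return self.c_NM_per_uM * 1e-3


@dataclass
class DriveConfig:
    """Sinusoidal rate program of the feed-forward protocol (Hz scale).

    ``nu_i = rate_scale * (a_i sin(2 pi f0 t) + minor_amp sin(2 pi f1 t)
    + n(sigma))`` with negative rates clamped to zero and ``||a|| = 1``.
    """

    a_ratio: float = 0.3
    rate_scale: float = 40.0
    f0: float = 1.0
    minor_amp: float = 0.05
    f1: float = 4.0
    sigma: float = 0.1

    def amplitudes(self) -> np.ndarray:
        a = np.array([self.a_ratio, 1.0])
        return a / np.linalg.norm(a)


@dataclass
class ExperimentConfig:
    """Complete description of one simulation run."""

    kind: str  # "feedforward" | "two_mass" | "leg"
    duration: float
    dt_neural: float
    dt_ser: float
    seed: int = 0
    speedup: float = 100.0
    record_weights_every: float = 1.0
    record_state_every: float = 1e-3
    #: motor polarity: -1 realizes a stretch reflex (force opposes the
    #: sensed deflection); with the conduction/filter lag this pumps energy
    #: into the resonance, while +1 would damp it.
    m_f: float = 0.0
    tau_f: float = 0.1
    motor_sign: float = -1.0
    w_stdp_0: tuple[float, float] = (0.5, 0.5)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    plasticity: TripletParams = field(default_factory=TripletParams)
    serotonin: SerotoninConfig = field(default_factory=SerotoninConfig)
    lif: LIFParams = field(default_factory=LIFParams)
    drive: DriveConfig | None = None
    two_mass: TwoMassModel | None = None
    leg: LegModel | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt_neural <= 0 or self.dt_ser <= 0:
            raise ValueError("durations and time steps must be positive")
        if self.record_weights_every < self.dt_neural:
            raise ValueError("recording cadence must be >= dt")
        if round(self.dt_ser / self.dt_neural) != self.dt_ser / self.dt_neural:
            raise ValueError("dt_ser must be an integer multiple of dt_neural")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("two_mass", "leg"):
            if d[key] is not None:
                d[key] = {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in d[key].items()
                }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["network"] = NetworkConfig(**d["network"])
        d["plasticity"] = TripletParams(**d["plasticity"])
        ser = d["serotonin"]
        ser["conc0"] = tuple(ser["conc0"])
        d["serotonin"] = SerotoninConfig(**ser)
        d["lif"] = LIFParams(**d["lif"])
        d["drive"] = DriveConfig(**d["drive"]) if d.get("drive") else None
        if d.get("two_mass"):
            d["two_mass"] = TwoMassModel(**d["two_mass"])
        if d.get("leg"):
            leg = d["leg"]
            leg["contact"] = ContactParams(**leg["contact"])
            d["leg"] = LegModel(**leg)
        d["w_stdp_0"] = tuple(d["w_stdp_0"])
        return cls(**d)


def _scaled_plasticity(base: TripletParams, speedup: float) -> TripletParams:
    return base.scaled(speedup) if speedup != 1.0 else base


def feedforward_config(
    a_ratio: float = 0.3,
    sigma: float = 0.1,
    seed: int = 0,
    speedup: float = 10.0,
    duration: float | None = None,
) -> ExperimentConfig:
    """Open-loop protocol: sinusoidal Poisson drive, no mechanics."""
    plast = _scaled_plasticity(
        TripletParams(tau_s=50.0, nu_tar=8.0, tau_rs=5.0), speedup
    )
    return ExperimentConfig(
        kind="feedforward",
        duration=duration if duration is not None else 60_000.0 / speedup,
        dt_neural=1e-3,
        dt_ser=1e-3,
        seed=seed,
        speedup=speedup,
        record_weights_every=max(1.0 / speedup, 1e-2),
        record_state_every=1e-1,
        w_stdp_0=(0.5, 0.5),
        network=NetworkConfig(n_sens=1, n_tim=1, n_inh=0, n_ser=1, p_con=1.0),
        plasticity=plast,
        serotonin=SerotoninConfig(conc0=(17.0, 17.0), c_ser=0.3),
        drive=DriveConfig(a_ratio=a_ratio, sigma=sigma),
    )


def two_mass_config(
    seed: int = 0,
    speedup: float = 100.0,
    duration: float | None = None,
    w_stdp_0: tuple[float, float] = (0.7, 0.4),
    conc0: tuple[float, float] = (50.0, 20.0),
) -> ExperimentConfig:
    """Closed loop around the linear two-mass plant."""
    plast = _scaled_plasticity(
        TripletParams(tau_s=50.0, nu_tar=30.0, tau_rs=5.0), speedup
    )
    return ExperimentConfig(
        kind="two_mass",
        duration=duration if duration is not None else 15_000.0 / speedup,
        dt_neural=1e-4,
        dt_ser=1e-3,
        seed=seed,
        speedup=speedup,
        record_weights_every=max(0.1 / speedup, 1e-2),
        record_state_every=1e-3,
        m_f=10e-3,
        tau_f=0.1,
        w_stdp_0=w_stdp_0,
        network=NetworkConfig(
            n_sens=290, n_tim=1, n_inh=0, n_ser=290, p_con=1.0, m_sens=10.0
        ),
        plasticity=plast,
        serotonin=SerotoninConfig(
            conc0=conc0, c_ser=0.04, c_NM_per_uM=15.0, m_ser=9.0, b_ser=0.9
        ),
        two_mass=TwoMassModel(phi=np.array([0.0, 0.1]), dphi=np.zeros(2)),
    )


def leg_config(
    seed: int = 0,
    speedup: float = 100.0,
    duration: float | None = None,
    large: bool = False,
    w_stdp_0: tuple[float, float] | None = None,
    conc0: tuple[float, float] = (18.0, 6.0),
) -> ExperimentConfig:
    """Closed loop around the hopping leg."""
    # The leg's synaptic scaling is two orders of magnitude weaker than in
    # the other protocols (tau_s = 15000 s), so compressing only the STDP
    # amplitudes would shift the LTP/scaling balance.  Here amplitudes and
    # the homeostatic time constants are compressed together, which keeps
    # both the weight fixed point and the loop damping ratio; the rate
    # estimator (tau_rs = 3 s at speedup 100) stays long against the hop
    # period, so the estimate remains a cycle average.
    plast = TripletParams(
        A_plus=6.5e-5 * speedup,
        A_minus=1.1e-5 * speedup,
        tau_s=15_000.0 / speedup,
        nu_tar=15.0,
        tau_rs=300.0 / speedup,
    )
    size = 3 if large else 1
    lif_factor = 2 if large else 1
    if w_stdp_0 is None:
        w_stdp_0 = (1.0 / size, 1.0 / size)
    return ExperimentConfig(
        kind="leg",
        duration=duration if duration is not None else 15_000.0 / speedup,
        dt_neural=1e-4,
        dt_ser=1e-3,
        seed=seed,
        speedup=speedup,
        record_weights_every=max(0.25 / speedup, 1e-2),
        record_state_every=1e-3,
        m_f=525e-6,
        tau_f=5e-3,
        w_stdp_0=w_stdp_0,
        network=NetworkConfig(
            n_sens=130 * size,
            n_tim=6 * lif_factor,
            n_inh=100,
            n_ser=10,
            p_con=0.7,
            w_ext=0.1,
            nu_ext=3.0,
            tau_del_stdp=30e-3,
            tau_del_nm=200e-3,
            m_sens=9.0,
        ),
        plasticity=plast,
        serotonin=SerotoninConfig(
            conc0=conc0,
            c_ser=0.005,
            c_NM_per_uM=65.0 / lif_factor,
            m_ser=1000.0,
            b_ser=0.0,
        ),
        leg=LegModel(),
    )
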