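"""Parameter containers for single-compartment HVC-type model neurons.

Units convention used throughout the package: mV, ms, nS, pA, pF
(so nS*mV = pA and pA/pF = mV/ms).  Calcium concentrations are in the
arbitrary micromolar-like units fixed by ``CalciumParams.eps``.

Two neuron classes are modelled:

* ``HVC_X`` -- excitatory projection neurons (the combination-sensitive
  neuron, CSN, is modelled as one of these).  8 state variables:
  V, n, h, e, rT, rf, rs, Ca_i.
* ``HVC_INT`` -- local inhibitory interneurons with a large delayed
  rectifier (spikes undershoot rest) and no SK current.  7 state
  variables (no intracellular calcium).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "GateParams",
    "TGateParams",
    "HGateParams",
    "CalciumParams",
    "PhysicalConstants",
    "NeuronParams",
    "NeuronState",
    "default_neuron_params",
    "HVC_X",
    "HVC_INT",
]

HVC_X = "HVC_X"
HVC_INT = "HVC_INT"

#: Physiological temperature used for the GHK exponent default (Kelvin).
_BODY_TEMP_K = 310.0
_FARADAY = 96485.332  # C/mol
_GAS_R = 8.314462  # J/(mol K)


def two_f_over_rt(temperature_k: float = _BODY_TEMP_K) -> float:
    """2F/(RT) in 1/mV at the given temperature."""
    return 2.0 * _FARADAY / (_GAS_R * temperature_k) / 1000.0


class InvalidParameterError(ValueError):
    """Raised when a parameter block violates its invariants."""


@dataclass
class GateParams:
    """Boltzmann gate: x_inf(V) = 1/(1+exp((V-theta)/sigma)).

    ``sigma`` is signed: negative slope gives a gate that opens with
    depolarization.  ``tau`` (ms) is the first-order relaxation time for
    dynamic gates; instantaneous gates leave it unused.
    """

    theta: float
    sigma: float
    tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma == 0:
            raise InvalidParameterError("gate slope sigma must be nonzero")
        if self.tau is not None and self.tau <= 0:
            raise InvalidParameterError("gate time constant tau must be > 0")


@dataclass
class TGateParams:
    """Low-threshold T-type calcium current gating constants.

    Activation aT is instantaneous in V; availability bT is an
    instantaneous function of the slow variable rT, whose voltage
    dependent time constant is tau_r0 + tau_r1/(1+exp((V-theta_rrT)/sigma_rrT)).
    """

    theta_aT: float = -62.0
    sigma_aT: float = -4.0
    theta_b: float = 0.25
    sigma_b: float = -0.1
    theta_rT: float = -75.0
    sigma_rT: float = 3.0
    tau_r0: float = 60.0
    tau_r1: float = 140.0
    theta_rrT: float = -72.0
    sigma_rrT: float = 4.0

    def __post_init__(self) -> None:
        if self.tau_r0 <= 0 or self.tau_r0 + self.tau_r1 <= 0:
            raise InvalidParameterError("T-gate time constants must be positive")


@dataclass
class HGateParams:
    """Hyperpolarization-activated current: fast (rf) + slow (rs) components.

    IH = gH [kr rf + (1-kr) rs] (V - Vh).  The fast time constant follows
    the Destexhe form tau_rf = prf / (alpha(V) + beta(V)) with
    alpha = -7.4(V+70)/(exp(-(V+70)/0.8) - 1) and
    beta = 65 exp(-(V+56)/23); prf is a dimensionless scale.
    """

    kr: float = 0.6
    prf: float = 6000.0
    theta_rf: float = -90.0
    sigma_rf: float = 6.0
    theta_rs: float = -90.0
    sigma_rs: float = -6.0
    tau_rs: float = 300.0
    Vh: float = -30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kr <= 1.0:
            raise InvalidParameterError("kr must lie in [0, 1]")
        if self.tau_rs <= 0 or self.prf <= 0:
            raise InvalidParameterError("H time constants must be positive")


@dataclass
class CalciumParams:
    """Intracellular calcium handling and SK half-activation."""

    f: float = 0.01  # free-to-total cytosolic Ca fraction
    eps: float = 0.025  # current-to-concentration factor
    kCa: float = 0.02  # pump rate (1/ms)
    bCa: float = 0.05  # basal Ca
    ks: float = 0.4  # SK dissociation constant
    Ca_ex: float = 10.0  # external Ca scale entering the GHK drive (a.u.)

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise InvalidParameterError("calcium parameters must be positive")
        if self.f > 1.0:
            raise InvalidParameterError("free-Ca fraction f must be <= 1")


@dataclass
class PhysicalConstants:
    two_F_over_RT: float = field(default_factory=two_f_over_rt)

    def __post_init__(self) -> None:
        if self.two_F_over_RT <= 0:
            raise InvalidParameterError("2F/RT must be positive")


@dataclass
class NeuronParams:
    """Full parameter block for one model neuron."""

    neuron_class: str = HVC_X
    Cm: float = 40.0  # pF

    # maximal conductances (nS)
    gNa: float = 450.0
    gK: float = 240.0
    gA: float = 2.0
    gL: float = 1.5
    gCaL: float = 0.5
    gCaT: float = 0.4
    gSK: float = 6.0
    gH: float = 6.0

    # reversal potentials (mV)
    VNa: float = 55.0
    VK: float = -90.0
    VL: float = -75.0

    m: GateParams = field(default_factory=lambda: GateParams(-35.0, -5.0))
    n: GateParams = field(default_factory=lambda: GateParams(-30.0, -5.0, tau=1.0))
    a: GateParams = field(default_factory=lambda: GateParams(-20.0, -10.0))
    e: GateParams = field(default_factory=lambda: GateParams(-60.0, 5.0, tau=20.0))
    s: GateParams = field(default_factory=lambda: GateParams(-20.0, -5.0))
    t: TGateParams = field(default_factory=TGateParams)
    h_cur: HGateParams = field(default_factory=HGateParams)
    ca: CalciumParams = field(default_factory=CalciumParams)
    pc: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        for name in ("Cm", "gNa", "gK", "gA", "gL", "gCaL", "gCaT", "gSK", "gH"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.Cm == 0:
            raise InvalidParameterError("Cm must be positive")
        if self.neuron_class not in (HVC_X, HVC_INT):
            raise InvalidParameterError(f"unknown neuron class {self.neuron_class!r}")
        if self.neuron_class == HVC_INT and self.gSK != 0.0:
            # interneurons carry no SK current by construction
            self.gSK = 0.0

    @property
    def n_states(self) -> int:
        """8 for HVC_X (V, n, h, e, rT, rf, rs, Ca), 7 for HVC_INT."""
        return 8 if self.neuron_class == HVC_X else 7

    def replace(self, **kwargs) -> "NeuronParams":
        """Copy with changes; nested blocks accept partial dicts.

        ``p.replace(gCaT=0.8)`` changes a scalar;
        ``p.replace(t={"tau_r0": 30.0})`` updates fields inside a nested
        parameter block, leaving its other fields untouched.
        """
        resolved = {}
        for key, value in kwargs.items():
            current = getattr(self, key)
            if isinstance(value, dict) and dataclasses.is_dataclass(current):
                resolved[key] = dataclasses.replace(current, **value)
            else:
                resolved[key] = value
        return dataclasses.replace(self, **resolved)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        d = dict(d)
        for key, sub in (
            ("m", GateParams), ("n", GateParams), ("a", GateParams),
            ("e", GateParams), ("s", GateParams),
            ("t", TGateParams), ("h_cur", HGateParams),
            ("ca", CalciumParams), ("pc", PhysicalConstants),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass
class NeuronState:
    """Dynamic variables of one neuron (Ca_i only for HVC_X)."""

    V: float
    n: float
    h: float
    e: float
    rT: float
    rf: float
    rs: float
    Ca_i: Optional[float] = None

    def as_vector(self) -> list:
        vec = [self.V, self.n, self.h, self.e, self.rT, self.rf, self.rs]
        if self.Ca_i is not None:
            vec.append(self.Ca_i)
        return vec

    def validate(self) -> None:
        gates = (self.n, self.h, self.e, self.rT, self.rf, self.rs)
        if not all(map(math.isfinite, (self.V, *gates))):
            raise ValueError("non-finite neuron state")
        if any(g < -1e-9 or g > 1.0 + 1e-9 for g in gates):
            raise ValueError("gating variable outside [0, 1]")
        if self.Ca_i is not None and self.Ca_i < 0:
            raise ValueError("Ca_i must be >= 0")


def save_neuron_params(params_by_label: dict, path) -> None:
    """Serialize labelled NeuronParams blocks to a YAML file."""
    import yaml

    payload = {label: p.to_dict() for label, p in params_by_label.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_neuron_params(path) -> dict:
    """Load labelled NeuronParams blocks from a YAML file."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {label: NeuronParams.from_dict(d) for label, d in payload.items()}


def default_neuron_params(neuron_class: str = HVC_X) -> NeuronParams:
    """Canonical per-class defaults.

    HVC_X: sag, post-inhibitory rebound and SK-mediated spike frequency
    adaptation.  HVC_INT: fast spiking with a large delayed rectifier so
    spikes undershoot rest; no SK, weak T and H currents.
    """
    if neuron_class == HVC_X:
        return NeuronParams(neuron_class=HVC_X)
    if neuron_class == HVC_INT:
        return NeuronParams(
            neuron_class=HVC_INT,
            Cm=25.0,
            gNa=700.0,
            gK=700.0,
            gA=1.0,
            gL=2.5,
            gCaL=0.1,
            gCaT=0.1,
            gSK=0.0,
            gH=0.5,
            VL=-65.0,
            n=GateParams(-32.0, -4.0, tau=3.0),
        )
    raise InvalidParameterError(f"unknown neuron class {neuron_class!r}")
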