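"""First-order kinetic AMPA / GABA_A synapses with sigmoidal release.

Transmitter concentration [T] is an instantaneous sigmoid of the
presynaptic voltage; the open fraction s obeys
ds/dt = ar [T] (1 - s) - ad s and the current is g s (V_post - Vrev).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMPA",
    "GABA_A",
    "RECEPTOR_DEFAULTS",
    "SynapseSpec",
    "SynapseState",
    "transmitter_concentration",
    "synapse_gate_derivative",
    "synaptic_current",
]

AMPA = "AMPA"
GABA_A = "GABA_A"

#: Receptor-class kinetic defaults: rise/decay rates (1/ms, with [T]
#: dimensionless) and reversal potential (mV).
RECEPTOR_DEFAULTS = {
    AMPA: {"ar": 1.1, "ad": 0.19, "Vrev": 0.0},
    GABA_A: {"ar": 5.0, "ad": 0.18, "Vrev": -95.0},
}


@dataclass
class SynapseSpec:
    """One directed kinetic synapse."""

    pre: str
    post: str
    receptor: str
    g: float  # maximal conductance, nS
    Vrev: float = None  # type: ignore[assignment]
    ar: float = None  # type: ignore[assignment]
    ad: float = None  # type: ignore[assignment]
    Tmax: float = 1.0
    Kp: float = 5.0
    VT: float = 2.0

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTOR_DEFAULTS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        defaults = RECEPTOR_DEFAULTS[self.receptor]
        if self.Vrev is None:
            self.Vrev = defaults["Vrev"]
        if self.ar is None:
            self.ar = defaults["ar"]
        if self.ad is None:
            self.ad = defaults["ad"]
        if self.g < 0:
            raise ValueError("synaptic conductance must be >= 0")
        if self.ar <= 0 or self.ad <= 0:
            raise ValueError("synaptic rates ar, ad must be > 0")

    @property
    def label(self) -> str:
        return f"{self.pre}->{self.post}"


@dataclass
class SynapseState:
    s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("open fraction s must lie in [0, 1]")


def transmitter_concentration(V_pre, spec: SynapseSpec):
    """[T] = Tmax / (1 + exp(-(V_pre - VT)/Kp)); Tmax/2 at V_pre = VT."""
    return spec.Tmax / (1.0 + np.exp(-(np.asarray(V_pre, dtype=float) - spec.VT)
                                     / spec.Kp))


def synapse_gate_derivative(s, T, spec: SynapseSpec):
    """ds/dt = ar [T] (1-s) - ad s; the unit interval is invariant."""
    return spec.ar * T * (1.0 - s) - spec.ad * s


def synaptic_current(s, V_post, spec: SynapseSpec):
    """I = g s (V_post - Vrev) in pA; inward (negative) for excitation."""
    return spec.g * s * (V_post - spec.Vrev)
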