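"""DC-pulse stimulus protocols for paired-stimulus experiments.

Stimuli are abstract "simple drivers": a DC pulse to a stimulus-selective
neuron marks stimulus onset, offset and duration.  The default protocol
presents S1 (50 ms, 200 pA, onset t = 100 ms) to the A-selective neuron
and S2 to the B-selective pathway after a configurable gap measured from
S1 offset, so a 150 ms delay puts S2 onset at t = 300 ms.

Pulse intervals are half-open [onset, onset + duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

__all__ = [
    "PulseStimulus",
    "PairedProtocol",
    "S1_ONSET",
    "make_paired_protocol",
    "make_control_protocol",
    "applied_current",
    "total_charge",
]

#: Default S1 onset (ms); doubles as the settling period before stimulation.
S1_ONSET = 100.0

#: Simulation continues this long past the last pulse offset by default.
POST_STIMULUS_HORIZON = 400.0

CONTROL_CONDITIONS = ("reversed", "S1_only", "S2_only", "S1_S1", "S2_S2")


@dataclass(frozen=True)
class PulseStimulus:
    """One DC pulse: target neuron, onset (ms), duration (ms), amplitude (pA)."""

    target: str
    onset: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")
        if self.onset < 0:
            raise ValueError("pulse onset must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class PairedProtocol:
    """A stimulus condition: list of pulses plus its label and S1->S2 gap."""

    pulses: tuple
    condition: str = "paired"
    delay: float = 0.0

    @property
    def t_end(self) -> float:
        """Default simulation horizon: last pulse offset + 400 ms."""
        return max(p.offset for p in self.pulses) + POST_STIMULUS_HORIZON

    def pulses_for(self, neuron_id: str) -> List[PulseStimulus]:
        return [p for p in self.pulses if p.target == neuron_id]

    def breakpoints(self) -> List[float]:
        """Sorted distinct pulse edges (integration is split at these)."""
        edges = {p.onset for p in self.pulses} | {p.offset for p in self.pulses}
        return sorted(edges)


def make_paired_protocol(
    delay: float,
    dur1: float = 50.0,
    dur2: float = 50.0,
    amp1: float = 200.0,
    amp2: float = 200.0,
    s1_target: str = "A",
    s2_target: str = "B",
    s1_onset: float = S1_ONSET,
) -> PairedProtocol:
    """S1 then S2 separated by ``delay`` ms measured from S1 offset.

    Negative delay (down to -dur1) expresses overlap conditions in which
    S2 arrives before S1 has ended.
    """
    if dur1 <= 0 or dur2 <= 0:
        raise ValueError("stimulus durations must be positive")
    if delay < -dur1:
        raise ValueError("delay may not precede S1 onset by more than dur1")
    s2_onset = s1_onset + dur1 + delay
    pulses = (
        PulseStimulus(s1_target, s1_onset, dur1, amp1),
        PulseStimulus(s2_target, s2_onset, dur2, amp2),
    )
    condition = "overlap" if delay < 0 else "paired"
    return PairedProtocol(pulses=pulses, condition=condition, delay=delay)


def make_control_protocol(
    condition: str,
    delay: float = 0.0,
    dur: float = 50.0,
    amp: float = 200.0,
    s1_target: str = "A",
    s2_target: str = "B",
    s1_onset: float = S1_ONSET,
) -> PairedProtocol:
    """Control conditions that must all fail the combination criterion.

    ``reversed`` swaps which selective neuron receives the first pulse;
    ``S1_only``/``S2_only`` drop one pulse; ``S1_S1``/``S2_S2`` repeat the
    same stimulus twice separated by ``delay``.
    """
    if condition not in CONTROL_CONDITIONS:
        raise ValueError(f"unknown control condition {condition!r}")
    second_onset = s1_onset + dur + delay
    if condition == "reversed":
        pulses = (
            PulseStimulus(s2_target, s1_onset, dur, amp),
            PulseStimulus(s1_target, second_onset, dur, amp),
        )
    elif condition == "S1_only":
        pulses = (PulseStimulus(s1_target, s1_onset, dur, amp),)
    elif condition == "S2_only":
        pulses = (PulseStimulus(s2_target, s1_onset, dur, amp),)
    elif condition == "S1_S1":
        pulses = (
            PulseStimulus(s1_target, s1_onset, dur, amp),
            PulseStimulus(s1_target, second_onset, dur, amp),
        )
    else:  # S2_S2
        pulses = (
            PulseStimulus(s2_target, s1_onset, dur, amp),
            PulseStimulus(s2_target, second_onset, dur, amp),
        )
    return PairedProtocol(pulses=pulses, condition=condition, delay=delay)


def applied_current(protocol: PairedProtocol, neuron_id: str, t: float) -> float:
    """Sum of pulse amplitudes covering time t (half-open intervals), pA."""
    return sum(
        p.amplitude
        for p in protocol.pulses
        if p.target == neuron_id and p.onset <= t < p.offset
    )


def total_charge(protocol: PairedProtocol) -> float:
    """Injected charge audit: sum of amplitude x duration (pA*ms = fC)."""
    return sum(p.amplitude * p.duration for p in protocol.pulses)
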