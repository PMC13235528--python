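"""Analysis stage: spike detection, burst classification and windowed
quantification of the CSN's intrinsic rebound currents.

A successful stimulus combination is a CSN burst of 4-12 spikes spanning
at most 80 ms; control conditions (reversed order, single stimulus,
repeated stimulus) must stay subthreshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .biophysics import h_current, t_current
from .integrate import SimResult
from .stimulus import S1_ONSET

__all__ = [
    "SpikeTrain",
    "CombinationOutcome",
    "CurrentQuantification",
    "detect_spikes",
    "classify_combination",
    "reconstruct_currents",
    "quantify_current_windows",
    "hyperpolarization_epochs",
]

#: Spike detection threshold (mV) and dead time (ms).  Acceptance anchors
#: are insensitive to +-10 mV threshold shifts (guard-tested).
SPIKE_THRESHOLD = -20.0
SPIKE_DEAD_TIME = 1.0

#: Burst-success band: 4-12 spikes within <= 80 ms.
SUCCESS_MIN_SPIKES = 4
SUCCESS_MAX_SPIKES = 12
SUCCESS_MAX_SPAN = 80.0


@dataclass(frozen=True)
class SpikeTrain:
    neuron_id: str
    times: np.ndarray  # ms, strictly increasing

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def count(self) -> int:
        return int(np.asarray(self.times).size)

    def rate(self, t_start: float, t_stop: float) -> float:
        """Mean firing rate (Hz) of spikes inside [t_start, t_stop)."""
        t = np.asarray(self.times)
        n = int(np.sum((t >= t_start) & (t < t_stop)))
        return 1000.0 * n / (t_stop - t_start)


@dataclass(frozen=True)
class CombinationOutcome:
    spike_count: int
    burst_span: float  # ms, last - first spike time (0 for < 2 spikes)
    success: bool
    condition: str = ""

    @staticmethod
    def from_spikes(spikes: SpikeTrain, condition: str = "") -> "CombinationOutcome":
        n = spikes.count
        span = float(spikes.times[-1] - spikes.times[0]) if n >= 2 else 0.0
        ok = (SUCCESS_MIN_SPIKES <= n <= SUCCESS_MAX_SPIKES
              and span <= SUCCESS_MAX_SPAN)
        return CombinationOutcome(n, span, ok, condition)


@dataclass(frozen=True)
class CurrentQuantification:
    delay: float
    peak_abs_IH: float  # a.u.
    peak_abs_ICaT: float  # a.u.
    norm_IH: float = np.nan
    norm_ICaT: float = np.nan


def detect_spikes(
    V: np.ndarray,
    t: np.ndarray,
    neuron_id: str = "",
    threshold: float = SPIKE_THRESHOLD,
    dead_time: float = SPIKE_DEAD_TIME,
) -> SpikeTrain:
    """Upward threshold crossings with a refractory dead time.

    Expects a uniform time grid.  Crossing times are taken at the first
    suprathreshold sample.
    """
    V = np.asarray(V, dtype=float)
    t = np.asarray(t, dtype=float)
    above = V >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times: List[float] = []
    for idx in crossings:
        if not times or t[idx] - times[-1] >= dead_time:
            times.append(float(t[idx]))
    return SpikeTrain(neuron_id=neuron_id, times=np.asarray(times))


def classify_combination(result: SimResult, neuron_id: str = "CSN",
                         condition: Optional[str] = None) -> CombinationOutcome:
    """Count CSN spikes over the whole run and apply the burst criterion."""
    spikes = detect_spikes(result.V(neuron_id), result.t, neuron_id)
    cond = condition if condition is not None else (
        result.protocol.condition if result.protocol else "")
    return CombinationOutcome.from_spikes(spikes, cond)


def reconstruct_currents(result: SimResult, neuron_id: str = "CSN"
                         ) -> Dict[str, np.ndarray]:
    """Pointwise IH(t) and ICaT(t) along the stored trajectory (a.u.).

    Evaluates the same biophysical formulas used inside the model on the
    stored V and gate traces; negative deflections are inward
    (depolarizing).  No rescaling is applied.
    """
    p = result.model.neuron(neuron_id).params
    states = result.neuron_states(neuron_id)
    for needed in ("V", "rT", "rf", "rs"):
        if needed not in states:
            raise KeyError(f"missing {needed} trajectory for {neuron_id}")
    IH = h_current(states["V"], states["rf"], states["rs"], p.h_cur, p.gH)
    ICaT = t_current(states["V"], states["rT"], p.t, p.ca, p.pc, p.gCaT)
    return {"IH": np.asarray(IH), "ICaT": np.asarray(ICaT)}


def quantify_current_windows(
    results_by_delay: Dict[float, SimResult],
    neuron_id: str = "CSN",
    s1_offset: float = S1_ONSET + 50.0,
    post_window: float = 100.0,
) -> List[CurrentQuantification]:
    """Windowed peak |IH| and |ICaT| per delay, normalized across delays.

    IH is assessed in the gap window [S1 offset, S1 offset + delay]
    (hyperpolarization phase); ICaT over [S2 onset, S2 onset + 100 ms]
    (rebound phase).  Each series is normalized to its maximum across the
    delay set, so the normalized peak is exactly 1 at its argmax delay.
    """
    rows: List[CurrentQuantification] = []
    for delay, res in sorted(results_by_delay.items()):
        cur = reconstruct_currents(res, neuron_id)
        t = res.t
        gap = (t >= s1_offset) & (t <= s1_offset + delay)
        onset_b = s1_offset + delay
        post = (t >= onset_b) & (t <= onset_b + post_window)
        if not gap.any() or not post.any() or t[-1] < onset_b + post_window:
            raise ValueError(
                f"quantification window outside simulated horizon at delay {delay}")
        rows.append(CurrentQuantification(
            delay=delay,
            peak_abs_IH=float(np.max(np.abs(cur["IH"][gap]))),
            peak_abs_ICaT=float(np.max(np.abs(cur["ICaT"][post]))),
        ))
    max_ih = max(r.peak_abs_IH for r in rows) or 1.0
    max_it = max(r.peak_abs_ICaT for r in rows) or 1.0
    return [
        CurrentQuantification(r.delay, r.peak_abs_IH, r.peak_abs_ICaT,
                              norm_IH=r.peak_abs_IH / max_ih,
                              norm_ICaT=r.peak_abs_ICaT / max_it)
        for r in rows
    ]


def hyperpolarization_epochs(
    V: np.ndarray,
    t: np.ndarray,
    v_rest: float,
    margin: float = 2.0,
) -> List[Tuple[float, float]]:
    """Maximal intervals where V < v_rest - margin (integration windows)."""
    below = np.asarray(V) < (v_rest - margin)
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = list(edges[~below[edges]] + 1)
    stops = list(edges[below[edges]])
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(len(below) - 1)
    return [(float(t[a]), float(t[b])) for a, b in zip(starts, stops)]
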