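"""Experiment drivers: the delay sweep, two-parameter heatmaps,
stimulus duration/intensity sweeps, motif battery and one-at-a-time
(OAT) sensitivity range search.

Every cell of every grid is one deterministic simulation; re-running a
cell reproduces its spike count exactly.  Sweeps sample the output grid
at 0.05 ms (spike counting is insensitive to this; single-run analyses
use the 0.01 ms default).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .integrate import SimResult, SolverOptions, find_rest_state, simulate
from .metrics import CombinationOutcome, classify_combination
from .network import NetworkModel, build_full_network, build_simple_motif
from .stimulus import make_control_protocol, make_paired_protocol

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "OATRange",
    "run_network_condition",
    "run_delay_sweep",
    "run_heatmap",
    "run_stimulus_sweeps",
    "run_motif_battery",
    "run_oat_search",
    "DEFAULT_DELAY_GRID",
]

#: Fig-3B-style default delay grid: 0-300 ms in 20 ms steps, 16 points.
DEFAULT_DELAY_GRID = tuple(float(d) for d in range(0, 320, 20))

SWEEP_SOLVER = SolverOptions(output_dt=0.05)


@dataclass
class SweepGrid:
    """Result of a parameter sweep: axes plus a spike-count array."""

    axis_names: Tuple[str, ...]
    axis_values: Tuple[Tuple[float, ...], ...]
    spike_counts: np.ndarray  # shape = product of axis lengths
    success: np.ndarray  # same shape, bool
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = tuple(len(v) for v in self.axis_values)
        if tuple(self.spike_counts.shape) != expected:
            raise ValueError("result shape must match the axis lengths")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for idx in itertools.product(*(range(len(v)) for v in self.axis_values)):
            row = {name: self.axis_values[k][idx[k]]
                   for k, name in enumerate(self.axis_names)}
            row["spike_count"] = int(self.spike_counts[idx])
            row["success"] = bool(self.success[idx])
            rows.append(row)
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        return {
            "axes": [{"name": n, "values": list(v)}
                     for n, v in zip(self.axis_names, self.axis_values)],
            "context": self.context,
            "n_simulations": int(self.spike_counts.size),
        }

    def save(self, out_dir, stem: str) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / f"{stem}.csv", index=False)
        (out / f"{stem}.json").write_text(json.dumps(self.manifest(), indent=2))


@dataclass(frozen=True)
class OATRange:
    """Accepted one-at-a-time variation range of a single parameter."""

    parameter: str
    baseline: float
    accepted_min: float
    accepted_max: float
    failure_reason_low: str = ""
    failure_reason_high: str = ""

    def __post_init__(self) -> None:
        if not self.accepted_min <= self.baseline <= self.accepted_max:
            raise ValueError("baseline must lie inside the accepted range")


# ----------------------------------------------------------------- running

_REST_CACHE: Dict[str, np.ndarray] = {}


def _rest_key(neuron_overrides, synapse_g, drive_IB_directly) -> str:
    blob = json.dumps(
        {"n": neuron_overrides or {}, "s": {f"{k[0]}->{k[1]}": v
                                            for k, v in (synapse_g or {}).items()},
         "ib": drive_IB_directly}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_network_condition(
    delay: Optional[float] = None,
    condition: str = "paired",
    neuron_overrides: Optional[Dict[str, Dict[str, float]]] = None,
    synapse_g: Optional[Dict[Tuple[str, str], float]] = None,
    dur1: float = 50.0,
    dur2: float = 50.0,
    amp1: float = 200.0,
    amp2: float = 200.0,
    solver: SolverOptions = SWEEP_SOLVER,
    drive_IB_directly: bool = False,
    keep_result: bool = False,
) -> Tuple[CombinationOutcome, Optional[SimResult]]:
    """One full-network simulation under one stimulus condition.

    Stimulus labels S1/S2 are resolved through the model's stimulus-target
    map.  Rest states are cached per parameter configuration.
    """
    model = build_full_network(neuron_overrides=neuron_overrides,
                               synapse_g=synapse_g,
                               drive_IB_directly=drive_IB_directly)
    if condition == "paired":
        protocol = make_paired_protocol(delay, dur1=dur1, dur2=dur2,
                                        amp1=amp1, amp2=amp2,
                                        s1_target="S1", s2_target="S2")
    else:
        protocol = make_control_protocol(condition, delay=delay or 0.0,
                                         s1_target="S1", s2_target="S2")
    key = _rest_key(neuron_overrides, synapse_g, drive_IB_directly)
    if key not in _REST_CACHE:
        _REST_CACHE[key] = find_rest_state(model, solver=solver)
    res = simulate(model, protocol, solver=solver, rest_state=_REST_CACHE[key])
    outcome = classify_combination(res)
    return outcome, (res if keep_result else None)


# ------------------------------------------------------------- delay sweep

def run_delay_sweep(
    delays: Sequence[float] = DEFAULT_DELAY_GRID,
    neuron_overrides: Optional[Dict[str, Dict[str, float]]] = None,
    synapse_g: Optional[Dict[Tuple[str, str], float]] = None,
    solver: SolverOptions = SWEEP_SOLVER,
) -> SweepGrid:
    """CSN spike count as a function of inter-stimulus delay."""
    counts, succ = [], []
    for d in delays:
        outcome, _ = run_network_condition(
            delay=d, neuron_overrides=neuron_overrides, synapse_g=synapse_g,
            solver=solver)
        logger.info("delay %.0f ms -> %d spikes", d, outcome.spike_count)
        counts.append(outcome.spike_count)
        succ.append(outcome.success)
    return SweepGrid(("delay_ms",), (tuple(float(d) for d in delays),),
                     np.asarray(counts), np.asarray(succ),
                     context={"experiment": "delay_sweep"})


# ---------------------------------------------------------------- heatmaps

def _apply_axis(name: str, value: float, cell: dict) -> None:
    """Translate an axis name into per-cell simulation settings.

    Supported names: ``delay``; ``<neuron>.<param>`` (e.g. ``CSN.gCaT``);
    ``g:<pre>-><post>`` (synaptic conductance); ``s1_duration``,
    ``s2_duration``, ``s1_intensity``, ``s2_intensity``.
    """
    if name == "delay":
        cell["delay"] = value
    elif name.startswith("g:") and "->" in name:
        pre, post = name[2:].split("->")
        cell.setdefault("synapse_g", {})[(pre, post)] = value
    elif name in ("s1_duration", "s2_duration"):
        cell["dur1" if name == "s1_duration" else "dur2"] = value
    elif name in ("s1_intensity", "s2_intensity"):
        cell["amp1" if name == "s1_intensity" else "amp2"] = value
    elif "." in name:
        nid, attr = name.split(".", 1)
        cell.setdefault("neuron_overrides", {}).setdefault(nid, {})[attr] = value
    else:
        raise ValueError(f"unknown sweep parameter {name!r}")


def run_heatmap(
    x_axis: Tuple[str, Sequence[float]],
    y_axis: Tuple[str, Sequence[float]],
    delay: float = 50.0,
    neuron_overrides: Optional[Dict[str, Dict[str, float]]] = None,
    synapse_g: Optional[Dict[Tuple[str, str], float]] = None,
    solver: SolverOptions = SWEEP_SOLVER,
) -> SweepGrid:
    """Two-parameter interaction map of CSN spike counts.

    Axes may vary intrinsic conductances (``CSN.gCaT``), synaptic
    conductances (``g:B->CSN``) or the inter-stimulus ``delay``; the
    fixed context is the default paired protocol at the given delay.
    """
    (xn, xv), (yn, yv) = x_axis, y_axis
    counts = np.zeros((len(xv), len(yv)), dtype=int)
    succ = np.zeros_like(counts, dtype=bool)
    for i, xval in enumerate(xv):
        for j, yval in enumerate(yv):
            cell: dict = {
                "delay": delay,
                "neuron_overrides": {k: dict(v)
                                     for k, v in (neuron_overrides or {}).items()},
                "synapse_g": dict(synapse_g or {}),
            }
            _apply_axis(xn, float(xval), cell)
            _apply_axis(yn, float(yval), cell)
            outcome, _ = run_network_condition(solver=solver, **cell)
            counts[i, j] = outcome.spike_count
            succ[i, j] = outcome.success
        logger.info("heatmap row %s=%g done", xn, xval)
    return SweepGrid((xn, yn), (tuple(map(float, xv)), tuple(map(float, yv))),
                     counts, succ,
                     context={"experiment": "heatmap", "delay_ms": delay})


# --------------------------------------------------------- stimulus sweeps

def run_stimulus_sweeps(
    mode: str,
    grid: Optional[Sequence[float]] = None,
    delay: float = 50.0,
    solver: SolverOptions = SWEEP_SOLVER,
) -> Dict[str, SweepGrid]:
    """Duration or intensity robustness sweeps at a 50 ms delay.

    Returns the 2D S1 x S2 grid plus the two 1-D marginals in which one
    stimulus varies and the other is held at its default (50 ms, 200 pA).
    """
    if mode == "duration":
        values = tuple(np.round(np.linspace(10.0, 200.0, 10), 1)) \
            if grid is None else tuple(map(float, grid))
        axes = ("s1_duration", "s2_duration")
    elif mode == "intensity":
        values = tuple(np.round(np.linspace(10.0, 300.0, 10), 1)) \
            if grid is None else tuple(map(float, grid))
        axes = ("s1_intensity", "s2_intensity")
    else:
        raise ValueError(f"unknown stimulus sweep mode {mode!r}")

    grid2d = run_heatmap((axes[0], values), (axes[1], values),
                         delay=delay, solver=solver)
    marginals = {}
    for ax in axes:
        counts, succ = [], []
        for v in values:
            cell: dict = {"delay": delay}
            _apply_axis(ax, float(v), cell)
            outcome, _ = run_network_condition(solver=solver, **cell)
            counts.append(outcome.spike_count)
            succ.append(outcome.success)
        marginals[ax] = SweepGrid((ax,), (values,), np.asarray(counts),
                                  np.asarray(succ),
                                  context={"experiment": f"{mode}_marginal",
                                           "delay_ms": delay})
    return {"grid": grid2d, **marginals}


# ------------------------------------------------------------ motif battery

MOTIF_CONDITIONS = (
    ("paired", 0.0),
    ("paired", 50.0),
    ("overlap", -30.0),
    ("reversed", 0.0),
    ("repeat_S2", 0.0),
)


def run_motif_battery(
    kinds: Sequence[str] = ("dual_excitatory", "inhibitory_excitatory"),
    g_inputs: Optional[Tuple[float, float]] = None,
    solver: SolverOptions = SWEEP_SOLVER,
) -> pd.DataFrame:
    """Boolean outcome table for the simple motifs under timing conditions.

    The inhibitory-excitatory (postsynaptic facilitation) motif should
    succeed only at near-zero gap; the dual-excitatory (temporal
    summation) motif is order-insensitive and not stimulus-specific.
    """
    rows = []
    for kind in kinds:
        model = build_simple_motif(kind, g_inputs=g_inputs)
        rest = find_rest_state(model, solver=solver)
        for condition, delay in MOTIF_CONDITIONS:
            if condition == "paired" or condition == "overlap":
                protocol = make_paired_protocol(delay)
            elif condition == "repeat_S2":
                protocol = make_control_protocol("S2_S2", delay=delay)
            else:
                protocol = make_control_protocol(condition, delay=delay)
            res = simulate(model, protocol, solver=solver, rest_state=rest)
            out = classify_combination(res)
            rows.append({
                "motif": kind, "condition": condition, "delay_ms": delay,
                "spike_count": out.spike_count, "burst_span": out.burst_span,
                "success": out.success,
            })
            logger.info("motif %s %s delay=%g -> %d spikes success=%s",
                        kind, condition, delay, out.spike_count, out.success)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- OAT

def run_oat_search(
    parameter: str,
    baseline: float,
    success_predicate: Callable[[float], bool],
    step_factor: float = 1.25,
    max_steps: int = 12,
    bisection_iters: int = 6,
) -> OATRange:
    """Outward multiplicative search from baseline until the predicate fails,
    refined by bisection to ~2 significant figures.

    The predicate receives a candidate parameter value and returns whether
    the network still shows the desired behaviour (combination success,
    control failures, single-cell signatures).
    """
    if not success_predicate(baseline):
        raise ValueError(f"baseline {parameter}={baseline} fails the predicate")

    def bound(direction: int) -> float:
        good, bad = baseline, None
        v = baseline
        for _ in range(max_steps):
            v = v * step_factor if direction > 0 else v / step_factor
            if success_predicate(v):
                good = v
            else:
                bad = v
                break
        if bad is None:
            return good  # never failed within the explored span
        for _ in range(bisection_iters):
            mid = 0.5 * (good + bad)
            if success_predicate(mid):
                good = mid
            else:
                bad = mid
        return good

    lo = bound(-1)
    hi = bound(+1)
    return OATRange(parameter=parameter, baseline=baseline,
                    accepted_min=min(baseline, float(f"{lo:.2g}")),
                    accepted_max=max(baseline, float(f"{hi:.2g}")),
                    failure_reason_low="predicate failure below accepted_min",
                    failure_reason_high="predicate failure above accepted_max")
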