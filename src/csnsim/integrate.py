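"""Numerical solution of the assembled network ODE system.

Integration is adaptive (scipy ``solve_ivp``), split piecewise at the
stimulus pulse edges so the DC-pulse discontinuities never fall inside a
solver step, and resampled onto a uniform output grid (default 0.01 ms).
Two adaptive methods are supported: ``RK23`` (default) and the
Adams-based ``LSODA`` fallback, which also handles the mildly stiff
spike upstrokes implicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel, StateLayout, assemble_system
from .stimulus import PairedProtocol

__all__ = ["SolverOptions", "SimResult", "find_rest_state", "simulate"]

#: state-variable names per neuron block (Ca only for HVC_X)
STATE_VARS = ("V", "n", "h", "e", "rT", "rf", "rs", "Ca")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    """Solver settings.  Tolerances default tighter than scipy's because
    rebound timing is threshold-sensitive."""

    method: str = "RK23"
    rtol: float = 1e-6
    atol: float = 1e-8
    output_dt: float = 0.01  # ms, uniform output grid
    max_step: float = 1.0  # ms

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rtol": self.rtol,
            "atol": self.atol,
            "output_dt": self.output_dt,
            "max_step": self.max_step,
        }


@dataclass
class SimResult:
    """Uniformly sampled trajectories of one simulation."""

    t: np.ndarray  # (nt,)
    y: np.ndarray  # (n_states, nt)
    layout: StateLayout
    model: NetworkModel
    protocol: Optional[PairedProtocol]
    solver: SolverOptions
    metadata: dict = field(default_factory=dict)

    def V(self, neuron_id: str) -> np.ndarray:
        return self.y[self.layout.var_index(neuron_id, "V")]

    def gate(self, neuron_id: str, var: str) -> np.ndarray:
        return self.y[self.layout.var_index(neuron_id, var)]

    def synapse_s(self, pre: str, post: str) -> np.ndarray:
        return self.y[self.layout.synapse_index[f"{pre}->{post}"]]

    def neuron_states(self, neuron_id: str) -> Dict[str, np.ndarray]:
        sl = self.layout.neuron_slices[neuron_id]
        nvars = sl.stop - sl.start
        return {STATE_VARS[i]: self.y[sl.start + i] for i in range(nvars)}

    def to_dataframe(self):
        """Wide table: time plus one column per state variable."""
        import pandas as pd

        cols = {"time_ms": self.t}
        for nid in self.model.neuron_ids:
            for var, tr in self.neuron_states(nid).items():
                cols[f"{nid}.{var}"] = tr
        for label, idx in self.layout.synapse_index.items():
            cols[f"s[{label}]"] = self.y[idx]
        return pd.DataFrame(cols)

    def save(self, path_stem) -> None:
        """Write <stem>.csv (wide trajectories) and <stem>.json metadata."""
        stem = Path(path_stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(stem.with_suffix(".csv"), index=False)
        meta = {
            "solver": self.solver.to_dict(),
            "condition": self.protocol.condition if self.protocol else None,
            "delay_ms": self.protocol.delay if self.protocol else None,
            "pulses": [
                {"target": p.target, "onset": p.onset,
                 "duration": p.duration, "amplitude": p.amplitude}
                for p in (self.protocol.pulses if self.protocol else [])
            ],
            **self.metadata,
        }
        stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _initial_state(model: NetworkModel) -> np.ndarray:
    """Generic in-basin initial guess: rest-ish V, gates at their V=-70 values."""
    layout = model.layout()
    y0 = np.zeros(layout.n_states)
    from .biophysics import h_gate_kinetics, sigmoid_gate

    for spec in model.neurons:
        sl = layout.neuron_slices[spec.id]
        p = spec.params
        V0 = p.VL
        h_inf, _ = h_gate_kinetics(V0)
        vals = [
            V0,
            sigmoid_gate(V0, p.n),
            float(h_inf),
            sigmoid_gate(V0, p.e),
            1.0 / (1.0 + np.exp((V0 - p.t.theta_rT) / p.t.sigma_rT)),
            sigmoid_gate(V0, type(p.m)(p.h_cur.theta_rf, p.h_cur.sigma_rf)),
            sigmoid_gate(V0, type(p.m)(p.h_cur.theta_rf, p.h_cur.sigma_rf)),
        ]
        if sl.stop - sl.start == 8:
            vals.append(p.ca.bCa)
        y0[sl] = vals
    return y0


def _check_finite(t, y, layout: StateLayout) -> None:
    if np.all(np.isfinite(y)):
        return
    bad_flat = np.argwhere(~np.isfinite(y))
    i_state, i_t = bad_flat[0]
    name = f"state[{i_state}]"
    for nid, sl in layout.neuron_slices.items():
        if sl.start <= i_state < sl.stop:
            name = f"{nid}.{STATE_VARS[i_state - sl.start]}"
    for lbl, idx in layout.synapse_index.items():
        if idx == i_state:
            name = f"s[{lbl}]"
    raise SimulationError(
        f"non-finite state: {name} at t = {np.asarray(t).ravel()[i_t]:.3f} ms"
    )


def find_rest_state(
    model: NetworkModel,
    relax_ms: float = 1000.0,
    solver: SolverOptions = SolverOptions(),
    tol: float = 1e-6,
    refine: bool = True,
) -> np.ndarray:
    """Zero-stimulus rest state: long relaxation plus root refinement.

    Raises ``SimulationError`` if the relaxed state is not stationary to
    ``tol`` in every derivative component.
    """
    f, layout = assemble_system(model, protocol=None)
    y0 = _initial_state(model)
    sol = solve_ivp(f, (0.0, relax_ms), y0, method="LSODA",
                    rtol=solver.rtol, atol=solver.atol, dense_output=False)
    if not sol.success:
        raise SimulationError(f"rest-state relaxation failed: {sol.message}")
    y = sol.y[:, -1]
    if refine:
        from scipy.optimize import root

        res = root(lambda v: f(0.0, v), y, method="hybr", tol=1e-12)
        if res.success and np.max(np.abs(f(0.0, res.x))) < np.max(np.abs(f(0.0, y))):
            y = res.x
    resid = np.max(np.abs(f(0.0, y)))
    if resid > tol:
        raise SimulationError(
            f"no rest state found: max |dy/dt| = {resid:.2e} after "
            f"{relax_ms} ms relaxation (oscillatory or drifting network?)"
        )
    return y


def simulate(
    model: NetworkModel,
    protocol: PairedProtocol,
    solver: SolverOptions = SolverOptions(),
    y0: Optional[np.ndarray] = None,
    t_end: Optional[float] = None,
    rest_state: Optional[np.ndarray] = None,
) -> SimResult:
    """Integrate the network under a stimulus protocol.

    The run starts at t = 0 from the rest state (computed if not given),
    so the pre-S1 settling segment is simulated and printed event times
    (S1 onset at 100 ms etc.) are directly comparable.
    """
    f, layout = assemble_system(model, protocol)
    if y0 is None:
        y0 = rest_state if rest_state is not None else find_rest_state(
            model, solver=solver)
    t_final = float(t_end if t_end is not None else protocol.t_end)

    # piecewise integration split at pulse edges
    edges = [e for e in protocol.breakpoints() if 0.0 < e < t_final]
    seg_bounds = [0.0, *edges, t_final]

    dt = solver.output_dt
    t_grid = np.round(np.arange(0.0, np.floor(t_final / dt) * dt + dt / 2, dt), 9)
    ys = np.empty((layout.n_states, t_grid.size))
    y = np.array(y0, dtype=float)
    filled = 0
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        # half-open [onset, offset) pulse convention: output samples at a
        # segment's start belong to that segment, samples at b to the next
        mask = (t_grid >= a) & ((t_grid <= b) if b == t_final else (t_grid < b))
        t_eval = t_grid[mask]
        sol = solve_ivp(
            f, (a, b), y, method=solver.method, rtol=solver.rtol,
            atol=solver.atol, max_step=solver.max_step, dense_output=True,
        )
        if not sol.success:
            raise SimulationError(
                f"solver {solver.method} failed on [{a}, {b}] ms: {sol.message}")
        _check_finite(sol.t, sol.y, layout)
        if t_eval.size:
            block = sol.sol(t_eval)
            _check_finite(t_eval, block, layout)
            ys[:, filled:filled + t_eval.size] = block
            filled += t_eval.size
        y = sol.y[:, -1]  # state exactly at b, continues the next segment
    return SimResult(t=t_grid, y=ys, layout=layout, model=model,
                     protocol=protocol, solver=solver)
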