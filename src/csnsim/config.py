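"""Run configuration: YAML schema, validation, hashing and execution.

A ``RunConfig`` fully determines a run: the experiment block, network
parameter overrides, stimulus protocol settings and solver options.  The
model is deterministic, so the config hash uniquely identifies a run's
inputs; the ``seed`` field exists only for future stochastic extensions
and is recorded but unused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .integrate import SolverOptions, simulate, find_rest_state
from .network import build_full_network
from .stimulus import make_control_protocol, make_paired_protocol

__all__ = ["RunConfig", "load_config", "save_config", "run_from_config",
           "default_config_path"]

_TOP_KEYS = {"experiment", "network", "protocol", "solver", "output_dir", "seed"}
_EXPERIMENT_KEYS = {"name", "delays", "x_axis", "y_axis", "mode", "grid",
                    "parameter", "baseline", "kinds"}
_NETWORK_KEYS = {"neuron_overrides", "synapse_g", "drive_IB_directly"}
_PROTOCOL_KEYS = {"condition", "delay", "dur1", "dur2", "amp1", "amp2"}
_SOLVER_KEYS = {"method", "rtol", "atol", "output_dt", "max_step"}

EXPERIMENTS = ("simulate", "delay-sweep", "heatmap", "stimulus-sweep",
               "motif-battery", "oat")


class ConfigError(ValueError):
    pass


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    experiment: dict = field(default_factory=lambda: {"name": "simulate"})
    network: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=lambda: {"condition": "paired",
                                                    "delay": 50.0})
    solver: dict = field(default_factory=dict)
    output_dir: str = "runs"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        _reject_unknown(self.experiment, _EXPERIMENT_KEYS, "experiment")
        _reject_unknown(self.network, _NETWORK_KEYS, "network")
        _reject_unknown(self.protocol, _PROTOCOL_KEYS, "protocol")
        _reject_unknown(self.solver, _SOLVER_KEYS, "solver")
        name = self.experiment.get("name", "simulate")
        if name not in EXPERIMENTS:
            raise ConfigError(f"unknown experiment {name!r}")
        for nid, changes in self.network.get("neuron_overrides", {}).items():
            for attr, v in changes.items():
                if attr.startswith("g") and v < 0:
                    raise ConfigError(f"negative conductance {nid}.{attr}")
        for edge, g in self.network.get("synapse_g", {}).items():
            if g < 0:
                raise ConfigError(f"negative synaptic conductance for {edge}")

    # ------------------------------------------------------------ plumbing
    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    def network_kwargs(self) -> dict:
        syn = {}
        for edge, g in self.network.get("synapse_g", {}).items():
            pre, post = edge.split("->")
            syn[(pre, post)] = float(g)
        return {
            "neuron_overrides": self.network.get("neuron_overrides") or None,
            "synapse_g": syn or None,
            "drive_IB_directly": bool(self.network.get("drive_IB_directly",
                                                       False)),
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(resources.files("csnsim") / "conf" / "defaults.yaml")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config root")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def run_from_config(cfg: RunConfig, out_dir=None) -> Path:
    """Execute the configured experiment; write tables + a JSON manifest.

    Returns the output directory.  Identical configs produce byte-identical
    results tables (deterministic ODE integration).
    """
    from . import experiments as ex

    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    solver = cfg.solver_options()
    name = cfg.experiment.get("name", "simulate")
    net_kwargs = cfg.network_kwargs()

    if name == "simulate":
        model = build_full_network(**net_kwargs)
        p = cfg.protocol
        if p.get("condition", "paired") in ("paired", "overlap"):
            protocol = make_paired_protocol(
                p.get("delay", 50.0), dur1=p.get("dur1", 50.0),
                dur2=p.get("dur2", 50.0), amp1=p.get("amp1", 200.0),
                amp2=p.get("amp2", 200.0), s1_target="S1", s2_target="S2")
        else:
            protocol = make_control_protocol(p["condition"],
                                             delay=p.get("delay", 0.0),
                                             s1_target="S1", s2_target="S2")
        res = simulate(model, protocol, solver=solver)
        res.save(out / "trajectories")
    elif name == "delay-sweep":
        grid = ex.run_delay_sweep(
            delays=cfg.experiment.get("delays", ex.DEFAULT_DELAY_GRID),
            solver=solver, **{k: v for k, v in net_kwargs.items()
                              if k != "drive_IB_directly"})
        grid.save(out, "delay_sweep")
    elif name == "heatmap":
        x = cfg.experiment["x_axis"]
        y = cfg.experiment["y_axis"]
        grid = ex.run_heatmap((x["name"], x["values"]), (y["name"], y["values"]),
                              delay=cfg.protocol.get("delay", 50.0),
                              solver=solver,
                              **{k: v for k, v in net_kwargs.items()
                                 if k != "drive_IB_directly"})
        grid.save(out, "heatmap")
    elif name == "stimulus-sweep":
        grids = ex.run_stimulus_sweeps(cfg.experiment.get("mode", "duration"),
                                       grid=cfg.experiment.get("grid"),
                                       delay=cfg.protocol.get("delay", 50.0),
                                       solver=solver)
        for key, g in grids.items():
            g.save(out, f"stimulus_{key}")
    elif name == "motif-battery":
        table = ex.run_motif_battery(
            kinds=cfg.experiment.get("kinds",
                                     ("dual_excitatory", "inhibitory_excitatory")),
            solver=solver)
        table.to_csv(out / "motif_battery.csv", index=False)
    elif name == "oat":
        raise ConfigError(
            "the OAT search needs a Python predicate; use "
            "csnsim.experiments.run_oat_search or the oat-demo example")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "solver": solver.to_dict(),
        "experiment": name,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return out
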