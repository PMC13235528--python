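"""Declarative network construction and compilation to one ODE system.

Builds the three simple two-input motifs and the full layered network:
a transient reverberatory delay loop (TRDL: E1-E3, I1-I2 with E3->I1
feedback) plus a feedforward inhibitory convergence pathway (FFIC:
I_A1-I_A3) converging on the combination-sensitive neuron (CSN), and the
B/I_B disinhibition pair driven by the second stimulus.

Receptor classes follow the presynaptic neuron class: excitatory HVC_X
cells make AMPA synapses, HVC_INT interneurons make GABA_A synapses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from . import _kernel
from .params import NeuronParams, default_neuron_params, HVC_X, HVC_INT
from .stimulus import PairedProtocol
from .synapses import SynapseSpec, AMPA, GABA_A

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronSpec",
    "NetworkModel",
    "StateLayout",
    "build_simple_motif",
    "build_full_network",
    "assemble_system",
    "DEFAULT_SYNAPSE_G",
]

MOTIF_KINDS = ("dual_excitatory", "dual_inhibitory", "inhibitory_excitatory")


@dataclass
class NeuronSpec:
    id: str
    neuron_class: str
    role: str = "generic"
    params: NeuronParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = default_neuron_params(self.neuron_class)
        if self.params.neuron_class != self.neuron_class:
            raise ValueError(
                f"neuron {self.id}: params class {self.params.neuron_class} "
                f"!= spec class {self.neuron_class}"
            )
        if self.role == "CSN" and self.neuron_class != HVC_X:
            raise ValueError("the CSN is modelled as an HVC_X neuron")


@dataclass
class StateLayout:
    """Mapping from neuron/synapse identity to global state-vector indices."""

    neuron_slices: Dict[str, slice]
    neuron_index: Dict[str, int]
    synapse_index: Dict[str, int]  # synapse label -> global index of its s gate
    n_states: int

    def var_index(self, neuron_id: str, var: str) -> int:
        names = ("V", "n", "h", "e", "rT", "rf", "rs", "Ca")
        sl = self.neuron_slices[neuron_id]
        i = names.index(var)
        if sl.stop - sl.start == 7 and var == "Ca":
            raise KeyError(f"{neuron_id} has no intracellular calcium state")
        return sl.start + i


@dataclass
class NetworkModel:
    neurons: List[NeuronSpec]
    synapses: List[SynapseSpec]
    stimulus_targets: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------ helpers
    def neuron(self, neuron_id: str) -> NeuronSpec:
        for n in self.neurons:
            if n.id == neuron_id:
                return n
        raise KeyError(neuron_id)

    def synapse(self, pre: str, post: str) -> SynapseSpec:
        for s in self.synapses:
            if s.pre == pre and s.post == post:
                return s
        raise KeyError(f"{pre}->{post}")

    @property
    def neuron_ids(self) -> List[str]:
        return [n.id for n in self.neurons]

    def validate(self) -> None:
        ids = set()
        for n in self.neurons:
            if n.id in ids:
                raise ValueError(f"duplicate neuron id {n.id!r}")
            ids.add(n.id)
        for s in self.synapses:
            if s.pre not in ids or s.post not in ids:
                raise ValueError(f"synapse {s.label} references unknown neuron")
            pre_class = self.neuron(s.pre).neuron_class
            expected = AMPA if pre_class == HVC_X else GABA_A
            if s.receptor != expected:
                raise ValueError(
                    f"synapse {s.label}: receptor {s.receptor} inconsistent "
                    f"with presynaptic class {pre_class}"
                )
        for label, targets in self.stimulus_targets.items():
            for t in targets:
                if t not in ids:
                    raise ValueError(f"stimulus {label} targets unknown neuron {t!r}")

    def layout(self) -> StateLayout:
        slices, index = {}, {}
        pos = 0
        for i, n in enumerate(self.neurons):
            k = n.params.n_states
            slices[n.id] = slice(pos, pos + k)
            index[n.id] = i
            pos += k
        syn_index = {}
        for j, s in enumerate(self.synapses):
            syn_index[s.label] = pos + j
        return StateLayout(slices, index, syn_index, pos + len(self.synapses))

    def connectivity_table(self) -> str:
        lines = [f"{'pre':>6} -> {'post':<6} {'receptor':<7} g(nS)"]
        for s in self.synapses:
            lines.append(f"{s.pre:>6} -> {s.post:<6} {s.receptor:<7} {s.g:g}")
        return "\n".join(lines)

    def with_overrides(
        self,
        neuron_params: Optional[Dict[str, Dict[str, float]]] = None,
        synapse_g: Optional[Dict[Tuple[str, str], float]] = None,
    ) -> "NetworkModel":
        """Copy of the model with per-neuron conductance / per-edge g changes.

        ``neuron_params`` maps neuron id to {attr: value} where attr is a
        scalar NeuronParams field (e.g. gCaT, gH).  ``synapse_g`` maps
        (pre, post) to a new maximal conductance.
        """
        import copy

        m = copy.deepcopy(self)
        for nid, changes in (neuron_params or {}).items():
            spec = m.neuron(nid)
            spec.params = spec.params.replace(**changes)
        for (pre, post), g in (synapse_g or {}).items():
            m.synapse(pre, post).g = g
        return m


# ------------------------------------------------------------------ motifs

#: Calibrated per-kind default input conductances (nS).  Excitatory
#: inputs are individually subthreshold; the facilitation motif's B
#: input matches the layered network's B->CSN weight scale.
MOTIF_DEFAULT_G = {
    "dual_excitatory": (4.5, 4.5),
    "dual_inhibitory": (15.0, 15.0),
    "inhibitory_excitatory": (15.0, 3.2),
}


def build_simple_motif(kind: str,
                       g_inputs: Optional[Tuple[float, float]] = None,
                       csn_params: Optional[NeuronParams] = None) -> NetworkModel:
    """Three-neuron motif: two stimulus-driven inputs converging on a CSN.

    ``dual_excitatory``   -- temporal summation: both edges AMPA.
    ``dual_inhibitory``   -- dual post-inhibitory rebound: both edges GABA_A.
    ``inhibitory_excitatory`` -- postsynaptic facilitation: A inhibits
    (GABA_A), B excites (AMPA).

    The CSN uses the same calibrated parameters as in the layered
    network unless ``csn_params`` is given.
    """
    if kind not in MOTIF_KINDS:
        raise ValueError(f"unknown motif kind {kind!r}")
    if g_inputs is None:
        g_inputs = MOTIF_DEFAULT_G[kind]
    if csn_params is None:
        from .calibration import ROLE_PARAM_OVERRIDES

        csn_params = default_neuron_params(HVC_X).replace(
            **ROLE_PARAM_OVERRIDES["CSN"])
    a_class = HVC_X if kind == "dual_excitatory" else HVC_INT
    b_class = HVC_INT if kind == "dual_inhibitory" else HVC_X
    csn = NeuronSpec("CSN", HVC_X, role="CSN", params=csn_params)
    a = NeuronSpec("A", a_class, role="A_selective")
    b = NeuronSpec("B", b_class, role="B_selective")
    ga, gb = g_inputs
    syn = [
        SynapseSpec("A", "CSN", AMPA if a_class == HVC_X else GABA_A, ga),
        SynapseSpec("B", "CSN", AMPA if b_class == HVC_X else GABA_A, gb),
    ]
    model = NetworkModel([a, b, csn], syn,
                         stimulus_targets={"S1": ["A"], "S2": ["B"]})
    logger.info("built %s motif\n%s", kind, model.connectivity_table())
    return model


# ------------------------------------------------------------- full network

#: Default maximal synaptic conductances (nS) for the layered network.
#: The B->CSN excitatory weight sits in the printed 2.4-4 nS sweep band;
#: all others sit in the admissible 5-30 nS band.
DEFAULT_SYNAPSE_G = {
    # A->E1 is deliberately weak: E1 must integrate sustained A firing,
    # which sets the network's stimulus duration/intensity thresholds
    ("A", "E1"): 3.4,
    ("E1", "I1"): 15.0,
    ("I1", "E2"): 15.0,
    ("E2", "I2"): 15.0,
    ("I2", "E3"): 15.0,
    ("E3", "I1"): 15.0,
    ("E1", "I_A1"): 15.0,
    ("E2", "I_A2"): 15.0,
    ("E3", "I_A3"): 15.0,
    ("I_A1", "CSN"): 22.0,
    ("I_A2", "CSN"): 22.0,
    ("I_A3", "CSN"): 22.0,
    ("B", "CSN"): 2.6,
    ("B", "I_B"): 15.0,
    ("I_B", "I1"): 15.0,
    ("I_B", "I2"): 15.0,
    ("I_B", "I_A2"): 15.0,
    ("I_B", "I_A3"): 15.0,
}

#: Neuron ids and classes of the layered network.
FULL_NETWORK_CLASSES = {
    "A": (HVC_X, "A_selective"),
    "B": (HVC_X, "B_selective"),
    "I_B": (HVC_INT, "I_B"),
    "CSN": (HVC_X, "CSN"),
    "E1": (HVC_X, "E1"),
    "E2": (HVC_X, "E2"),
    "E3": (HVC_X, "E3"),
    "I1": (HVC_INT, "I1"),
    "I2": (HVC_INT, "I2"),
    "I_A1": (HVC_INT, "I_A1"),
    "I_A2": (HVC_INT, "I_A2"),
    "I_A3": (HVC_INT, "I_A3"),
}


def build_full_network(
    neuron_overrides: Optional[Dict[str, Dict[str, float]]] = None,
    synapse_g: Optional[Dict[Tuple[str, str], float]] = None,
    drive_IB_directly: bool = False,
) -> NetworkModel:
    """The 12-neuron TRDL + FFIC network of the layered model.

    S2 drives neuron B, which recruits I_B through a B->I_B AMPA edge
    (set ``drive_IB_directly`` to apply the S2 pulse to I_B instead; the
    edge is dropped in that case so the disinhibition timing is preserved
    under either reading).
    """
    from .calibration import ROLE_PARAM_OVERRIDES  # canonical calibrated values

    neurons = []
    for nid, (cls, role) in FULL_NETWORK_CLASSES.items():
        p = default_neuron_params(cls)
        changes = dict(ROLE_PARAM_OVERRIDES.get(nid, {}))
        changes.update((neuron_overrides or {}).get(nid, {}))
        if changes:
            p = p.replace(**changes)
        neurons.append(NeuronSpec(nid, cls, role=role, params=p))

    g = dict(DEFAULT_SYNAPSE_G)
    g.update(synapse_g or {})

    def receptor(pre: str) -> str:
        return AMPA if FULL_NETWORK_CLASSES[pre][0] == HVC_X else GABA_A

    edges = list(DEFAULT_SYNAPSE_G.keys())
    if drive_IB_directly:
        edges.remove(("B", "I_B"))
    synapses = [SynapseSpec(pre, post, receptor(pre), g[(pre, post)])
                for pre, post in edges]

    s2_targets = ["B", "I_B"] if drive_IB_directly else ["B"]
    model = NetworkModel(neurons, synapses,
                         stimulus_targets={"S1": ["A"], "S2": s2_targets})
    logger.info("built full network\n%s", model.connectivity_table())
    return model


# ------------------------------------------------------------- compilation

def _pack_stimulus(model: NetworkModel, protocol: Optional[PairedProtocol],
                   layout: StateLayout):
    """Resolve protocol pulses to neuron indices, expanding stimulus labels.

    A pulse target may be a neuron id or a stimulus label (S1/S2) that the
    model maps to one or more neurons.
    """
    tgt, on, dur, amp = [], [], [], []
    if protocol is not None:
        for p in protocol.pulses:
            if p.target in layout.neuron_index:
                ids = [p.target]
            elif p.target in model.stimulus_targets:
                ids = model.stimulus_targets[p.target]
            else:
                raise KeyError(f"pulse target {p.target!r} not in model")
            for nid in ids:
                tgt.append(layout.neuron_index[nid])
                on.append(p.onset)
                dur.append(p.duration)
                amp.append(p.amplitude)
    return (np.asarray(tgt, dtype=np.int64),
            np.asarray(on, dtype=float),
            np.asarray(dur, dtype=float),
            np.asarray(amp, dtype=float))


def assemble_system(
    model: NetworkModel, protocol: Optional[PairedProtocol] = None
) -> Tuple[Callable[[float, np.ndarray], np.ndarray], StateLayout]:
    """Compile the model + protocol into a derivative function f(t, y).

    Returns the jitted RHS closure and the state layout.  Total dimension
    is 8 per HVC_X neuron + 7 per HVC_INT neuron + one s gate per synapse.
    """
    model.validate()
    layout = model.layout()
    P, off, isx, nstate = _kernel.pack_neuron_params([n.params for n in model.neurons])
    if nstate + len(model.synapses) != layout.n_states:
        raise RuntimeError("state layout / packing dimension mismatch")

    nidx = layout.neuron_index
    spre = np.asarray([nidx[s.pre] for s in model.synapses], dtype=np.int64)
    spost = np.asarray([nidx[s.post] for s in model.synapses], dtype=np.int64)
    sg = np.asarray([s.g for s in model.synapses], dtype=float)
    svrev = np.asarray([s.Vrev for s in model.synapses], dtype=float)
    sar = np.asarray([s.ar for s in model.synapses], dtype=float)
    sad = np.asarray([s.ad for s in model.synapses], dtype=float)
    stmax = np.asarray([s.Tmax for s in model.synapses], dtype=float)
    skp = np.asarray([s.Kp for s in model.synapses], dtype=float)
    svt = np.asarray([s.VT for s in model.synapses], dtype=float)
    soff = nstate

    stim_tgt, stim_on, stim_dur, stim_amp = _pack_stimulus(model, protocol, layout)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return _kernel.rhs(t, y, P, off, isx,
                           spre, spost, sg, svrev, sar, sad, stmax, skp, svt,
                           soff, stim_tgt, stim_on, stim_dur, stim_amp)

    return f, layout
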