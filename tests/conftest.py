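"""Shared fixtures: memoized network simulations so expensive runs are
computed once per session."""

import numpy as np
import pytest

from csnsim.experiments import run_network_condition
from csnsim.integrate import SolverOptions
from csnsim.metrics import detect_spikes


SWEEP = SolverOptions(output_dt=0.05)


class NetCache:
    """Memoized full-network runs keyed by condition and overrides."""

    def __init__(self):
        self._store = {}

    def run(self, delay=None, condition="paired", neuron_overrides=None,
            synapse_g=None, **kw):
        key = (delay, condition, _freeze(neuron_overrides), _freeze(synapse_g),
               _freeze(kw))
        if key not in self._store:
            self._store[key] = run_network_condition(
                delay=delay, condition=condition,
                neuron_overrides=neuron_overrides, synapse_g=synapse_g,
                solver=SWEEP, keep_result=True, **kw)
        return self._store[key]

    def csn_spikes(self, **kw):
        outcome, _ = self.run(**kw)
        return outcome.spike_count


def _freeze(obj):
    if isinstance(obj, dict):
        return tuple(sorted((k, _freeze(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(_freeze(v) for v in obj)
    return obj


@pytest.fixture(scope="session")
def netcache():
    return NetCache()


@pytest.fixture(scope="session")
def isolated_x_run():
    """Isolated stimulus-selective HVC_X cell under the default pulse."""
    from csnsim.network import NetworkModel, NeuronSpec
    from csnsim.params import default_neuron_params, HVC_X
    from csnsim.stimulus import PairedProtocol, PulseStimulus
    from csnsim.integrate import find_rest_state, simulate

    p = default_neuron_params(HVC_X)
    model = NetworkModel([NeuronSpec("A", HVC_X, params=p)], [], {})
    protocol = PairedProtocol((PulseStimulus("A", 100.0, 50.0, 200.0),))
    rest = find_rest_state(model, solver=SWEEP)
    result = simulate(model, protocol, solver=SWEEP, rest_state=rest,
                      t_end=400.0)
    return rest, result


def assert_zero_conductance_decouples():
    """Shared check: zero-conductance network equals isolated cells."""
    import numpy as np

    from csnsim.integrate import find_rest_state, simulate
    from csnsim.network import (DEFAULT_SYNAPSE_G, NetworkModel, NeuronSpec,
                                build_full_network)
    from csnsim.stimulus import (PairedProtocol, PulseStimulus,
                                 make_paired_protocol)

    zero_g = {edge: 0.0 for edge in DEFAULT_SYNAPSE_G}
    net = build_full_network(synapse_g=zero_g)
    prot = make_paired_protocol(50.0, s1_target="S1", s2_target="S2")
    rest = find_rest_state(net, solver=SWEEP)
    res = simulate(net, prot, solver=SWEEP, rest_state=rest, t_end=300.0)

    for nid in ("A", "CSN"):
        spec = net.neuron(nid)
        iso = NetworkModel([NeuronSpec(nid, spec.neuron_class,
                                       params=spec.params)], [], {})
        pulses = tuple(PulseStimulus(nid, p.onset, p.duration, p.amplitude)
                       for p in prot.pulses
                       if nid in net.stimulus_targets.get(p.target,
                                                          [p.target]))
        iso_prot = PairedProtocol(pulses if pulses else
                                  (PulseStimulus(nid, 1.0, 1.0, 0.0),))
        iso_rest = find_rest_state(iso, solver=SWEEP)
        iso_res = simulate(iso, iso_prot, solver=SWEEP, rest_state=iso_rest,
                           t_end=300.0)
        np.testing.assert_allclose(res.V(nid), iso_res.V(nid), atol=0.5)
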