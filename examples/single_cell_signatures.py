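"""Single-cell electrophysiological signatures of the two model classes.

Builds one excitatory projection-type (HVC_X) cell and one fast-spiking
interneuron (HVC_INT), applies depolarizing and hyperpolarizing current
pulses, and prints the signatures the model is calibrated to show:
~200 Hz tonic firing at 200 pA, membrane sag and post-inhibitory rebound
(with a delay-loop cell's strong T current), and interneuron spikes that
undershoot rest.
"""

import numpy as np

from csnsim import (
    HVC_INT, HVC_X, NetworkModel, NeuronSpec, SolverOptions,
    default_neuron_params, detect_spikes, find_rest_state, simulate,
)
from csnsim.calibration import ROLE_PARAM_OVERRIDES
from csnsim.stimulus import PairedProtocol, PulseStimulus

solver = SolverOptions(output_dt=0.05)


def pulse_run(params, amplitude, duration=50.0):
    model = NetworkModel([NeuronSpec("N", params.neuron_class,
                                     params=params)], [], {})
    protocol = PairedProtocol((PulseStimulus("N", 100.0, duration,
                                             amplitude),))
    rest = find_rest_state(model, solver=solver)
    res = simulate(model, protocol, solver=solver, rest_state=rest,
                   t_end=100.0 + duration + 250.0)
    return rest[0], res


# --- excitatory projection cell: tonic firing at the calibrated rate
p_x = default_neuron_params(HVC_X)
v_rest, res = pulse_run(p_x, 200.0)
spikes = detect_spikes(res.V("N"), res.t)
rate = spikes.rate(100.0, 150.0)
print(f"HVC_X rest {v_rest:.1f} mV; 200 pA x 50 ms -> {rate:.0f} Hz "
      f"({int(rate * 0.05)} spikes)")

# --- sag and rebound: delay-loop cell (strong, fast T current)
p_e = default_neuron_params(HVC_X).replace(**ROLE_PARAM_OVERRIDES["E2"])
v_rest, res = pulse_run(p_e, -100.0, duration=100.0)
V, t = res.V("N"), res.t
during = (t >= 100.0) & (t < 200.0)
sag = V[during][-1] - V[during].min()
rebound = detect_spikes(V[t >= 200.0], t[t >= 200.0]).count
print(f"E-type cell, -100 pA x 100 ms: min {V[during].min():.1f} mV, "
      f"sag {sag:.1f} mV, rebound burst of {rebound} spikes at release")

# --- interneuron: fast spiking with undershoot
p_i = default_neuron_params(HVC_INT)
v_rest, res = pulse_run(p_i, 200.0)
V, t = res.V("N"), res.t
n = detect_spikes(V, t).count
ahp = V[(t >= 110.0) & (t < 150.0)].min()
print(f"HVC_INT rest {v_rest:.1f} mV; 200 pA -> {n} spikes, "
      f"AHP minimum {ahp:.1f} mV (undershoots rest)")
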