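"""Calibrated per-role parameter overrides for the layered network.

Most kinetic constants are shared within a neuron class
(:func:`csnsim.params.default_neuron_params`); the values below are the
per-role differences fixed by the calibration protocol in
``scripts/calibrate.py``:

* the CSN uses the canonical gH = 6 nS, gCaT = 0.4 nS operating point,
  a higher leak (so the bare S2 excitatory input stays subthreshold —
  the cell fires only when rebound priming and excitation coincide), a
  larger GHK drive scale, and slow T-current de-inactivation so priming
  accumulates over one to two hundred milliseconds of inhibition;
* E2 and E3 fire purely by post-inhibitory rebound inside the delay
  loop: strong T conductance (within the admissible 0.4-5 nS band) with
  activation reaching slightly lower voltages and fast de-inactivation,
  so a ~50 ms inhibitory epoch primes them fully; their SK conductance
  sets how quickly successive rebound cycles attenuate, which ends the
  loop (and the integration window) after roughly two cycles.

Values here are the package's shipped defaults; experiments override
them through ``build_full_network(neuron_overrides=...)``.
"""

from __future__ import annotations

#: Per-role overrides applied on top of the class defaults.
ROLE_PARAM_OVERRIDES: dict = {
    "CSN": {
        "gCaT": 0.4,
        "gH": 6.0,
        "gSK": 0.5,
        "gL": 4.0,
        "ca": {"Ca_ex": 18.0},
        "t": {"theta_b": 0.2, "theta_rrT": -80.0, "sigma_rrT": 3.0},
    },
    "E2": {
        "gCaT": 2.0,
        "gSK": 0.9,
        "gH": 15.0,
        "t": {"theta_aT": -66.0, "tau_r0": 30.0, "tau_r1": 40.0},
    },
    "E3": {
        "gCaT": 2.0,
        "gSK": 0.9,
        "gH": 15.0,
        "t": {"theta_aT": -66.0, "tau_r0": 20.0, "tau_r1": 20.0},
    },
}
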