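"""Rest-state preparation and adaptive integration."""

import numpy as np
import pytest

from csnsim.integrate import (
    SimResult, SimulationError, SolverOptions, find_rest_state, simulate,
)
from csnsim.network import NetworkModel, NeuronSpec, assemble_system, \
    build_full_network
from csnsim.params import default_neuron_params, HVC_X
from csnsim.stimulus import PairedProtocol, PulseStimulus, \
    make_paired_protocol
from csnsim.metrics import detect_spikes
from tests.conftest import SWEEP


@pytest.fixture(scope="module")
def single_cell():
    p = default_neuron_params(HVC_X)
    return NetworkModel([NeuronSpec("N", HVC_X, params=p)], [], {})


class TestRestState:
    def test_derivative_below_tolerance(self, single_cell):
        y = find_rest_state(single_cell, solver=SWEEP)
        f, _ = assemble_system(single_cell, None)
        assert np.max(np.abs(f(0.0, y))) < 1e-6

    def test_resting_potential_physiological(self, single_cell):
        y = find_rest_state(single_cell, solver=SWEEP)
        v = y[0]
        assert -80.0 < v < -60.0  # near -70 mV, not deeply hyperpolarized

    def test_convergence_from_two_basin_points(self, single_cell):
        """Relaxation reaches the same rest state from different guesses."""
        from csnsim.integrate import _initial_state
        from scipy.integrate import solve_ivp

        f, layout = assemble_system(single_cell, None)
        y_a = _initial_state(single_cell)
        y_b = y_a.copy()
        y_b[0] = -60.0  # different in-basin voltage
        y_b[1:7] = np.clip(y_b[1:7] + 0.05, 0, 1)
        ends = []
        for y0 in (y_a, y_b):
            # 5 s >> slowest gate time constant (tau_rs = 300 ms)
            sol = solve_ivp(f, (0.0, 5000.0), y0, method="LSODA",
                            rtol=1e-8, atol=1e-10)
            ends.append(sol.y[:, -1])
        np.testing.assert_allclose(ends[0], ends[1], atol=1e-4)


class TestSimulate:
    def test_zero_stimulus_stays_at_rest(self, single_cell):
        rest = find_rest_state(single_cell, solver=SWEEP)
        prot = PairedProtocol((PulseStimulus("N", 100.0, 50.0, 0.0),))
        res = simulate(single_cell, prot, solver=SWEEP, rest_state=rest,
                       t_end=400.0)
        assert np.max(np.abs(res.V("N") - rest[0])) < 0.5

    def test_uniform_output_grid(self, single_cell):
        rest = find_rest_state(single_cell, solver=SWEEP)
        prot = PairedProtocol((PulseStimulus("N", 100.0, 50.0, 200.0),))
        res = simulate(single_cell, prot, solver=SWEEP, rest_state=rest,
                       t_end=250.0)
        assert np.allclose(np.diff(res.t), SWEEP.output_dt)
        assert res.t[0] == 0.0

    def test_passive_membrane_charges_linearly(self):
        """All conductances zero: V grows at exactly I_app/Cm."""
        p = default_neuron_params(HVC_X).replace(
            gNa=0.0, gK=0.0, gA=0.0, gL=0.0, gCaL=0.0, gCaT=0.0, gSK=0.0,
            gH=0.0)
        m = NetworkModel([NeuronSpec("N", HVC_X, params=p)], [], {})
        prot = PairedProtocol((PulseStimulus("N", 10.0, 40.0, 100.0),))
        layout = m.layout()
        y0 = np.zeros(layout.n_states)
        y0[0] = -70.0
        res = simulate(m, prot, solver=SWEEP, y0=y0, t_end=50.0)
        i = np.searchsorted(res.t, 50.0) - 1
        expected = -70.0 + 100.0 / p.Cm * (res.t[i] - 10.0)
        assert res.V("N")[i] == pytest.approx(expected, rel=1e-6)

    def test_tolerance_refinement_shifts_spikes_little(self, single_cell):
        """Halving rtol/atol moves single-cell spike times < 0.1 ms."""
        rest = find_rest_state(single_cell, solver=SWEEP)
        prot = PairedProtocol((PulseStimulus("N", 100.0, 50.0, 200.0),))
        times = []
        for factor in (1.0, 0.5):
            opts = SolverOptions(output_dt=0.05, rtol=1e-6 * factor,
                                 atol=1e-8 * factor)
            res = simulate(single_cell, prot, solver=opts, rest_state=rest,
                           t_end=250.0)
            times.append(detect_spikes(res.V("N"), res.t).times)
        assert len(times[0]) == len(times[1])
        assert np.max(np.abs(times[0] - times[1])) < 0.1


class TestSolverRobustness:
    def test_cross_solver_spike_count(self, netcache):
        """RK23 and the Adams-based LSODA agree on the CSN spike count."""
        out_rk, _ = netcache.run(delay=50.0)
        model = build_full_network()
        prot = make_paired_protocol(50.0, s1_target="S1", s2_target="S2")
        opts = SolverOptions(method="LSODA", output_dt=0.05)
        rest = find_rest_state(model, solver=opts)
        res = simulate(model, prot, solver=opts, rest_state=rest)
        n_lsoda = detect_spikes(res.V("CSN"), res.t).count
        assert n_lsoda == out_rk.spike_count

    def test_tolerance_tightening_preserves_count(self, netcache):
        """10x tighter tolerances leave the sentinel spike count unchanged."""
        out_base, _ = netcache.run(delay=50.0)
        model = build_full_network()
        prot = make_paired_protocol(50.0, s1_target="S1", s2_target="S2")
        opts = SolverOptions(rtol=1e-7, atol=1e-9, output_dt=0.05)
        rest = find_rest_state(model, solver=opts)
        res = simulate(model, prot, solver=opts, rest_state=rest)
        assert detect_spikes(res.V("CSN"), res.t).count == out_base.spike_count


def test_gates_bounded_along_network_trajectory(netcache):
    """All gating variables stay in [0,1] and Ca stays near/above basal."""
    _, res = netcache.run(delay=150.0)
    for nid in res.model.neuron_ids:
        states = res.neuron_states(nid)
        for var in ("n", "h", "e", "rT", "rf", "rs"):
            tr = states[var]
            assert tr.min() >= -1e-6 and tr.max() <= 1.0 + 1e-6, \
                f"{nid}.{var} escaped [0,1]"
        if "Ca" in states:
            p = res.model.neuron(nid).params
            assert states["Ca"].min() >= p.ca.bCa * 0.99


def test_simresult_export_roundtrip(tmp_path, netcache):
    _, res = netcache.run(delay=50.0)
    res.save(tmp_path / "run")
    import json
    import pandas as pd

    df = pd.read_csv(tmp_path / "run.csv")
    assert "CSN.V" in df.columns and len(df) == res.t.size
    meta = json.loads((tmp_path / "run.json").read_text())
    assert meta["solver"]["rtol"] == res.solver.rtol
    assert meta["delay_ms"] == 50.0
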