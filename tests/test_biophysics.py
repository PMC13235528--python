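"""Gating curves, GHK driving term and single-neuron current equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csnsim.biophysics import (
    ghk_drive, h_current, h_gate_derivatives, h_gate_kinetics,
    membrane_currents, neuron_derivatives, sigmoid_gate, sk_activation,
    t_availability, t_current, t_gate_derivative, tau_rf,
)
from csnsim.params import (
    CalciumParams, GateParams, HGateParams, InvalidParameterError,
    NeuronParams, NeuronState, PhysicalConstants, TGateParams,
    default_neuron_params, HVC_INT, HVC_X,
)


class TestSigmoidGate:
    def test_midpoint_is_half(self):
        gp = GateParams(theta=-35.0, sigma=-5.0)
        assert sigmoid_gate(-35.0, gp) == pytest.approx(0.5)

    def test_asymptotes_with_negative_slope(self):
        gp = GateParams(theta=-35.0, sigma=-5.0)
        assert sigmoid_gate(1e3, gp) == pytest.approx(1.0)
        assert sigmoid_gate(-1e3, gp) == pytest.approx(0.0)

    def test_known_value(self):
        # 1/(1 + e^-1) for theta=-35, sigma=-5 at V=-30
        gp = GateParams(theta=-35.0, sigma=-5.0)
        assert sigmoid_gate(-30.0, gp) == pytest.approx(0.7310585786300049,
                                                        rel=1e-12)

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            GateParams(theta=-35.0, sigma=0.0)

    @given(v1=st.floats(-120, 60), v2=st.floats(-120, 60))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_v(self, v1, v2):
        gp = GateParams(theta=-40.0, sigma=-6.0)
        lo, hi = min(v1, v2), max(v1, v2)
        assert sigmoid_gate(lo, gp) <= sigmoid_gate(hi, gp) + 1e-15


class TestSodiumInactivation:
    def test_alpha_at_minus_15(self):
        # exponent vanishes: alpha = 0.128 exactly; oracle via direct rates
        h_inf, tau = h_gate_kinetics(-15.0)
        alpha, beta = 0.128, 4.0 / (1.0 + math.exp(-(-15.0 + 27.0) / 5.0))
        assert h_inf == pytest.approx(alpha / (alpha + beta), rel=1e-12)

    def test_beta_at_minus_27(self):
        # beta = 4/(1+e^0) = 2
        h_inf, tau = h_gate_kinetics(-27.0)
        alpha = 0.128 * math.exp(-(-27.0 + 15.0) / 18.0)
        assert tau == pytest.approx(1.0 / (alpha + 2.0), rel=1e-12)

    def test_against_arithmetic_oracle(self):
        alpha = 0.128 * math.exp(-(-40.0 + 15.0) / 18.0)
        beta = 4.0 / (1.0 + math.exp(-(-40.0 + 27.0) / 5.0))
        h_inf, tau = h_gate_kinetics(-40.0)
        assert h_inf == pytest.approx(alpha / (alpha + beta), rel=1e-12)
        assert tau == pytest.approx(1.0 / (alpha + beta), rel=1e-12)
        assert 0.0 < h_inf < 1.0 and tau > 0.0


class TestGhkDrive:
    PC = PhysicalConstants(two_F_over_RT=0.0748)

    def test_limit_at_zero(self):
        # L'Hopital: drive(0) = -Ca_ex / (2F/RT)
        assert ghk_drive(0.0, 2.5, self.PC) == pytest.approx(
            -2.5 / 0.0748, rel=1e-9)

    def test_hyperpolarized_asymptote(self):
        # denominator -> 1, so drive ~ Ca_ex * V
        assert ghk_drive(-100.0, 2.5, self.PC) == pytest.approx(
            2.5 * -100.0, rel=1e-3)

    def test_against_high_precision_oracle(self):
        # 50-digit evaluation of V/(1 - exp(kV)) via sympy
        import sympy

        k = sympy.Rational(748, 10000)
        for v in (20.0, -20.0, 1e-3, -1e-3, 0.5, 55.0):
            exact = float(2.5 * sympy.N(
                v / (1 - sympy.exp(k * sympy.Float(v, 50))), 50))
            assert ghk_drive(v, 2.5, self.PC) == pytest.approx(
                exact, rel=1e-10)

    def test_continuous_through_zero_with_shrinking_magnitude(self):
        # always negative (inward); |drive| falls smoothly as V rises
        v = np.linspace(-1.0, 1.0, 2001)
        d = ghk_drive(v, 2.5, self.PC)
        assert np.all(np.isfinite(d))
        assert np.all(d < 0)
        assert np.all(np.diff(np.abs(d)) < 0)


class TestTCurrent:
    TP = TGateParams()
    CA = CalciumParams()
    PC = PhysicalConstants()

    def test_zero_availability_at_rT_zero(self):
        # the two sigmoid terms in bT cancel exactly at rT = 0
        assert t_availability(0.0, self.TP) == pytest.approx(0.0, abs=1e-15)
        assert t_current(-50.0, 0.0, self.TP, self.CA, self.PC,
                         gCaT=0.4) == pytest.approx(0.0, abs=1e-12)

    def test_activation_midpoint(self):
        aT = 1.0 / (1.0 + math.exp(0.0))
        got = t_current(self.TP.theta_aT, 0.6, self.TP, self.CA, self.PC, 1.0)
        expected = (aT ** 3
                    * t_availability(0.6, self.TP) ** 3
                    * ghk_drive(self.TP.theta_aT, self.CA.Ca_ex, self.PC))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_full_evaluation_against_scalar_oracle(self):
        # independent arithmetic for V=-50, rT=0.6 with the default constants
        tp, ca, pc = self.TP, self.CA, self.PC
        aT = 1.0 / (1.0 + math.exp((-50.0 - tp.theta_aT) / tp.sigma_aT))
        bT = (1.0 / (1.0 + math.exp((0.6 - tp.theta_b) / tp.sigma_b))
              - 1.0 / (1.0 + math.exp(-tp.theta_b / tp.sigma_b)))
        drive = ca.Ca_ex * -50.0 / (1.0 - math.exp(pc.two_F_over_RT * -50.0))
        assert t_current(-50.0, 0.6, tp, ca, pc, 0.4) == pytest.approx(
            0.4 * aT ** 3 * bT ** 3 * drive, rel=1e-12)

    def test_rT_relaxation_law(self):
        tp = self.TP
        rT_inf = 1.0 / (1.0 + math.exp((-85.0 - tp.theta_rT) / tp.sigma_rT))
        tau = tp.tau_r0 + tp.tau_r1 / (
            1.0 + math.exp((-85.0 - tp.theta_rrT) / tp.sigma_rrT))
        assert t_gate_derivative(-85.0, 0.3, tp) == pytest.approx(
            (rT_inf - 0.3) / tau, rel=1e-12)


class TestHCurrent:
    HP = HGateParams()

    def test_convex_combination_identity(self):
        # rf = rs = r makes the kr weighting drop out
        for kr in (0.0, 0.3, 1.0):
            hp = HGateParams(kr=kr)
            assert h_current(-80.0, 0.4, 0.4, hp, 6.0) == pytest.approx(
                6.0 * 0.4 * (-80.0 - hp.Vh), rel=1e-12)

    def test_zero_at_reversal(self):
        assert h_current(self.HP.Vh, 0.7, 0.2, self.HP, 6.0) == 0.0

    def test_gate_midpoints(self):
        drf, drs = h_gate_derivatives(self.HP.theta_rf, 0.5, 0.5, self.HP)
        # at V = theta both steady states are 0.5, so derivatives vanish
        assert drf == pytest.approx(0.0, abs=1e-12)
        assert drs == pytest.approx(0.0, abs=1e-12)

    def test_tau_rf_positive_and_finite(self):
        v = np.linspace(-130.0, 20.0, 400)
        tau = tau_rf(v, self.HP)
        assert np.all(np.isfinite(tau)) and np.all(tau > 0)
        # removable singularity at V = -70
        assert tau_rf(-70.0, self.HP) == pytest.approx(
            tau_rf(-70.0 + 1e-7, self.HP), rel=1e-4)


class TestMembraneCurrents:
    def _state(self, p, V):
        from csnsim.biophysics import sigmoid_gate as sg

        h_inf, _ = h_gate_kinetics(V)
        return NeuronState(V=V, n=0.1, h=float(h_inf), e=0.5, rT=0.3,
                           rf=0.2, rs=0.2,
                           Ca_i=p.ca.bCa if p.neuron_class == HVC_X else None)

    def test_zero_at_potassium_reversal(self):
        p = default_neuron_params(HVC_X)
        cur = membrane_currents(self._state(p, p.VK), p)
        assert cur["IK"] == pytest.approx(0.0, abs=1e-12)
        assert cur["IA"] == pytest.approx(0.0, abs=1e-12)
        assert cur["ISK"] == pytest.approx(0.0, abs=1e-12)

    def test_sk_half_activation(self):
        p = default_neuron_params(HVC_X)
        assert sk_activation(p.ca.ks, p.ca.ks) == pytest.approx(0.5)

    def test_interneuron_has_no_sk(self):
        p = default_neuron_params(HVC_INT)
        cur = membrane_currents(self._state(p, -50.0), p)
        assert cur["ISK"] == 0.0

    def test_current_vector_against_printed_formulas(self):
        p = default_neuron_params(HVC_X)
        st_ = self._state(p, -55.0)
        cur = membrane_currents(st_, p)
        V = -55.0
        m = 1.0 / (1.0 + math.exp((V - p.m.theta) / p.m.sigma))
        a = 1.0 / (1.0 + math.exp((V - p.a.theta) / p.a.sigma))
        s = 1.0 / (1.0 + math.exp((V - p.s.theta) / p.s.sigma))
        drive = p.ca.Ca_ex * V / (1.0 - math.exp(p.pc.two_F_over_RT * V))
        assert cur["IL"] == pytest.approx(p.gL * (V - p.VL), rel=1e-12)
        assert cur["IK"] == pytest.approx(p.gK * 0.1 ** 4 * (V - p.VK),
                                          rel=1e-12)
        assert cur["INa"] == pytest.approx(
            p.gNa * m ** 3 * st_.h * (V - p.VNa), rel=1e-12)
        assert cur["IA"] == pytest.approx(p.gA * a * 0.5 * (V - p.VK),
                                          rel=1e-12)
        assert cur["ICaL"] == pytest.approx(p.gCaL * s ** 2 * drive,
                                            rel=1e-12)


class TestNeuronDerivatives:
    @given(x=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_gates_relax_into_unit_interval(self, x):
        p = default_neuron_params(HVC_X)
        st0 = NeuronState(V=-70.0, n=0.0, h=0.0, e=0.0, rT=0.0, rf=0.0,
                          rs=0.0, Ca_i=p.ca.bCa)
        d0 = neuron_derivatives(st0, p)
        assert min(d0.n, d0.h, d0.e, d0.rT, d0.rf, d0.rs) >= 0.0
        st1 = NeuronState(V=-70.0, n=1.0, h=1.0, e=1.0, rT=1.0, rf=1.0,
                          rs=1.0, Ca_i=p.ca.bCa)
        d1 = neuron_derivatives(st1, p)
        assert max(d1.n, d1.h, d1.e, d1.rT, d1.rf, d1.rs) <= 0.0

    def test_nonfinite_state_rejected(self):
        p = default_neuron_params(HVC_X)
        bad = NeuronState(V=float("nan"), n=0.1, h=0.5, e=0.5, rT=0.2,
                          rf=0.1, rs=0.1, Ca_i=0.05)
        with pytest.raises(ValueError):
            neuron_derivatives(bad, p)

    def test_calcium_pump_restores_basal(self):
        p = default_neuron_params(HVC_X)
        st_ = NeuronState(V=p.VK, n=0.0, h=0.5, e=0.5, rT=0.0, rf=0.0,
                          rs=0.0, Ca_i=2.0 * p.ca.bCa)
        d = neuron_derivatives(st_, p)
        # at VK with rT=0, Ca currents are ~0; pump must pull Ca down
        assert d.Ca_i < 0.0


def test_characteristic_firing_rate(isolated_x_run):
    """200 pA x 50 ms drives the stimulus-selective cell at ~200 Hz."""
    from csnsim.metrics import detect_spikes

    _, result = isolated_x_run
    spikes = detect_spikes(result.V("A"), result.t)
    in_pulse = spikes.times[(spikes.times >= 100.0) & (spikes.times < 150.0)]
    assert len(in_pulse) == 10


def test_sag_and_rebound_signatures():
    """Hyperpolarizing current produces sag; a strong-T cell rebounds."""
    from csnsim.network import NetworkModel, NeuronSpec
    from csnsim.params import default_neuron_params
    from csnsim.stimulus import PairedProtocol, PulseStimulus
    from csnsim.integrate import find_rest_state, simulate
    from csnsim.metrics import detect_spikes
    from csnsim.calibration import ROLE_PARAM_OVERRIDES
    from tests.conftest import SWEEP

    p = default_neuron_params(HVC_X).replace(**ROLE_PARAM_OVERRIDES["E2"])
    model = NetworkModel([NeuronSpec("N", HVC_X, params=p)], [], {})
    protocol = PairedProtocol((PulseStimulus("N", 100.0, 100.0, -100.0),))
    rest = find_rest_state(model, solver=SWEEP)
    res = simulate(model, protocol, solver=SWEEP, rest_state=rest,
                   t_end=450.0)
    V, t = res.V("N"), res.t
    during = (t >= 100.0) & (t < 200.0)
    sag = V[during][-1] - V[during].min()
    assert sag > 2.0  # depolarizing sag during sustained hyperpolarization
    post = detect_spikes(V[t >= 200.0], t[t >= 200.0])
    assert post.count >= 2  # post-inhibitory rebound burst


def test_interneuron_spikes_undershoot_rest():
    from csnsim.network import NetworkModel, NeuronSpec
    from csnsim.params import default_neuron_params
    from csnsim.stimulus import PairedProtocol, PulseStimulus
    from csnsim.integrate import find_rest_state, simulate
    from tests.conftest import SWEEP

    p = default_neuron_params(HVC_INT)
    model = NetworkModel([NeuronSpec("I", HVC_INT, params=p)], [], {})
    protocol = PairedProtocol((PulseStimulus("I", 100.0, 50.0, 200.0),))
    rest = find_rest_state(model, solver=SWEEP)
    res = simulate(model, protocol, solver=SWEEP, rest_state=rest,
                   t_end=300.0)
    V, t = res.V("I"), res.t
    v_rest = rest[res.layout.var_index("I", "V")]
    inter_spike = (t >= 110.0) & (t < 150.0)
    assert V[inter_spike].min() < v_rest - 1.0
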