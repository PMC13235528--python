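"""Ionic-current equations for single-compartment HVC-type model neurons.

These are plain numpy implementations of every gating curve and current
used by the model.  The network integrator runs a compiled copy of the
same math (:mod:`csnsim._kernel`); the functions here are the readable
reference used for current reconstruction and for testing, and operate
elementwise on scalars or arrays.

Sign convention: currents are written as they appear in the membrane
equation ``Cm dV/dt = -sum(I_ionic) - I_syn + I_app``; a *negative*
ionic current therefore depolarizes the cell (inward).
"""

from __future__ import annotations

import numpy as np

from .params import (
    CalciumParams,
    GateParams,
    HGateParams,
    InvalidParameterError,
    NeuronParams,
    NeuronState,
    PhysicalConstants,
    TGateParams,
    HVC_X,
)

__all__ = [
    "sigmoid_gate",
    "h_gate_kinetics",
    "ghk_drive",
    "t_current",
    "t_gate_derivative",
    "h_current",
    "h_gate_derivatives",
    "tau_rf",
    "sk_activation",
    "membrane_currents",
    "neuron_derivatives",
]


def sigmoid_gate(V, gp: GateParams):
    """Boltzmann steady state 1/(1+exp((V-theta)/sigma)); 0.5 at V=theta."""
    if gp.sigma == 0:
        raise InvalidParameterError("gate slope sigma must be nonzero")
    return 1.0 / (1.0 + np.exp((V - gp.theta) / gp.sigma))


def h_gate_kinetics(V):
    """Sodium inactivation: (h_inf, tau_h) from the alpha/beta rates.

    alpha_h = 0.128 exp(-(V+15)/18), beta_h = 4/(1+exp(-(V+27)/5)).
    """
    alpha = 0.128 * np.exp(-(np.asarray(V, dtype=float) + 15.0) / 18.0)
    beta = 4.0 / (1.0 + np.exp(-(np.asarray(V, dtype=float) + 27.0) / 5.0))
    return alpha / (alpha + beta), 1.0 / (alpha + beta)


def ghk_drive(V, Ca_ex: float, pc: PhysicalConstants):
    """GHK-form driving term Ca_ex * V / (1 - exp(2FV/RT)).

    Negative for all V (inward when multiplied by a positive conductance
    and gates).  The removable singularity at V = 0 is evaluated by its
    series expansion: the limit is -Ca_ex/(2F/RT).
    """
    k = pc.two_F_over_RT
    V = np.asarray(V, dtype=float)
    x = k * V
    small = np.abs(x) < 1e-4
    # series of V/(1-e^{kV}) = -(1/k) * 1/(1 + x/2 + x^2/6 + ...)
    series = -(1.0 / k) / (1.0 + x / 2.0 + x * x / 6.0)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        exact = V / (1.0 - np.exp(x))
    drive = Ca_ex * np.where(small, series, exact)
    return drive if drive.ndim else float(drive)


def t_availability(rT, tp: TGateParams):
    """bT_inf(rT): availability built from the offset-subtracted Boltzmann.

    Exactly 0 at rT = 0 (the two sigmoid terms cancel) and increasing in rT.
    """
    return (
        1.0 / (1.0 + np.exp((rT - tp.theta_b) / tp.sigma_b))
        - 1.0 / (1.0 + np.exp(-tp.theta_b / tp.sigma_b))
    )


def t_current(V, rT, tp: TGateParams, ca: CalciumParams, pc: PhysicalConstants,
              gCaT: float):
    """ICaT = gCaT * aT_inf(V)^3 * bT_inf(rT)^3 * ghk_drive(V)."""
    aT = 1.0 / (1.0 + np.exp((V - tp.theta_aT) / tp.sigma_aT))
    bT = t_availability(rT, tp)
    return gCaT * aT ** 3 * bT ** 3 * ghk_drive(V, ca.Ca_ex, pc)


def t_gate_derivative(V, rT, tp: TGateParams):
    """drT/dt = (rT_inf(V) - rT)/tau_rT(V); slow de-inactivation variable."""
    rT_inf = 1.0 / (1.0 + np.exp((V - tp.theta_rT) / tp.sigma_rT))
    tau = tp.tau_r0 + tp.tau_r1 / (1.0 + np.exp((V - tp.theta_rrT) / tp.sigma_rrT))
    return (rT_inf - rT) / tau


def tau_rf(V, hp: HGateParams):
    """Fast H-gate time constant, Destexhe form with prf scale.

    tau_rf = prf / (alpha + beta), alpha = -7.4(V+70)/(exp(-(V+70)/0.8)-1),
    beta = 65 exp(-(V+56)/23).  alpha's singularity at V = -70 is removable
    (limit 7.4*0.8 = 5.92).
    """
    V = np.asarray(V, dtype=float)
    u = V + 70.0
    small = np.abs(u) < 1e-6
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        alpha = np.where(small, 7.4 * 0.8, -7.4 * u / (np.expm1(-u / 0.8)))
    beta = 65.0 * np.exp(-(V + 56.0) / 23.0)
    out = hp.prf / (alpha + beta)
    return out if out.ndim else float(out)


def h_current(V, rf, rs, hp: HGateParams, gH: float):
    """IH = gH [kr rf + (1-kr) rs] (V - Vh)."""
    return gH * (hp.kr * rf + (1.0 - hp.kr) * rs) * (V - hp.Vh)


def h_gate_derivatives(V, rf, rs, hp: HGateParams):
    """(drf/dt, drs/dt) for the fast and slow H-current activation gates."""
    rf_inf = 1.0 / (1.0 + np.exp((V - hp.theta_rf) / hp.sigma_rf))
    # printed form 1/(1+exp(-(V-theta_rs)/sigma_rs)); sigma_rs < 0 makes
    # the gate open under hyperpolarization
    rs_inf = 1.0 / (1.0 + np.exp(-(V - hp.theta_rs) / hp.sigma_rs))
    return (rf_inf - rf) / tau_rf(V, hp), (rs_inf - rs) / hp.tau_rs


def sk_activation(Ca_i, ks: float):
    """k_inf(Ca) = Ca^2/(Ca^2 + ks^2); 0.5 at Ca_i = ks."""
    c2 = np.asarray(Ca_i, dtype=float) ** 2
    return c2 / (c2 + ks * ks)


def membrane_currents(state: NeuronState, p: NeuronParams) -> dict:
    """All ionic currents at one state point, keyed by name.

    m, a, s, aT, bT and the SK activation are instantaneous functions;
    n, h, e, rT, rf, rs are read from the state.  For HVC_INT the SK
    current is reported as 0.
    """
    V = state.V
    out = {
        "IL": p.gL * (V - p.VL),
        "IK": p.gK * state.n ** 4 * (V - p.VK),
        "INa": p.gNa * sigmoid_gate(V, p.m) ** 3 * state.h * (V - p.VNa),
        "IA": p.gA * sigmoid_gate(V, p.a) * state.e * (V - p.VK),
        "ICaL": p.gCaL * sigmoid_gate(V, p.s) ** 2
        * ghk_drive(V, p.ca.Ca_ex, p.pc),
        "ICaT": t_current(V, state.rT, p.t, p.ca, p.pc, p.gCaT),
        "IH": h_current(V, state.rf, state.rs, p.h_cur, p.gH),
    }
    if p.neuron_class == HVC_X and state.Ca_i is not None:
        out["ISK"] = p.gSK * sk_activation(state.Ca_i, p.ca.ks) * (V - p.VK)
    else:
        out["ISK"] = 0.0
    return out


def neuron_derivatives(state: NeuronState, p: NeuronParams,
                       I_syn_total: float = 0.0, I_app: float = 0.0) -> NeuronState:
    """Time derivative of the full neuron state.

    Cm dV/dt = -sum(I_ionic) - I_syn_total + I_app.  The calcium pump
    relaxes Ca_i toward the basal level bCa.
    """
    state.validate()
    cur = membrane_currents(state, p)
    I_ion = sum(cur.values())
    dV = (-(I_ion) - I_syn_total + I_app) / p.Cm

    V = state.V
    n_inf = sigmoid_gate(V, p.n)
    h_inf, tau_h = h_gate_kinetics(V)
    e_inf = sigmoid_gate(V, p.e)
    dn = (n_inf - state.n) / p.n.tau
    dh = (h_inf - state.h) / tau_h
    de = (e_inf - state.e) / p.e.tau
    drT = t_gate_derivative(V, state.rT, p.t)
    drf, drs = h_gate_derivatives(V, state.rf, state.rs, p.h_cur)

    dCa = None
    if p.neuron_class == HVC_X and state.Ca_i is not None:
        dCa = (
            -p.ca.f * p.ca.eps * (cur["ICaL"] + cur["ICaT"])
            - p.ca.kCa * (state.Ca_i - p.ca.bCa)
        )
    return NeuronState(V=dV, n=dn, h=dh, e=de, rT=drT, rf=drf, rs=drs, Ca_i=dCa)
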