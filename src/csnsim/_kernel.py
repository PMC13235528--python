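"""Compiled right-hand side of the coupled network ODE system.

The network (neurons + synapses + DC-pulse drive) is packed into flat
numpy arrays and evaluated by a numba-jitted kernel.  The math here is a
line-for-line copy of :mod:`csnsim.biophysics` / :mod:`csnsim.synapses`;
agreement between the two paths is asserted by the test suite.

State layout: per-neuron blocks [V, n, h, e, rT, rf, rs(, Ca_i)] — 8
slots for HVC_X, 7 for HVC_INT — followed by one s gate per synapse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import NeuronParams, HVC_X

# ---------------------------------------------------------------- packing

#: number of per-neuron parameter columns
NPCOLS = 49

_COL = {name: i for i, name in enumerate([
    "Cm", "gNa", "gK", "gA", "gL", "gCaL", "gCaT", "gSK", "gH",
    "VNa", "VK", "VL",
    "th_m", "sg_m",
    "th_n", "sg_n", "tau_n",
    "th_a", "sg_a",
    "th_e", "sg_e", "tau_e",
    "th_s", "sg_s",
    "th_aT", "sg_aT", "th_b", "sg_b", "th_rT", "sg_rT",
    "tau_r0", "tau_r1", "th_rrT", "sg_rrT",
    "kr", "prf", "th_rf", "sg_rf", "th_rs", "sg_rs", "tau_rs", "Vh",
    "f", "eps", "kCa", "bCa", "ks", "Ca_ex", "kGHK",
])}


def pack_neuron_params(plist: list) -> tuple:
    """Pack NeuronParams into (P matrix, state offsets, is_x flags, n_states)."""
    nn = len(plist)
    P = np.zeros((nn, NPCOLS))
    isx = np.zeros(nn, dtype=np.int64)
    off = np.zeros(nn, dtype=np.int64)
    pos = 0
    for i, p in enumerate(plist):
        row = P[i]
        row[_COL["Cm"]] = p.Cm
        for g in ("gNa", "gK", "gA", "gL", "gCaL", "gCaT", "gSK", "gH",
                  "VNa", "VK", "VL"):
            row[_COL[g]] = getattr(p, g)
        row[_COL["th_m"]], row[_COL["sg_m"]] = p.m.theta, p.m.sigma
        row[_COL["th_n"]], row[_COL["sg_n"]] = p.n.theta, p.n.sigma
        row[_COL["tau_n"]] = p.n.tau
        row[_COL["th_a"]], row[_COL["sg_a"]] = p.a.theta, p.a.sigma
        row[_COL["th_e"]], row[_COL["sg_e"]] = p.e.theta, p.e.sigma
        row[_COL["tau_e"]] = p.e.tau
        row[_COL["th_s"]], row[_COL["sg_s"]] = p.s.theta, p.s.sigma
        t = p.t
        row[_COL["th_aT"]], row[_COL["sg_aT"]] = t.theta_aT, t.sigma_aT
        row[_COL["th_b"]], row[_COL["sg_b"]] = t.theta_b, t.sigma_b
        row[_COL["th_rT"]], row[_COL["sg_rT"]] = t.theta_rT, t.sigma_rT
        row[_COL["tau_r0"]], row[_COL["tau_r1"]] = t.tau_r0, t.tau_r1
        row[_COL["th_rrT"]], row[_COL["sg_rrT"]] = t.theta_rrT, t.sigma_rrT
        h = p.h_cur
        row[_COL["kr"]], row[_COL["prf"]] = h.kr, h.prf
        row[_COL["th_rf"]], row[_COL["sg_rf"]] = h.theta_rf, h.sigma_rf
        row[_COL["th_rs"]], row[_COL["sg_rs"]] = h.theta_rs, h.sigma_rs
        row[_COL["tau_rs"]], row[_COL["Vh"]] = h.tau_rs, h.Vh
        ca = p.ca
        row[_COL["f"]], row[_COL["eps"]] = ca.f, ca.eps
        row[_COL["kCa"]], row[_COL["bCa"]] = ca.kCa, ca.bCa
        row[_COL["ks"]], row[_COL["Ca_ex"]] = ca.ks, ca.Ca_ex
        row[_COL["kGHK"]] = p.pc.two_F_over_RT
        isx[i] = 1 if p.neuron_class == HVC_X else 0
        off[i] = pos
        pos += 8 if isx[i] else 7
    return P, off, isx, pos


# ---------------------------------------------------------------- kernel

@njit(cache=True)
def _ghk(V, Ca_ex, k):
    x = k * V
    if abs(x) < 1e-4:
        return Ca_ex * (-(1.0 / k) / (1.0 + x / 2.0 + x * x / 6.0))
    return Ca_ex * V / (1.0 - np.exp(x))


@njit(cache=True)
def _tau_rf(V, prf):
    u = V + 70.0
    if abs(u) < 1e-6:
        alpha = 7.4 * 0.8
    else:
        alpha = -7.4 * u / (np.expm1(-u / 0.8))
    beta = 65.0 * np.exp(-(V + 56.0) / 23.0)
    return prf / (alpha + beta)


@njit(cache=True)
def rhs(t, y, P, off, isx,
        spre, spost, sg, svrev, sar, sad, stmax, skp, svt, soff,
        stim_tgt, stim_on, stim_dur, stim_amp):
    dy = np.zeros(y.shape[0])
    nn = off.shape[0]
    isyn = np.zeros(nn)

    # synapses: accumulate postsynaptic current, advance the s gates
    for j in range(spre.shape[0]):
        s = y[soff + j]
        v_post = y[off[spost[j]]]
        isyn[spost[j]] += sg[j] * s * (v_post - svrev[j])
        v_pre = y[off[spre[j]]]
        T = stmax[j] / (1.0 + np.exp(-(v_pre - svt[j]) / skp[j]))
        dy[soff + j] = sar[j] * T * (1.0 - s) - sad[j] * s

    for i in range(nn):
        o = off[i]
        V = y[o]
        n_ = y[o + 1]
        h_ = y[o + 2]
        e_ = y[o + 3]
        rT = y[o + 4]
        rf = y[o + 5]
        rs = y[o + 6]
        p = P[i]

        m_inf = 1.0 / (1.0 + np.exp((V - p[12]) / p[13]))
        n_inf = 1.0 / (1.0 + np.exp((V - p[14]) / p[15]))
        a_inf = 1.0 / (1.0 + np.exp((V - p[17]) / p[18]))
        e_inf = 1.0 / (1.0 + np.exp((V - p[19]) / p[20]))
        s_inf = 1.0 / (1.0 + np.exp((V - p[22]) / p[23]))

        alpha_h = 0.128 * np.exp(-(V + 15.0) / 18.0)
        beta_h = 4.0 / (1.0 + np.exp(-(V + 27.0) / 5.0))

        drive = _ghk(V, p[47], p[48])

        IL = p[4] * (V - p[11])
        IK = p[2] * n_ ** 4 * (V - p[10])
        INa = p[1] * m_inf ** 3 * h_ * (V - p[9])
        IA = p[3] * a_inf * e_ * (V - p[10])
        ICaL = p[5] * s_inf ** 2 * drive

        aT = 1.0 / (1.0 + np.exp((V - p[24]) / p[25]))
        bT = (1.0 / (1.0 + np.exp((rT - p[26]) / p[27]))
              - 1.0 / (1.0 + np.exp(-p[26] / p[27])))
        ICaT = p[6] * aT ** 3 * bT ** 3 * drive

        IH = p[8] * (p[34] * rf + (1.0 - p[34]) * rs) * (V - p[41])

        ISK = 0.0
        if isx[i] == 1:
            ca_i = y[o + 7]
            ISK = p[7] * (ca_i * ca_i / (ca_i * ca_i + p[46] * p[46])) * (V - p[10])
            dy[o + 7] = (-p[42] * p[43] * (ICaL + ICaT)
                         - p[44] * (ca_i - p[45]))

        iapp = 0.0
        for kk in range(stim_tgt.shape[0]):
            if stim_tgt[kk] == i and stim_on[kk] <= t < stim_on[kk] + stim_dur[kk]:
                iapp += stim_amp[kk]

        dy[o] = (-(IL + IK + INa + IA + ICaL + ICaT + ISK + IH)
                 - isyn[i] + iapp) / p[0]
        dy[o + 1] = (n_inf - n_) / p[16]
        dy[o + 2] = alpha_h * (1.0 - h_) - beta_h * h_  # == (h_inf - h)/tau_h
        dy[o + 3] = (e_inf - e_) / p[21]

        rT_inf = 1.0 / (1.0 + np.exp((V - p[28]) / p[29]))
        tau_rT = p[30] + p[31] / (1.0 + np.exp((V - p[32]) / p[33]))
        dy[o + 4] = (rT_inf - rT) / tau_rT

        rf_inf = 1.0 / (1.0 + np.exp((V - p[36]) / p[37]))
        rs_inf = 1.0 / (1.0 + np.exp(-(V - p[38]) / p[39]))
        dy[o + 5] = (rf_inf - rf) / _tau_rf(V, p[35])
        dy[o + 6] = (rs_inf - rs) / p[40]

    return dy
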