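CSN:
  Cm: 40.0
  VK: -90.0
  VL: -75.0
  VNa: 55.0
  a:
    sigma: -10.0
    tau: null
    theta: -20.0
  ca:
    Ca_ex: 18.0
    bCa: 0.05
    eps: 0.025
    f: 0.01
    kCa: 0.02
    ks: 0.4
  e:
    sigma: 5.0
    tau: 20.0
    theta: -60.0
  gA: 2.0
  gCaL: 0.5
  gCaT: 0.4
  gH: 6.0
  gK: 240.0
  gL: 4.0
  gNa: 450.0
  gSK: 0.5
  h_cur:
    Vh: -30.0
    kr: 0.6
    prf: 6000.0
    sigma_rf: 6.0
    sigma_rs: -6.0
    tau_rs: 300.0
    theta_rf: -90.0
    theta_rs: -90.0
  m:
    sigma: -5.0
    tau: null
    theta: -35.0
  n:
    sigma: -5.0
    tau: 1.0
    theta: -30.0
  neuron_class: HVC_X
  pc:
    two_F_over_RT: 0.0748678643192098
  s:
    sigma: -5.0
    tau: null
    theta: -20.0
  t:
    sigma_aT: -4.0
    sigma_b: -0.1
    sigma_rT: 3.0
    sigma_rrT: 3.0
    tau_r0: 60.0
    tau_r1: 140.0
    theta_aT: -62.0
    theta_b: 0.2
    theta_rT: -75.0
    theta_rrT: -80.0
E2:
  Cm: 40.0
  VK: -90.0
  VL: -75.0
  VNa: 55.0
  a:
    sigma: -10.0
    tau: null
    theta: -20.0
  ca:
    Ca_ex: 10.0
    bCa: 0.05
    eps: 0.025
    f: 0.01
    kCa: 0.02
    ks: 0.4
  e:
    sigma: 5.0
    tau: 20.0
    theta: -60.0
  gA: 2.0
  gCaL: 0.5
  gCaT: 2.0
  gH: 15.0
  gK: 240.0
  gL: 1.5
  gNa: 450.0
  gSK: 0.9
  h_cur:
    Vh: -30.0
    kr: 0.6
    prf: 6000.0
    sigma_rf: 6.0
    sigma_rs: -6.0
    tau_rs: 300.0
    theta_rf: -90.0
    theta_rs: -90.0
  m:
    sigma: -5.0
    tau: null
    theta: -35.0
  n:
    sigma: -5.0
    tau: 1.0
    theta: -30.0
  neuron_class: HVC_X
  pc:
    two_F_over_RT: 0.0748678643192098
  s:
    sigma: -5.0
    tau: null
    theta: -20.0
  t:
    sigma_aT: -4.0
    sigma_b: -0.1
    sigma_rT: 3.0
    sigma_rrT: 4.0
    tau_r0: 30.0
    tau_r1: 40.0
    theta_aT: -66.0
    theta_b: 0.25
    theta_rT: -75.0
    theta_rrT: -72.0
E3:
  Cm: 40.0
  VK: -90.0
  VL: -75.0
  VNa: 55.0
  a:
    sigma: -10.0
    tau: null
    theta: -20.0
  ca:
    Ca_ex: 10.0
    bCa: 0.05
    eps: 0.025
    f: 0.01
    kCa: 0.02
    ks: 0.4
  e:
    sigma: 5.0
    tau: 20.0
    theta: -60.0
  gA: 2.0
  gCaL: 0.5
  gCaT: 2.0
  gH: 15.0
  gK: 240.0
  gL: 1.5
  gNa: 450.0
  gSK: 0.9
  h_cur:
    Vh: -30.0
    kr: 0.6
    prf: 6000.0
    sigma_rf: 6.0
    sigma_rs: -6.0
    tau_rs: 300.0
    theta_rf: -90.0
    theta_rs: -90.0
  m:
    sigma: -5.0
    tau: null
    theta: -35.0
  n:
    sigma: -5.0
    tau: 1.0
    theta: -30.0
  neuron_class: HVC_X
  pc:
    two_F_over_RT: 0.0748678643192098
  s:
    sigma: -5.0
    tau: null
    theta: -20.0
  t:
    sigma_aT: -4.0
    sigma_b: -0.1
    sigma_rT: 3.0
    sigma_rrT: 4.0
    tau_r0: 20.0
    tau_r1: 20.0
    theta_aT: -66.0
    theta_b: 0.25
    theta_rT: -75.0
    theta_rrT: -72.0
HVC_INT:
  Cm: 25.0
  VK: -90.0
  VL: -65.0
  VNa: 55.0
  a:
    sigma: -10.0
    tau: null
    theta: -20.0
  ca:
    Ca_ex: 10.0
    bCa: 0.05
    eps: 0.025
    f: 0.01
    kCa: 0.02
    ks: 0.4
  e:
    sigma: 5.0
    tau: 20.0
    theta: -60.0
  gA: 1.0
  gCaL: 0.1
  gCaT: 0.1
  gH: 0.5
  gK: 700.0
  gL: 2.5
  gNa: 700.0
  gSK: 0.0
  h_cur:
    Vh: -30.0
    kr: 0.6
    prf: 6000.0
    sigma_rf: 6.0
    sigma_rs: -6.0
    tau_rs: 300.0
    theta_rf: -90.0
    theta_rs: -90.0
  m:
    sigma: -5.0
    tau: null
    theta: -35.0
  n:
    sigma: -4.0
    tau: 3.0
    theta: -32.0
  neuron_class: HVC_INT
  pc:
    two_F_over_RT: 0.0748678643192098
  s:
    sigma: -5.0
    tau: null
    theta: -20.0
  t:
    sigma_aT: -4.0
    sigma_b: -0.1
    sigma_rT: 3.0
    sigma_rrT: 4.0
    tau_r0: 60.0
    tau_r1: 140.0
    theta_aT: -62.0
    theta_b: 0.25
    theta_rT: -75.0
    theta_rrT: -72.0
HVC_X:
  Cm: 40.0
  VK: -90.0
  VL: -75.0
  VNa: 55.0
  a:
    sigma: -10.0
    tau: null
    theta: -20.0
  ca:
    Ca_ex: 10.0
    bCa: 0.05
    eps: 0.025
    f: 0.01
    kCa: 0.02
    ks: 0.4
  e:
    sigma: 5.0
    tau: 20.0
    theta: -60.0
  gA: 2.0
  gCaL: 0.5
  gCaT: 0.4
  gH: 6.0
  gK: 240.0
  gL: 1.5
  gNa: 450.0
  gSK: 6.0
  h_cur:
    Vh: -30.0
    kr: 0.6
    prf: 6000.0
    sigma_rf: 6.0
    sigma_rs: -6.0
    tau_rs: 300.0
    theta_rf: -90.0
    theta_rs: -90.0
  m:
    sigma: -5.0
    tau: null
    theta: -35.0
  n:
    sigma: -5.0
    tau: 1.0
    theta: -30.0
  neuron_class: HVC_X
  pc:
    two_F_over_RT: 0.0748678643192098
  s:
    sigma: -5.0
    tau: null
    theta: -20.0
  t:
    sigma_aT: -4.0
    sigma_b: -0.1
    sigma_rT: 3.0
    sigma_rrT: 4.0
    tau_r0: 60.0
    tau_r1: 140.0
    theta_aT: -62.0
    theta_b: 0.25
    theta_rT: -75.0
    theta_rrT: -72.0
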