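# Canonical default run configuration: full layered network, paired
# stimulus at a 50 ms inter-stimulus delay (the default operating point:
# CSN gH = 6 nS, gCaT = 0.4 nS live in the calibrated class defaults).
experiment:
  name: simulate
network:
  neuron_overrides: {}
  synapse_g: {}
  drive_IB_directly: false
protocol:
  condition: paired
  delay: 50.0
  dur1: 50.0
  dur2: 50.0
  amp1: 200.0
  amp2: 200.0
solver:
  method: RK23
  rtol: 1.0e-6
  atol: 1.0e-8
  output_dt: 0.01
  max_step: 1.0
output_dir: runs
seed: null
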