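# Methods

## Model

Every neuron is a single-compartment conductance-based
Hodgkin–Huxley-type model.  Two classes are implemented:

* **HVC_X** (excitatory projection cells, including the
  combination-sensitive output neuron, CSN): leak, transient sodium
  (instantaneous m∞³, dynamic h via the α/β rates
  αh = 0.128·e^(−(V+15)/18), βh = 4/(1+e^(−(V+27)/5))), delayed
  rectifier (n⁴), A-type potassium (instantaneous a∞ with dynamic
  inactivation e), L-type and T-type calcium with GHK-form driving term,
  SK (calcium-gated potassium) and H current.  8 state variables
  (V, n, h, e, rT, rf, rs, Ca_i).
* **HVC_INT** (inhibitory interneurons): same structure without SK or a
  calcium pool (7 state variables) and with a large delayed rectifier so
  spikes undershoot the resting potential.

The T-type current is the mechanistic centrepiece:
ICaT = gCaT·aT∞³(V)·bT∞³(rT)·Ca_ex·V/(1−e^(2FV/RT)).  Activation aT is
instantaneous and engages below ≈ −55 mV; availability bT is an
instantaneous, offset-subtracted sigmoid of the slow variable rT
(exactly 0 at rT = 0), and rT relaxes toward a hyperpolarization-
activated steady state with a voltage-dependent time constant.  rT is
therefore a memory of recent hyperpolarization: it is the quantity that
accumulates during the inter-stimulus gap ("delay-dependent priming")
and is spent during the rebound burst.

The H current uses fast and slow activation gates,
IH = gH[kr·rf + (1−kr)·rs](V−Vh) with Vh = −30 mV; the fast time
constant follows the Destexhe form
τrf = prf/(α+β), α = −7.4(V+70)/(e^(−(V+70)/0.8)−1),
β = 65·e^(−(V+56)/23), with the removable singularity at V = −70 mV
evaluated by its limit.  The calcium pump is implemented as
−kCa(Ca_i − bCa), relaxing calcium to its basal level, so that the pool
is bounded and SK-mediated spike-frequency adaptation recovers between
events.

Synapses are first-order kinetic conductances
(ds/dt = ar[T](1−s) − ad·s, I = g·s·(V−Vrev)) with sigmoidal transmitter
release [T] = Tmax/(1+e^(−(Vpre−VT)/Kp)), Tmax = 1, Kp = 5, VT = 2 mV.
AMPA: ar = 1.1, ad = 0.19, Vrev = 0 mV.  GABA_A: ar = 5, ad = 0.18,
Vrev = −95 mV.  The hyperpolarized GABA_A reversal is required for the
inhibition to drive the CSN to its ≈ −89 mV integration-window minimum;
it is exposed in configuration.  Transmission is instantaneous (no
axonal latency parameter); each synapse adds one ODE.

## Parameters

Units are mV, ms, nS, pA, pF throughout (nS·mV = pA, pA/pF = mV/ms).
Class defaults live in `csnsim.params.default_neuron_params`, per-role
differences in `csnsim.calibration.ROLE_PARAM_OVERRIDES`, and synaptic
weights in `csnsim.network.DEFAULT_SYNAPSE_G`; the same values ship as
`csnsim/conf/neuron_defaults.yaml`.  The parameters that matter most:

| parameter | default | role |
| --- | --- | --- |
| Cm (HVC_X) | 40 pF | sets membrane time scale (τm ≈ 10–27 ms with leak) |
| gNa/gK (HVC_X) | 450/240 nS | spike generation; tuned so 200 pA × 50 ms gives exactly 10 spikes (200 Hz) |
| gCaT (CSN) | 0.4 nS | burst generator; one extra spike per ≈ 0.1 nS |
| gH (CSN) | 6 nS | sag and rebound kick; sets window minimum (−89 mV at 6 nS, −85 mV at 20 nS) |
| gCaT (E2, E3) | 2.0 nS | loop rebound cells, fast rT kinetics (τ ≈ 30–70 ms) |
| gSK (E2, E3) | 0.9 nS | loop attenuation: calcium accumulated across rebound cycles quenches the third cycle, ending the integration window at ≈ 320 ms absolute |
| τrT (CSN) | 60 + 140/(1+e^((V+80)/3)) ms | priming accumulates over ≈ 150–200 ms of hyperpolarization and decays within tens of ms at rest |
| A→E1 | 3.4 nS | deliberately weak: E1 must integrate sustained A firing, which places the stimulus duration (≈ 30 ms) and intensity (≈ 100 pA) thresholds |
| I_A→CSN | 22 nS | inhibition depth (window minimum ≈ −89 mV) |
| B→CSN | 2.6 nS | excitatory trigger, individually subthreshold (S2 alone never fires the CSN) |

The GHK driving term carries an arbitrary concentration scale
(`Ca_ex`, 10 for the shared class default, 18 for the CSN); reported
reconstructed currents are therefore in arbitrary units, and only
relative and normalized comparisons are meaningful.  2F/RT defaults to
its physical value at 310 K and is configurable.

Calibration was performed with `scripts/calibrate.py`: the kinetic
structure was fixed first against single-cell signatures (tonic 200 Hz
firing with mild adaptation, sag, post-inhibitory rebound, interneuron
undershoot), then the network-level anchors (delay anchors, conductance
ladder, window minimum, control silence, stimulus thresholds) fixed the
remaining conductances; `verify` re-checks all 17 anchors and `search`
re-derives the two swept CSN afferent weights from a documented
objective.  A one-at-a-time sensitivity search on the calibrated network
brackets the CSN's T conductance to an accepted band of
[0.34, 0.9] nS — above ≈ 0.9 nS the cell starts responding to stimulus
B alone, losing selectivity.

## Stimuli

Stimuli are DC pulses ("simple drivers"): S1 (default 50 ms, 200 pA,
onset t = 100 ms) to the A-selective neuron, S2 to the B pathway with
its onset `delay` ms after S1 offset (so a 150 ms delay puts S2 at
t = 300 ms).  Negative delays express overlap.  Control conditions:
reversed order, either stimulus alone, and same-stimulus repeats.
Pulse windows are half-open [onset, onset+duration); the 100 ms pre-S1
segment is simulated, so event times are directly comparable across
protocols, and runs extend 400 ms past the last pulse.  Protocol
generation is pure and deterministic.

This generator reproduces the *timing structure* of paired sensory
events, not their content: no acoustic or spectral encoding, no trial
noise, no across-trial variability.  Passing tests therefore show that
the circuit mechanism produces order- and interval-selective bursts
under clean, stereotyped drive; they say nothing about robustness to
stochastic input or cell-to-cell heterogeneity.

## Numerics

Integration uses scipy's adaptive RK23 (LSODA available as the
stiff/Adams fallback) with rtol 1e−6, atol 1e−8 — tighter than library
defaults because rebound timing is threshold-sensitive — a 1 ms step
cap, and piecewise integration split at pulse edges so the
discontinuous drive never falls inside a solver step.  Output is
resampled on a uniform grid: 0.01 ms for single-run analyses, 0.05 ms
inside sweeps (spike counts are insensitive to this; the suite checks
counts against 10× tighter tolerances and across both methods).  The
rest state is found by 1000 ms relaxation plus Newton refinement and
must satisfy max|dy/dt| < 1e−6.  The GHK term and τrf evaluate their
removable singularities by series expansion/limit; the compiled
(numba) network kernel is a line-for-line copy of the reference numpy
implementation and the test suite asserts agreement between the two.

Spike detection: upward crossings of −20 mV with a 1 ms dead time;
anchors are insensitive to ±10 mV threshold shifts (guard-tested).
A successful combination is 4–12 spikes spanning ≤ 80 ms, counted over
the whole run.  Windowed current quantification evaluates peak |IH|
over the gap window [S1 offset, S1 offset + delay] and peak |ICaT| over
[S2 onset, S2 onset + 100 ms], each normalized to its maximum across
the delay set.

## Design choices

* The printed membrane equations omit the A-type current, but the gate
  inventory and the 8/7 ODE counts require a dynamic e gate; IA is
  included with a small configurable gA (setting gA = 0 recovers the
  reduced equations).
* S2 drives neuron B, and I_B is recruited through a B→I_B AMPA edge; a
  configuration switch (`drive_IB_directly`) applies the S2 pulse to
  I_B instead.  I_B inhibits I1, I2, I_A2 and I_A3 but not I_A1.
* I1→E2 and I2→E3 are GABA_A: E2 and E3 fire exclusively by
  post-inhibitory rebound at inhibition offset, which is what makes the
  loop a sequence of discrete, delayed events.
* The loop is designed to attenuate: E-cell SK accumulation ends it
  after two rebound cycles (integration window ≈ 220 ms), so the delay
  tuning collapses rather than persisting indefinitely.
* Sweeps are embarrassingly parallel over cells but run sequentially;
  results are independent of execution order, and re-running any cell
  reproduces its count exactly (no randomness anywhere in the core; the
  config `seed` field is recorded but unused).
* Heatmap axes are explicit value lists; shipped grids use the
  documented ranges (gCaT 0.4–0.9, gH 2–20, delays to 230 ms,
  durations 10–200 ms, intensities 10–300 pA) at desk-scale counts.

## Known limitations

* **The 230 ms operating edge.**  The calibrated loop dies at ≈ 320 ms
  absolute, so a 230 ms delay falls just outside the sharp-release
  regime: spike counts there are 0–2 and do not recover the strong
  (gCaT 0.7) or misaligned (gCaT 0.9) outcomes this operating point can
  show when the loop survives slightly longer.  Near the collapse edge
  the outcome is a near-discontinuous function of loop lifetime, and
  lengthening the loop without destroying the ≥ 260 ms collapse proved
  incompatible with the other anchors under this kinetic structure.
* **gH direction.**  Raising CSN gH shallows the integration window
  (−85 mV at 20 nS, as intended) but *reduces* burst size here: with
  the Destexhe τrf form, the fast H gate deactivates slowly near
  −70 mV, so between inhibitory bursts the H current lifts the membrane
  and drains rT priming.  In the calibrated model gH is modulatory and
  slightly suppressive rather than slightly facilitating.
* **Windowed |IH| across delays.**  The gap windows are nested across
  delays ([150, 150+delay]), so the windowed peak |IH| is
  non-decreasing in delay by construction and cannot strictly decline
  at 280 ms; |ICaT| (whose window tracks S2 onset) does decline.
* The maximal burst across long S1 durations saturates at 6 spikes;
  pushing the ceiling higher broke the one-spike-per-0.1 nS gCaT ladder.
* Single "neurons" stand for populations; no synaptic plasticity,
  stochasticity, neuromodulation or dendritic structure.
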