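# Methods

This note documents the model, its assumptions, the parameters that
matter, the numerical choices, what the synthetic inputs and the
surrogate plant do and do not emulate, and the known limitations of
the reduced-scale configuration the tests and the acceptance script
run at.  All parameters live in `src/dbsloop/params.yaml`; values
quoted here are those defaults.

## Network model

Six populations are simulated: cortical layer V pyramidal cells
(multi-compartment), cortical fast-spiking interneurons, STN, GPe,
GPi, and thalamic relay cells (all single-compartment).  Every cell
obeys the compartmental membrane equation

    C_m dv/dt = −Σ_J I_ion − Σ_K I_syn + Σ_M I_app.

**Cell models.**  The basal-ganglia and thalamic cells use
Rubin–Terman-type ionic current sets: leak, Na, delayed-rectifier K,
T-type Ca, high-threshold Ca, and a Ca-gated AHP current with a
first-order calcium balance (the thalamic relay cell drops the AHP
and high-threshold Ca).  The STN parameters were adjusted
(g_T = 1.2 mS/cm², slowed T-inactivation, φ_r = 0.2) so the cell
expresses the plateau-potential/rebound-burst response to release
from hyperpolarization that underlies pathological STN bursting; this
is asserted in the test suite.  The cortical soma is a
Pospischil-type regular-spiking cell (leak, Na, Kd, slow M-type K;
V_T = −56.2 mV, τ_max = 608 ms); the interneuron is the fast-spiking
variant without the slow K current.  The pyramidal axon is a chain of
six compartments — axon initial segment, two main-axon nodes, three
collateral nodes — carrying Na, Kd and a slowly inactivating D-type K
current but no M current (the soma, conversely, has M but no
D-current).  Axonal Na inactivation recovers six-fold slower than
somatic (h_slow_axon = 6), which sets the axon's refractory ceiling
for high-frequency following.

A constant bias current sets each population's intrinsic rate.  At
the defaults, isolated cells fire ~12 Hz (STN), ~75 Hz (GPe), ~70 Hz
(GPi), ~10–30 Hz (cortex, drive-dependent); thalamic relay cells are
quiescent in isolation and respond phasically to release from GPi
inhibition.  These ranges are asserted in `tests/test_neurons.py`.

**Wiring.**  Afferent counts per postsynaptic cell: cortex→STN 5,
GPe→STN 2, striatum→GPe 1, GPe→GPe 1 (no self-connections), STN→GPe
2, STN→GPi 1, GPe→GPi 1, GPi→thalamus 1, thalamus→cortex 1,
interneuron→cortex 10, cortex→interneuron 10.  Partners are drawn
uniformly without replacement per postsynaptic cell.  The striatum is
reduced to independent 3 Hz Poisson trains onto GPe; the indirect
pathway is otherwise out of scope.

**Synapses.**  First-order transmitter-pulse kinetics: a presynaptic
spike opens a 1 ms transmitter pulse during which the gating state R
relaxes toward α/(α+β); otherwise R decays with rate β.  AMPA:
α = 1.1/ms, β = 0.19/ms, E_rev = 0 mV.  GABAa: α = 5/ms, E_rev =
−80 mV, with a *fast* decay (β = 0.18/ms, τ ≈ 5.6 ms) at cortical
synapses and a *slow* decay (β = 0.08–0.12/ms, τ ≈ 8–12.5 ms) at
pallidal projections.  This split is deliberate: the fast cortical
GABAa sets the period of the cortex–interneuron loop that paces the
beta rhythm, while the slow pallidal GABAa summates temporally during
high-frequency GPe firing, producing the net STN inhibition observed
during effective DBS.

The hyperdirect cortex→STN synapse additionally carries short-term
depression (release-resource scheme, u = 0.3, τ_rec = 120 ms).
Differential synaptic depletion is the mechanism by which
high-frequency orthodromic drive fails to excite STN: at 130 Hz the
synapse transmits < 20% per spike, while beta-rate transmission
(~20 Hz) retains ~60%.  Without it, 130 Hz stimulation *excites* STN
through the hyperdirect pathway and no suppression occurs.

**Beta generation.**  The cortical population paces a 13–27 Hz
(wiring-seed dependent; typically ~20 Hz) collective rhythm through
the pyramidal–interneuron loop when the somatic bias is at its burst
value (3.8 µA/cm²); at the baseline value (2.6 µA/cm²) the rhythm is
weak.  The burst schedule alternates bursts and fixed 300 ms
interburst gaps; each burst is healthy (100 ms) with probability 1/2,
otherwise pathological with duration uniform on [600, 1000] ms.
Schedules are half-open ([start, end)) and a burst overrunning the
simulation end is truncated.

## Stimulation and the extracellular field

The electrode is a point current source at the origin of a
homogeneous, isotropic, purely resistive medium (quasi-static
approximation), σ = 0.27 S/m, with two recording contacts at ±1 mm on
the in-plane x axis.  Collaterals run perpendicular to that plane at
(x, y) positions drawn uniformly over a 6 × 6 mm square excluding the
0.7 mm lead radius.  Each cortical cell's compartment chain descends
through the plane (z from 7.5 mm at the soma to −1.5 mm at the
collateral terminal, 1.5 mm node spacing) and every compartment
receives its local point-source potential; the field couples into the
cable through the axial activating-function term
g_axial · (V_e,neighbor − V_e,node).  Applying the field only to
collateral nodes with V_e = 0 elsewhere creates a spurious virtual
anode at the junction and was rejected.

A dimensionless polarization efficacy (`field_scale` = 0.38, which
absorbs effective fiber diameter) sets the activation rheobase just
above 1.1 mA at the closest admissible distance.  Consequently
amplitudes ≤ 1.1 mA activate no collaterals and leave the network at
its DBS-off state, while 2.5–3 mA entrain 10–25% of collaterals 1:1.
This reproduces the model's amplitude threshold literally; the
trade-off is discussed under Limitations.

Activation bookkeeping follows the clinical definitions: a collateral
is *activated* when its firing rate over a trailing 100 ms window
exceeds 60 Hz, and *reliably stimulated* when it answers ≥ 90% of
pulses within 2.5 ms.  The >60 Hz criterion is applied unchanged at
all stimulation frequencies (literal reading).  The activated
fraction drives the GPe surrogate: the first `round(fraction·N)` GPe
neurons of a fixed seeded entrainment order receive one depolarizing
intracellular pulse (60 µA/cm², 0.3 ms) per DBS pulse, entraining
them 1:1 at 130 Hz.

## LFP synthesis and biomarker

All synapses of STN neuron j sit at its (x, y) location, 250 µm off
the electrode plane; the monopolar LFP at each contact is
(1/4πσ) Σ_jk I_syn,jk / r_ij (the same σ as stimulation — the text
does not restate it for recording, and a single tissue conductivity
is the parsimonious choice).  The bipolar trace is contact(+x) −
contact(−x).  Membrane current densities are converted to absolute
currents with a nominal STN somatic area of 3·10⁻⁵ cm²; the LFP is
decimated from the integration grid to 10 kHz by 10-sample averaging.

The beta ARV chain is causal (the controller runs online): 4th-order
Chebyshev type-I band-pass (8 Hz bandwidth, 0.5 dB ripple — type and
ripple are design choices) centered on the DBS-off spectral peak;
full-wave rectification; the final 100 ms of the rectified signal is
discarded (filter edge artifact) and the mean of the preceding 100 ms
is the ARV, i.e. the average over [t−200 ms, t−100 ms].  A 300 ms
rolling buffer per 20 ms controller call is the smallest window
honoring both 100 ms epochs plus settling; the buffer length is
configurable.  The spectral peak search detrends the aperiodic (1/f)
background over 5–45 Hz before peak-picking within 13–30 Hz, so a
sloping background cannot pull the detected center to the band edge.
Targets are the 20th (single threshold) and 10th (dual-threshold
lower bound) percentiles of the DBS-off ARV series, linear
interpolation convention.

## Controllers

All controllers run at T_s = 20 ms, clamp to [u_min, u_max]
(0–3 mA or 0–250 Hz), and start from u(0) = 0 (the safe clinical
default).  The rate limit is R_L = (u_max − u_min)/T_Ramp with
T_Ramp = 250 ms: 0.012 A/s (0.24 mA/call) for amplitude, 1000 Hz/s
(20 Hz/call) for frequency.  On-off and dual-threshold step by
exactly ±0.24 mA per call; the dual-threshold error is computed
against whichever band edge is violated and is zero inside the band.
PI control uses rectangular (Euler) integral accumulation and
conditional integration: the accumulator is frozen whenever the
pre-clamp output lies beyond a bound and the current error drives it
further outward.  The P controller omits the integral term.  The
frequency controller passes a continuous frequency to the waveform
generator; pulse onsets are phase-continuous across parameter updates
and rounded to the integration grid.

The PI tuning rule selects T_i = 0.2 s (between the 100 ms healthy
and 600 ms minimum pathological burst durations) and
K_p = R_L / (max|de/dt| + max(e)/T_i) with the extrema measured on a
30 s DBS-off error recording (finite differences at T_s).  A
controller with the tuned gain cannot exceed the rate limit on the
tuning trace (property-tested).

## Metrics

Power: Z_E⟨I²_DBS⟩ with Z_E = 0.5 kΩ; for rectangular pulse trains
the closed form Z_E A² f w serves as the oracle (24.375 µW at
2.5 mA/130 Hz/60 µs).  Mean error: time-average of max(e, 0)
normalized to the DBS-off value on the same modulation signal.
Suppression efficiency: 100 × mean[(b_off − b_ctrl)/b_off] / power,
in %/µW, so zero suppression gives zero efficiency.  A typeset
variant of this formula that measures the *unsuppressed* fraction
exists (`printed_form=True`) but the prose definition — percentage
beta suppression per unit power — is taken as authoritative.
References (b_off, and the open-loop power/error baselines) are
always computed on the same beta modulation signal as the controller
run, and comparisons are averaged over ten independent signals.

## Surrogate plant

`experiments.SurrogatePlant` is synthetic controller-test machinery,
not part of the biophysical model.  It generates a beta-ARV envelope
that follows the burst schedule (first-order relaxation, τ = 120 ms,
5% multiplicative noise) and responds to stimulation through a
saturating dose–response mirroring the network's open-loop
characterization: no effect below 1.1 mA or 20 Hz, saturating by
~1.5 mA and ~60 Hz, maximum suppression 92%.  The suppression state
carries an asymmetric lag — slow onset (200 ms, the synaptic
depletion time scale) and fast decay (50 ms; network beta re-emerges
quickly once stimulation stops) — which penalizes bang-bang
stimulation relative to a steady hold, as the full network does.
What passing surrogate-based tests shows is that the *controllers*
behave correctly against a plant with the right qualitative
input–output shape; it says nothing further about the biophysics,
which is why the open-loop characterization tests run on the full
network.

## Numerical choices

Fixed-step integration at dt = 0.01 ms: Crank–Nicolson for the
voltage equation (a scalar linear solve per single-compartment cell;
a per-neuron tridiagonal Thomas solve for the 7-compartment cortical
cell) with conductances frozen at the step start, and exact
exponential (Rush–Larsen) gating updates.  Halving dt changes a
100 ms subthreshold trajectory by < 0.5 mV RMS (tested).  Spikes are
upward 0 mV crossings with a 1 ms lockout.  Synaptic delays are
per-projection constants (cortex→STN 5.9 ms, GPe→STN 4 ms, others
1–8 ms) implemented as spike-history ring buffers.  Membrane state is
guarded (|v| < 200 mV, finite); violation raises a divergence error
naming the population.  Simulations advance in 20 ms compiled chunks
(one controller interval); a full dynamic-state snapshot (voltages,
gating, synaptic kinetics and depression resources, delay histories)
supports exact save/restore, which is bit-tested.

## Reduced scale and limitations

The reference configuration is 100 neurons per population.  Tests and
the acceptance script run at 40 per population with 4–6 s evaluation
windows after a 1 s settling period (a 6 s warm-up is the reference
protocol at full scale), which keeps the whole suite within a few
minutes on one CPU.  Wiring counts, weights and all structural rules
are scale-invariant, but three behaviors are known to differ from the
full-scale model:

* **STN suppression during high-frequency DBS is partial (~30–50%
  rate reduction at ≥100 Hz, monotone in frequency), not complete.**
  The point-source geometry makes the collateral threshold–distance
  curve steep, so the activated fraction at 2.5–3 mA (10–25%) — and
  with it the GPe surrogate fraction — is smaller than at full scale.
* **The DBS-off beta peak frequency varies with the wiring seed
  (13–27 Hz)** rather than sitting at a fixed ~25 Hz; small networks
  leave the collective loop period sensitive to the particular random
  graph.
* **Finite-size sensitivity:** with tens of neurons, a single
  antidromically activated cortical cell reaches a large fraction of
  the interneuron population, so beta disruption switches on sharply
  once any collateral entrains.  The activation rheobase placed just
  above 1.1 mA makes the amplitude threshold behavior robust despite
  this.

Also out of scope by design: dendritic morphology for basal-ganglia
cells, stochastic channel noise, encapsulation tissue and
capacitive/dispersive electrode properties, three-dimensional synapse
clouds and non-STN LFP contributions, tremor biomarkers, and
long-lasting post-stimulation beta attenuation (beta re-emerges
immediately when stimulation stops in this model).
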