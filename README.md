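# dbsloop

An *in silico* testbed for closed-loop deep brain stimulation (DBS) of
the subthalamic nucleus (STN) in Parkinson's disease.  The package
simulates a spiking cortico-basal-ganglia network together with the
three signals a closed-loop neurostimulator actually sees and drives:
the extracellular stimulation field, the local field potential (LFP)
recorded at non-stimulating electrode contacts, and the beta-band
biomarker derived from it.  On top of this plant it implements the
clinically motivated feedback controllers — on-off, dual-threshold,
proportional (P), and proportional-integral (PI) — for modulating
either the DBS pulse amplitude or frequency, including the clinical
rate-limit constraint and a rule for tuning the PI gains.

It is intended for researchers designing closed-loop DBS control
algorithms who want to iterate on controller structure and parameters
against a physiologically grounded plant before preclinical testing.

## Model

* **Network.**  Six populations (cortical layer V pyramidal cells,
  cortical interneurons, STN, GPe, GPi, thalamus) of conductance-based
  neurons obeying `C_m dv/dt = −ΣI_ion − ΣI_syn + ΣI_app`, randomly
  wired with fixed afferent counts (each STN cell receives 5 cortical
  and 2 GPe inputs, etc.).  Synapses are AMPA/GABAa with first-order
  transmitter-pulse kinetics, `I_syn = R (V_m − E_rev)`; striatal
  input is reduced to 3 Hz Poisson trains onto GPe.  Exaggerated
  beta-band activity is induced by strengthened cortex→STN, STN↔GPe
  and thalamus→cortex coupling, and beta *bursts* are imposed by
  modulating the cortical soma bias current between short (100 ms,
  "healthy") and long (600–1000 ms, "pathological") episodes separated
  by 300 ms.
* **Stimulation.**  A point-source electrode in a homogeneous medium
  (`V_e = I_DBS / 4πσr`, σ = 0.27 S/m) drives multi-compartment
  cortical axon collaterals distributed in a 6 × 6 mm plane around the
  lead; cathodic rectangular pulses (0–3 mA, 0–250 Hz, 60 µs)
  activate collaterals antidromically (toward cortex) and
  orthodromically (toward STN).  GPe neurons are co-stimulated with an
  intracellular surrogate current in proportion to the fraction of
  activated collaterals (rate > 60 Hz).
* **LFP and biomarker.**  The STN LFP at a bipolar contact pair is
  the distance-weighted sum of all STN synaptic currents,
  `LFP_i = (1/4πσ) Σ_j Σ_k I_syn,jk / r_ij`.  The controller input is
  the average rectified value (ARV) of the beta-filtered LFP
  (4th-order Chebyshev band-pass, 8 Hz wide, centered on the DBS-off
  spectral peak), normalized as `e = (b_measured − b_target)/b_target`
  against the 20th percentile of a DBS-off epoch.
* **Control.**  Controllers update every `T_s` = 20 ms subject to the
  clinical rate limit `R_L = (u_max − u_min)/T_Ramp` with
  `T_Ramp` = 250 ms (0.012 A/s for amplitude, 1000 Hz/s for
  frequency).  PI control uses conditional integration (anti-windup)
  and the tuning rule `K_p ≤ R_L / (max|de/dt| + max(e)/T_i)` with
  `T_i` between the healthy and pathological burst durations.
* **Metrics.**  Mean half-wave-rectified error (vs. DBS-off), power
  `Z_E ⟨I²_DBS⟩` with `Z_E` = 0.5 kΩ (vs. open-loop 2.5 mA/130 Hz/
  60 µs = 24.375 µW), and suppression efficiency in %/µW.

## Worked example

Tune a PI amplitude controller against a 30 s DBS-off reference epoch
of the surrogate beta plant and run the closed loop:

```python
import numpy as np
from dbsloop import control, metrics
from dbsloop.experiments import surrogate_reference, run_surrogate_closed_loop

plant, b_target, b_lower, arv_off = surrogate_reference(30.0, seed=1)
e_off = (arv_off - b_target) / b_target

spec = control.rate_limit(3.0)            # 0-3 mA amplitude range
tuned = control.tune_pi(e_off, spec)      # K_p = 0.360, T_i = 0.2 s
ctl = control.PIController(spec, kp=tuned.kp, ti=tuned.ti)
res = run_surrogate_closed_loop(plant, ctl, b_target, 30.0)

print(metrics.mean_rectified_error(res["e"], e_off))           # 15.0 %
print(metrics.suppression_efficiency(arv_off, res["arv"],
                                     float(np.mean(res["power_uw"]))))  # 5.35 %/uW
```

The tuned gain (`K_p = 0.360` mA here) is the largest proportional
gain that cannot violate the 0.012 A/s amplitude rate limit on the
reference epoch; the closed loop then holds the beta ARV near target
with a mean rectified error of ≈ 15% of the DBS-off value
and a suppression efficiency of ≈ 5.4 %/µW.  The same
protocol from the shell:

```bash
dbsloop tune --duration 30 --seed 1
# K_p = 0.3601, T_i = 0.2 s (max e 1.59, max |de/dt| 25.4 1/s)
```

Full-network runs go through `dbsloop.experiments.ScenarioConfig` and
`run_dbs_off` / `run_open_loop` / `run_closed_loop`, or the
`dbsloop simulate` / `sweep` / `pisweep` commands, which write HDF5
trace containers (see `dbsloop.io`).

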