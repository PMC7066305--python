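# Versioned model parameters.  Units: mV, ms, mS/cm2, uA/cm2, uF/cm2,
# mm, mA, Hz unless stated.  One section per population plus synapse,
# stimulation and schedule blocks.  These values are frozen; scenario
# configs may override them explicitly.

neurons:
  stn:
    # Rubin-Terman-lineage subthalamic cell: leak, Na, K, T-type Ca,
    # high-threshold Ca, Ca-activated K (AHP) with calcium balance.
    g_leak: 2.25
    e_leak: -60.0
    g_na: 37.5
    e_na: 55.0
    g_k: 45.0
    e_k: -80.0
    g_t: 1.2
    g_ca: 0.5
    e_ca: 140.0
    g_ahp: 9.0
    k1: 15.0
    eps: 5.0e-5
    k_ca: 22.5
    phi_h: 0.75
    phi_n: 0.75
    phi_r: 0.2
    cm: 1.0
    bias: 10.0           # sets the tonic rate
  gpe:
    g_leak: 0.1
    e_leak: -65.0
    g_na: 120.0
    e_na: 55.0
    g_k: 30.0
    e_k: -80.0
    g_t: 0.5
    g_ca: 0.15
    e_ca: 120.0
    g_ahp: 30.0
    k1: 30.0
    eps: 1.0e-4
    k_ca: 15.0
    phi_h: 0.05
    phi_n: 0.1
    phi_r: 1.0
    cm: 1.0
    bias: 5.0
  gpi:
    g_leak: 0.1
    e_leak: -65.0
    g_na: 120.0
    e_na: 55.0
    g_k: 30.0
    e_k: -80.0
    g_t: 0.5
    g_ca: 0.15
    e_ca: 120.0
    g_ahp: 30.0
    k1: 30.0
    eps: 1.0e-4
    k_ca: 15.0
    phi_h: 0.05
    phi_n: 0.1
    phi_r: 1.0
    cm: 1.0
    bias: 6.0
  tha:
    g_leak: 0.05
    e_leak: -70.0
    g_na: 3.0
    e_na: 50.0
    g_k: 5.0
    e_k: -90.0
    g_t: 5.0
    e_ca: 90.0
    cm: 1.0
    bias: 0.3
  intn:
    # fast-spiking interneuron (Pospischil lineage, no slow K)
    g_leak: 0.038
    e_leak: -70.4
    g_na: 58.0
    e_na: 50.0
    g_k: 3.9
    e_k: -90.0
    v_t: -57.9
    cm: 1.0
    bias: 0.55
  ctx:
    # regular-spiking layer V soma (Pospischil) + axonal chain:
    # soma, AIS, two main-axon nodes, three collateral nodes.
    g_leak_soma: 0.0205
    e_leak: -70.3
    g_na_soma: 56.0
    e_na: 50.0
    g_k_soma: 6.0
    e_k: -90.0
    g_m: 0.10
    tau_max: 608.0
    v_t: -56.2
    g_leak_axon: 0.05
    g_na_axon: 150.0
    g_k_axon: 60.0
    g_d: 1.0
    cm: 1.0
    h_slow_axon: 6.0
    n_compartments: 7
    # coupling conductance per interface (soma-AIS, AIS-ax1, ax1-ax2,
    # ax2-col1, col1-col2, col2-col3), scaled per compartment by the
    # inverse relative areas below
    g_axial: [0.15, 3.0, 3.0, 2.0, 2.0, 2.0]
    # relative membrane area per compartment (soma, AIS, ax1, ax2,
    # col1, col2, col3): coupling currents scale with 1/area
    area_rel: [1.0, 0.1, 0.1, 0.1, 0.12, 0.12, 0.12]
    bias_baseline: 2.6    # soma drive outside beta bursts
    bias_burst: 3.8       # soma drive during beta bursts
    bias_jitter: 0.1      # per-neuron heterogeneity (s.d.)

synapses:
  # transmitter-pulse kinetics per receptor
  kinetics:
    ampa: {alpha: 1.1, beta: 0.19, e_rev: 0.0}
    gabaa: {alpha: 5.0, beta: 0.18, e_rev: -80.0}
  transmitter_ms: 1.0
  # per-projection maximal conductance (mS/cm2), delay (ms) and
  # optional kinetic overrides (beta: decay rate 1/ms).  Cortical
  # GABAa is fast (sets the beta-band loop period); pallidal GABAa is
  # slow, so it summates temporally during high-frequency stimulation
  # (the substrate of STN suppression).  cortex->STN, STN<->GPe and
  # thalamus->cortex carry the increased dopamine-depleted coupling
  # that induces the network beta rhythm.
  projections:
    ctx_stn:   {weight: 1.0, delay: 5.9, u_dep: 0.3, tau_rec: 120.0}
    gpe_stn:   {weight: 0.80, delay: 4.0, beta: 0.12}
    str_gpe:   {weight: 0.30, delay: 5.0, beta: 0.08}
    gpe_gpe:   {weight: 0.05, delay: 1.0, beta: 0.08}
    stn_gpe:   {weight: 0.35, delay: 2.0}
    stn_gpi:   {weight: 0.20, delay: 1.5}
    gpe_gpi:   {weight: 0.25, delay: 3.0, beta: 0.08}
    gpi_tha:   {weight: 0.15, delay: 5.0, beta: 0.08}
    tha_ctx:   {weight: 0.12, delay: 8.0}
    intn_ctx:  {weight: 0.14, delay: 1.0}
    ctx_intn:  {weight: 0.07, delay: 1.0}

stimulation:
  sigma_s_per_m: 0.27
  lead_radius_mm: 0.7
  square_half_width_mm: 3.0
  contact_offset_mm: 1.0
  pulse_width_us: 60.0
  amplitude_bounds_ma: [0.0, 3.0]
  frequency_bounds_hz: [0.0, 250.0]
  collateral_node_spacing_mm: 1.5   # node z-positions -L, 0, +L
  # polarization efficacy of the field on axonal nodes (dimensionless;
  # absorbs fiber diameter): sets the ~1.1 mA activation rheobase
  field_scale: 0.38
  activation_rate_hz: 60.0
  reliable_fraction: 0.9
  activation_window_ms: 100.0
  # intracellular GPe surrogate pulse (one per DBS pulse)
  gpe_pulse_amp: 60.0      # uA/cm2
  gpe_pulse_width_ms: 0.3

lfp:
  z_offset_mm: 0.25
  stn_area_cm2: 3.0e-5     # converts membrane current density to nA
  sample_rate_hz: 10000.0

biomarker:
  bandwidth_hz: 8.0
  ripple_db: 0.5
  window_ms: 300.0
  hop_ms: 20.0

schedule:
  healthy_ms: 100.0
  pathological_ms: [600.0, 1000.0]
  interburst_ms: 300.0
  p_healthy: 0.5

simulation:
  dt_ms: 0.01
  warmup_s: 6.0
  controller_ts_ms: 20.0
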