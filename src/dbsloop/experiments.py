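"""Experiment orchestration.

Drives the integrated network model (or a fast surrogate plant)
through the study protocols: DBS-off reference runs, open-loop
stimulation, closed-loop control at a 20 ms sampling interval,
amplitude × frequency parameter sweeps, and the PI gain sweep.

The closed-loop chain per controller call mirrors the hardware loop:
bipolar LFP window → beta-band ARV → normalized error → controller
update → new DBS waveform parameters → extracellular field (and the
matched intracellular GPe surrogate, scaled by the fraction of
activated cortical collaterals over the trailing window).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import biomarker, control, metrics
from .model import CBGNetwork, ModelConfig
from .network import BetaModulationSignal, generate_beta_modulation

__all__ = [
    "ScenarioConfig",
    "SurrogatePlant",
    "NetworkRun",
    "run_dbs_off",
    "run_open_loop",
    "run_closed_loop",
    "run_parameter_sweep",
    "run_pi_gain_sweep",
    "run_surrogate_closed_loop",
    "surrogate_reference",
]

LFP_FS = 10_000.0  # Hz, decimated LFP rate
TS_MS = 20.0  # controller sampling interval
ARV_WINDOW_MS = 300.0


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``warmup_s`` precedes the evaluation window; metrics are computed
    on the evaluation window only.  All seeds are explicit.
    """

    n_per_pop: int = 20
    warmup_s: float = 1.0
    duration_s: float = 10.0
    dt_ms: float = 0.01
    mode: str = "amplitude"  # or "frequency"
    amplitude_ma: float = 0.0
    frequency_hz: float = 130.0
    pulse_width_us: float = 60.0
    seed: int = 1
    constant_beta: bool = False  # hold the cortical drive at burst level

    @property
    def total_s(self) -> float:
        return self.warmup_s + self.duration_s

    def model_config(self) -> ModelConfig:
        s = int(self.seed) % (2**31 - 1)
        return ModelConfig(
            n_per_pop=self.n_per_pop,
            dt_ms=self.dt_ms,
            beta_modulation=not self.constant_beta,
            duration_s=self.total_s,
            wiring_seed=s * 7 + 1,
            placement_seed=s * 7 + 2,
            modulation_seed=s * 7 + 3,
            striatal_seed=s * 7 + 4,
            init_seed=s * 7 + 5,
            entrainment_seed=s * 7 + 6,
        )


@dataclass
class NetworkRun:
    """Traces of one network simulation (evaluation window only)."""

    lfp: np.ndarray  # bipolar LFP at LFP_FS
    i_dbs: np.ndarray  # stimulation current (mA) at the integration step
    t_ctrl_ms: np.ndarray  # controller call times
    arv: np.ndarray  # beta ARV per controller call
    e: np.ndarray  # controller error per call (nan if no controller)
    u: np.ndarray  # modulated parameter per call
    fraction_activated: np.ndarray  # collateral activation fraction per call
    spikes: dict  # population -> (n_calls*chunk, n) uint8 rasters, concatenated
    dt_ms: float
    center_hz: float | None = None
    b_target: float | None = None


class _PulseClock:
    """Phase-continuous cathodic pulse-train generator."""

    def __init__(self, dt_ms: float, width_us: float):
        self.dt = dt_ms
        self.width_ms = width_us * 1e-3
        self.next_onset = 0.0

    def interval(self, t0: float, n_steps: int, amplitude_ma: float,
                 frequency_hz: float) -> np.ndarray:
        out = np.zeros(n_steps)
        if frequency_hz <= 0 or amplitude_ma <= 0:
            # keep the clock moving so a later frequency resumes cleanly
            self.next_onset = max(self.next_onset, t0 + n_steps * self.dt)
            return out
        period = 1e3 / frequency_hz
        if self.next_onset < t0:
            self.next_onset = t0
        t_end = t0 + n_steps * self.dt
        onset = self.next_onset
        w_steps = max(1, int(round(self.width_ms / self.dt)))
        while onset < t_end:
            k0 = int(round((onset - t0) / self.dt))
            if k0 >= n_steps:
                break  # rounding placed it in the next chunk; keep it there
            out[max(k0, 0) : k0 + w_steps] = -amplitude_ma
            onset += period
        self.next_onset = onset
        return out


def _gpe_pulse_trace(i_dbs: np.ndarray, amp: float, width_ms: float,
                     dt_ms: float) -> np.ndarray:
    """Depolarizing intracellular pulse per DBS pulse onset."""
    out = np.zeros_like(i_dbs)
    stim = i_dbs < 0
    prev = np.roll(stim, 1)
    prev[0] = False
    onsets = np.flatnonzero(stim & ~prev)
    w = max(1, int(round(width_ms / dt_ms)))
    for o in onsets:
        out[o : o + w] = amp
    return out


class _NetworkSession:
    """Shared machinery for open- and closed-loop network runs."""

    def __init__(self, cfg: ScenarioConfig):
        self.cfg = cfg
        self.net = CBGNetwork(cfg.model_config())
        p = self.net.p
        if cfg.constant_beta:
            ctx = self.net.pops["ctx"]
            ctx.bias = ctx.bias - np.mean(ctx.bias) + ctx.bias_burst
        self.dt = cfg.dt_ms
        self.chunk = int(round(TS_MS / self.dt))
        self.decim = int(round(1e3 / self.dt / LFP_FS))
        self.clock = _PulseClock(self.dt, cfg.pulse_width_us)
        self.gpe_amp = float(p["stimulation"]["gpe_pulse_amp"])
        self.gpe_width = float(p["stimulation"]["gpe_pulse_width_ms"])
        self.act_window_ms = float(p["stimulation"]["activation_window_ms"])
        self.act_rate = float(p["stimulation"]["activation_rate_hz"])
        n_act = int(round(self.act_window_ms / self.dt))
        self._col_hist = np.zeros((0, self.net.n), dtype=np.uint8)
        self._n_act = n_act

    def advance(self, amplitude_ma: float, frequency_hz: float) -> dict:
        t0 = self.net.step_count * self.dt
        i_dbs = self.clock.interval(t0, self.chunk, amplitude_ma, frequency_hz)
        gpe = _gpe_pulse_trace(i_dbs, self.gpe_amp, self.gpe_width, self.dt)
        out = self.net.run_interval(i_dbs, gpe)
        # trailing-window collateral activation -> GPe surrogate fraction
        self._col_hist = np.concatenate([self._col_hist, out["ctx_col"]])[-self._n_act:]
        rates = self._col_hist.sum(axis=0) / (self.act_window_ms * 1e-3)
        frac = float(np.mean(rates > self.act_rate))
        self.net.set_gpe_fraction(frac)
        out["i_dbs"] = i_dbs
        out["fraction_activated"] = frac
        out["lfp_dec"] = out["lfp_bipolar"].reshape(-1, self.decim).mean(axis=1)
        return out


def _collect(session: _NetworkSession, n_calls: int, controller=None,
             mode: str = "amplitude", fixed: tuple[float, float] = (0.0, 130.0),
             spec: biomarker.BetaFilterSpec | None = None,
             b_target: float | None = None,
             warmup_calls: int = 0) -> NetworkRun:
    cfg = session.cfg
    n_buf = int(round(ARV_WINDOW_MS * 1e-3 * LFP_FS))
    buf = np.zeros(0)
    lfp_all, idbs_all = [], []
    arv_l, e_l, u_l, frac_l, t_l = [], [], [], [], []
    rasters: dict[str, list] = {k: [] for k in
                                ["ctx_soma", "ctx_col", "stn", "gpe", "gpi", "tha",
                                 "intn"]}
    amp, freq = fixed
    u = None if controller is None else controller.u
    for call in range(warmup_calls + n_calls):
        if controller is not None:
            if mode == "amplitude":
                amp = u if u is not None else 0.0
            else:
                freq = u if u is not None else 0.0
        out = session.advance(amp, freq)
        eval_phase = call >= warmup_calls
        if eval_phase:
            lfp_all.append(out["lfp_dec"])
            idbs_all.append(out["i_dbs"])
            for k in rasters:
                rasters[k].append(out[k])
        buf = np.concatenate([buf, out["lfp_dec"]])[-n_buf:]
        if controller is not None and buf.size >= n_buf:
            arv = biomarker.beta_arv(buf, spec)
            if isinstance(controller, control.DualThresholdController):
                e = controller.band_error(arv)
                u = controller.update(arv)
            else:
                e = control.controller_error(arv, b_target)
                u = controller.update(e)
            if eval_phase:
                arv_l.append(arv)
                e_l.append(e)
                u_l.append(u)
                frac_l.append(out["fraction_activated"])
                t_l.append(session.net.step_count * session.dt)
        elif eval_phase and spec is not None and buf.size >= n_buf:
            arv_l.append(biomarker.beta_arv(buf, spec))
            e_l.append(np.nan)
            u_l.append(amp if mode == "amplitude" else freq)
            frac_l.append(out["fraction_activated"])
            t_l.append(session.net.step_count * session.dt)
    return NetworkRun(
        lfp=np.concatenate(lfp_all),
        i_dbs=np.concatenate(idbs_all),
        t_ctrl_ms=np.asarray(t_l),
        arv=np.asarray(arv_l),
        e=np.asarray(e_l),
        u=np.asarray(u_l),
        fraction_activated=np.asarray(frac_l),
        spikes={k: np.concatenate(v) for k, v in rasters.items()},
        dt_ms=session.dt,
        center_hz=None if spec is None else spec.center_hz,
        b_target=b_target,
    )


def run_dbs_off(cfg: ScenarioConfig) -> NetworkRun:
    """DBS-off run; afterwards the biomarker chain can be calibrated
    (spectral peak, filter center, percentile targets) from its LFP."""
    session = _NetworkSession(cfg)
    warmup_calls = int(round(cfg.warmup_s * 1e3 / TS_MS))
    n_calls = int(round(cfg.duration_s * 1e3 / TS_MS))
    return _collect(session, n_calls, fixed=(0.0, cfg.frequency_hz),
                    warmup_calls=warmup_calls)


def calibrate_biomarker(run: NetworkRun) -> tuple[biomarker.BetaFilterSpec, float, float]:
    """Filter center from the DBS-off spectral peak plus ARV targets."""
    center = biomarker.spectral_peak(run.lfp, LFP_FS)
    spec = biomarker.BetaFilterSpec(center_hz=center, fs_hz=LFP_FS)
    _, arv = biomarker.arv_series(run.lfp, spec, hop_ms=TS_MS)
    b_target, b_lower = biomarker.estimate_targets(arv)
    return spec, b_target, b_lower


def run_open_loop(cfg: ScenarioConfig, spec: biomarker.BetaFilterSpec | None = None
                  ) -> NetworkRun:
    """Constant-parameter stimulation (cfg.amplitude_ma, cfg.frequency_hz)."""
    session = _NetworkSession(cfg)
    warmup_calls = int(round(cfg.warmup_s * 1e3 / TS_MS))
    n_calls = int(round(cfg.duration_s * 1e3 / TS_MS))
    return _collect(session, n_calls, fixed=(cfg.amplitude_ma, cfg.frequency_hz),
                    spec=spec, warmup_calls=warmup_calls)


def run_closed_loop(
    cfg: ScenarioConfig,
    controller,
    spec: biomarker.BetaFilterSpec,
    b_target: float,
) -> NetworkRun:
    """Closed-loop run of one controller on the full network."""
    session = _NetworkSession(cfg)
    warmup_calls = int(round(cfg.warmup_s * 1e3 / TS_MS))
    n_calls = int(round(cfg.duration_s * 1e3 / TS_MS))
    if cfg.mode == "frequency":
        fixed = (cfg.amplitude_ma if cfg.amplitude_ma > 0 else 1.5, 0.0)
    else:
        fixed = (0.0, cfg.frequency_hz)
    return _collect(session, n_calls, controller=controller, mode=cfg.mode,
                    fixed=fixed, spec=spec, b_target=b_target,
                    warmup_calls=warmup_calls)


def run_parameter_sweep(
    amplitudes_ma: np.ndarray,
    frequencies_hz: np.ndarray,
    cfg: ScenarioConfig,
    spec: biomarker.BetaFilterSpec | None = None,
    beta_band: tuple[float, float] = (22.0, 30.0),
) -> np.ndarray:
    """Normalized LFP beta power on an amplitude × frequency grid.

    Each grid point is an independent open-loop run of
    ``cfg.duration_s``; powers are normalized by the (0 mA) DBS-off
    value, so zero stimulation maps to 1 by construction.
    """
    off = run_dbs_off(cfg)
    p_off = biomarker.band_power(off.lfp, LFP_FS, beta_band)
    out = np.empty((len(amplitudes_ma), len(frequencies_hz)))
    for i, a in enumerate(amplitudes_ma):
        for j, f in enumerate(frequencies_hz):
            if a <= 0 or f <= 0:
                out[i, j] = 1.0
                continue
            c = replace(cfg, amplitude_ma=float(a), frequency_hz=float(f))
            run = run_open_loop(c)
            out[i, j] = biomarker.band_power(run.lfp, LFP_FS, beta_band) / p_off
    return out


# ---------------------------------------------------------------------------
# surrogate plant: fast beta-ARV dynamics for controller-only studies
# ---------------------------------------------------------------------------


@dataclass
class SurrogatePlant:
    """Synthetic beta-ARV generator (explicitly not the network model).

    The DBS-off ARV envelope follows the burst schedule (high during
    bursts, low between, first-order relaxation) with multiplicative
    noise.  Stimulation scales the envelope by a saturating monotone
    dose response: no effect below an amplitude threshold (~1.1 mA) or
    frequency threshold (~40 Hz), saturating suppression beyond —
    mimicking the open-loop characterization of the full model.  Used
    for controller unit tests and fast sweeps only.
    """

    modulation: BetaModulationSignal
    ts_ms: float = TS_MS
    arv_low: float = 1.0
    arv_high: float = 3.5
    tau_ms: float = 120.0
    tau_dbs_on_ms: float = 200.0
    tau_dbs_off_ms: float = 50.0
    noise_sd: float = 0.05
    amp_threshold_ma: float = 1.1
    amp_sat_ma: float = 1.5
    freq_threshold_hz: float = 20.0
    freq_sat_hz: float = 60.0
    max_suppression: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self._x = self.arv_low
        self._s = 0.0  # lagged suppression state
        self._t = 0.0

    def dose_multiplier(self, amplitude_ma: float, frequency_hz: float) -> float:
        """Steady-state ARV multiplier in (0, 1].

        1 at zero stimulation; monotone non-increasing in each
        parameter beyond its threshold.  The amplitude factor has a
        sharp knee just above 1.1 mA (no effect below, saturating by
        ~1.5 mA) and the frequency factor saturates above ~60 Hz,
        echoing the open-loop amplitude x frequency characterization.
        """
        a = np.clip(
            (amplitude_ma - self.amp_threshold_ma)
            / (self.amp_sat_ma - self.amp_threshold_ma),
            0.0, 1.0,
        )
        f = np.clip(
            (frequency_hz - self.freq_threshold_hz)
            / (self.freq_sat_hz - self.freq_threshold_hz),
            0.0, 1.0,
        )
        return float(1.0 - self.max_suppression * a * f)

    def step(self, amplitude_ma: float, frequency_hz: float) -> float:
        """Advance one controller interval; returns the measured ARV.

        The suppression state relaxes toward its dose-determined
        value asymmetrically — slowly while building
        (``tau_dbs_on_ms``, the synaptic-depletion time scale) and
        quickly while decaying (``tau_dbs_off_ms``; network beta
        re-emerges fast once stimulation stops or becomes
        ineffective).  Intermittent bang-bang stimulation is therefore
        penalized relative to a steady hold, as in the full model.
        """
        target = (
            self.arv_high
            if bool(self.modulation.is_burst(self._t)[0])
            else self.arv_low
        )
        lam = 1.0 - np.exp(-self.ts_ms / self.tau_ms)
        self._x += lam * (target - self._x)
        s_target = 1.0 - self.dose_multiplier(amplitude_ma, frequency_hz)
        tau_s = self.tau_dbs_on_ms if s_target > self._s else self.tau_dbs_off_ms
        lam_s = 1.0 - np.exp(-self.ts_ms / tau_s)
        self._s += lam_s * (s_target - self._s)
        self._t += self.ts_ms
        noise = 1.0 + self.noise_sd * self._rng.standard_normal()
        return max(self._x * (1.0 - self._s) * max(noise, 0.0), 0.0)


def surrogate_reference(duration_s: float, seed: int) -> tuple[SurrogatePlant, float, float, np.ndarray]:
    """DBS-off surrogate epoch: plant, targets and the error trace."""
    mod = generate_beta_modulation(duration_s, seed)
    plant = SurrogatePlant(modulation=mod, seed=seed + 10_000)
    arv_off = np.array([plant.step(0.0, 0.0)
                        for _ in range(int(duration_s * 1e3 / TS_MS))])
    b_target, b_lower = biomarker.estimate_targets(arv_off)
    plant.reset()
    return plant, b_target, b_lower, arv_off


def run_surrogate_closed_loop(
    plant: SurrogatePlant,
    controller,
    b_target: float,
    duration_s: float,
    mode: str = "amplitude",
    fixed_amplitude_ma: float = 1.5,
    fixed_frequency_hz: float = 130.0,
    pulse_width_us: float = 60.0,
) -> dict:
    """Closed-loop run on the surrogate plant; returns call-grid traces."""
    plant.reset()
    n_calls = int(round(duration_s * 1e3 / TS_MS))
    amp = 0.0 if mode == "amplitude" else fixed_amplitude_ma
    freq = fixed_frequency_hz if mode == "amplitude" else 0.0
    arv_l, e_l, u_l, p_l = [], [], [], []
    for _ in range(n_calls):
        arv = plant.step(amp, freq)
        if isinstance(controller, control.DualThresholdController):
            e = controller.band_error(arv)
            u = controller.update(arv)
        else:
            e = control.controller_error(arv, b_target)
            u = controller.update(e)
        if mode == "amplitude":
            amp = u
        else:
            freq = u
        arv_l.append(arv)
        e_l.append(e)
        u_l.append(u)
        p_l.append(metrics.power_consumed_rectangular(amp, freq, pulse_width_us))
    return {
        "arv": np.asarray(arv_l),
        "e": np.asarray(e_l),
        "u": np.asarray(u_l),
        "power_uw": np.asarray(p_l),
    }


def run_pi_gain_sweep(
    kp_grid: np.ndarray,
    ti_grid: np.ndarray,
    duration_s: float,
    seed: int,
    bounds: tuple[float, float] = (0.0, 3.0),
    mode: str = "amplitude",
) -> dict:
    """PI parameter sweep on the surrogate plant.

    Returns normalized mean-error and power surfaces with shape
    (len(kp_grid), len(ti_grid)).
    """
    plant, b_target, _, arv_off = surrogate_reference(duration_s, seed)
    e_off = (arv_off - b_target) / b_target
    err = np.empty((len(kp_grid), len(ti_grid)))
    pwr = np.empty_like(err)
    spec = control.rate_limit(bounds[1], bounds[0])
    for i, kp in enumerate(kp_grid):
        for j, ti in enumerate(ti_grid):
            ctl = control.PIController(spec, kp=float(kp), ti=float(ti))
            res = run_surrogate_closed_loop(plant, ctl, b_target, duration_s,
                                            mode=mode)
            err[i, j] = metrics.mean_rectified_error(res["e"], e_off)
            pwr[i, j] = float(np.mean(res["power_uw"]))
    return {"error_pct": err, "power_uw": pwr, "kp": np.asarray(kp_grid),
            "ti": np.asarray(ti_grid)}


def antidromic_spike_rate(
    run: NetworkRun,
    frequency_hz: float,
    duration_s: float,
    response_ms: float = 2.5,
) -> tuple[float, int]:
    """Antidromic cortical spike rate during open-loop stimulation.

    A cortical neuron counts as *reliably stimulated* when its
    collateral answers at least 90% of DBS pulses within
    ``response_ms``; the antidromic rate is the mean rate of
    stimulation-evoked somatic spikes over the reliable subset.
    Returns (rate_hz, n_reliable).
    """
    from .stimulation import RELIABLE_FRACTION, pulse_onsets

    soma = run.spikes["ctx_soma"]
    col = run.spikes["ctx_col"]
    n_steps, n = soma.shape
    onsets = pulse_onsets(frequency_hz, 0.0, n_steps * run.dt_ms)
    if onsets.size == 0:
        return 0.0, 0
    o_idx = (onsets / run.dt_ms).astype(np.int64)
    w = int(round(response_ms / run.dt_ms))
    evoked = np.zeros(n)
    follow = np.zeros(n)
    for i in range(n):
        s = np.flatnonzero(soma[:, i])
        c = np.flatnonzero(col[:, i])
        if c.size == 0:
            continue
        hits_c = hits_s = 0
        for o in o_idx:
            if np.any((c > o) & (c <= o + w)):
                hits_c += 1
            if s.size and np.any((s > o) & (s <= o + w)):
                hits_s += 1
        follow[i] = hits_c / len(o_idx)
        evoked[i] = hits_s / duration_s
    reliable = follow >= RELIABLE_FRACTION
    if not reliable.any():
        return 0.0, 0
    return float(evoked[reliable].mean()), int(reliable.sum())
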