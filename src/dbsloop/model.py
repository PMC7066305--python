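"""Integrated cortico-basal-ganglia network model.

Composes the neuron populations, synaptic wiring, extracellular DBS
field, GPe surrogate stimulation and STN-LFP synthesis into a single
steppable model.  The heavy inner loop is compiled (``_kernels.run_chunk``)
and advances the network in chunks — typically one controller sampling
interval (20 ms) — with fixed DBS parameters per chunk, which is
exactly the closed-loop timing of the experiments.

All randomness (wiring, collateral and STN placement, burst schedule,
striatal Poisson trains, initial conditions, GPe entrainment order) is
derived from explicit seeds, so identical configurations reproduce
bit-identical trajectories.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import _kernels, neurons
from .lfp import SynapseGeometry
from .network import (
    ConnectivitySpec,
    build_network,
    generate_beta_modulation,
    striatal_drive,
)
from .stimulation import ElectrodeAssembly, extracellular_potential, place_collaterals

__all__ = ["ModelConfig", "CBGNetwork"]

# projection order inside the compiled kernel
_PROJ_ORDER = [
    ("ctx", "stn"),
    ("gpe", "stn"),
    ("str", "gpe"),
    ("gpe", "gpe"),
    ("stn", "gpe"),
    ("stn", "gpi"),
    ("gpe", "gpi"),
    ("gpi", "tha"),
    ("tha", "ctx"),
    ("intn", "ctx"),
    ("ctx", "intn"),
]
# spike-history source ids
_SRC = {"ctx_soma": 0, "ctx_col": 1, "intn": 2, "stn": 3, "gpe": 4, "gpi": 5, "tha": 6,
        "str": 7}
# which source a projection's presynaptic spikes come from: the
# hyperdirect cortex->STN synapse is driven by the collateral terminal,
# every other cortical efferent by the soma.
_PRE_SOURCE = {
    ("ctx", "stn"): "ctx_col",
    ("ctx", "intn"): "ctx_soma",
    ("gpe", "stn"): "gpe",
    ("str", "gpe"): "str",
    ("gpe", "gpe"): "gpe",
    ("stn", "gpe"): "stn",
    ("stn", "gpi"): "stn",
    ("gpe", "gpi"): "gpe",
    ("gpi", "tha"): "gpi",
    ("tha", "ctx"): "tha",
    ("intn", "ctx"): "intn",
}


@dataclass
class ModelConfig:
    """Scenario-level knobs of the network model."""

    n_per_pop: int = 20
    dt_ms: float = 0.01
    duration_s: float = 10.0
    wiring_seed: int = 11
    placement_seed: int = 12
    modulation_seed: int = 13
    striatal_seed: int = 14
    init_seed: int = 15
    entrainment_seed: int = 16
    beta_modulation: bool = True
    striatal_rate_hz: float = 3.0
    params: dict | None = None

    def resolved_params(self) -> dict:
        p = neurons.load_params()
        if self.params:
            # shallow, section-wise override
            for k, v in self.params.items():
                if isinstance(v, dict) and k in p:
                    _deep_update(p[k], v)
                else:
                    p[k] = v
        return p


def _deep_update(dst: dict, src: dict) -> None:
    for k, v in src.items():
        if isinstance(v, dict) and isinstance(dst.get(k), dict):
            _deep_update(dst[k], v)
        else:
            dst[k] = v


class CBGNetwork:
    """The wired six-population network with DBS and LFP recording."""

    #: z positions of the 7 cortical compartments (mm); the collateral
    #: descends through the electrode plane toward the STN.
    CTX_Z_MM = np.array([7.5, 6.0, 4.5, 3.0, 1.5, 0.0, -1.5])

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.p = cfg.resolved_params()
        n = cfg.n_per_pop
        self.n = n
        self.dt = cfg.dt_ms

        # --- populations -------------------------------------------------
        self.pops = {
            kind: neurons.create_population(kind, n, params=self.p,
                                            seed=cfg.init_seed + i)
            for i, kind in enumerate(["ctx", "intn", "stn", "gpe", "gpi", "tha"])
        }

        # --- geometry ----------------------------------------------------
        stim_cfg = self.p["stimulation"]
        self.collateral_xy = place_collaterals(n, cfg.placement_seed)
        self.electrode = ElectrodeAssembly(
            self.collateral_xy, contact_offset_mm=stim_cfg["contact_offset_mm"],
            sigma=stim_cfg["sigma_s_per_m"],
        )
        # STN neuron (x, y) positions for the LFP, same admissible region
        self.stn_xy = place_collaterals(n, cfg.placement_seed + 1000)
        self.geometry = SynapseGeometry.from_positions(
            self.stn_xy, self.electrode.recording_contacts,
            z_offset_mm=self.p["lfp"]["z_offset_mm"],
            sigma=stim_cfg["sigma_s_per_m"],
        )
        # field per mA at each compartment of each cortical cell (mV)
        r3 = np.sqrt(
            (self.collateral_xy[:, 0] ** 2 + self.collateral_xy[:, 1] ** 2)[:, None]
            + self.CTX_Z_MM[None, :] ** 2
        )
        self.ve_unit = extracellular_potential(
            1.0, r3.ravel(), sigma=stim_cfg["sigma_s_per_m"]
        ).reshape(n, neurons.CTX_NCOMP) * 1e3  # -> mV per mA
        self.ve_unit *= float(stim_cfg.get("field_scale", 1.0))

        # LFP weight matrix: membrane current density (µA/cm²) × area ->
        # nA, divided by 4πσ r (mm) -> µV at each contact
        area = self.p["lfp"]["stn_area_cm2"]
        i_scale = area * 1e3  # µA -> nA
        self.lfp_w = i_scale / (
            4.0 * np.pi * stim_cfg["sigma_s_per_m"] * self.geometry.distances
        )

        # --- wiring ------------------------------------------------------
        proj_cfg = self.p["synapses"]["projections"]
        spec = ConnectivitySpec(
            weights={k: proj_cfg[f"{k[0]}_{k[1]}"]["weight"] for k in _PROJ_ORDER},
            delays={k: proj_cfg[f"{k[0]}_{k[1]}"]["delay"] for k in _PROJ_ORDER},
        )
        sizes = {k: n for k in ["ctx", "intn", "stn", "gpe", "gpi", "tha"]}
        self.wiring = build_network(spec, sizes, cfg.wiring_seed)

        kin = self.p["synapses"]["kinetics"]
        offs = [0]
        pre_l, post_l = [], []
        alpha, beta, erev, w, delay_steps, pre_src, post_pop = [], [], [], [], [], [], []
        u_dep, tau_rec = [], []
        for key in _PROJ_ORDER:
            proj = self.wiring[key]
            pre_l.append(proj.pre_idx)
            post_l.append(proj.post_idx)
            offs.append(offs[-1] + len(proj))
            kk = kin[proj.receptor]
            entry = proj_cfg[f"{key[0]}_{key[1]}"]
            alpha.append(entry.get("alpha", kk["alpha"]))
            beta.append(entry.get("beta", kk["beta"]))
            erev.append(entry.get("e_rev", kk["e_rev"]))
            w.append(proj.weight)
            delay_steps.append(max(1, int(round(proj.delay_ms / self.dt))))
            pre_src.append(_SRC[_PRE_SOURCE[key]])
            post_pop.append(_SRC[key[1]] if key[1] != "ctx" else 0)
            u_dep.append(entry.get("u_dep", 0.0))
            tau_rec.append(entry.get("tau_rec", 1.0))
        self.syn_pre = np.concatenate(pre_l).astype(np.int64)
        self.syn_post = np.concatenate(post_l).astype(np.int64)
        self.syn_r = np.zeros(offs[-1])
        self.syn_pulse_end = np.full(offs[-1], -1e9)
        self.syn_x = np.ones(offs[-1])
        self.syn_scale = np.ones(offs[-1])
        self.proj_off = np.asarray(offs, dtype=np.int64)
        self.proj_alpha = np.asarray(alpha)
        self.proj_beta = np.asarray(beta)
        self.proj_erev = np.asarray(erev)
        self.proj_w = np.asarray(w)
        self.proj_delay = np.asarray(delay_steps, dtype=np.int64)
        self.proj_pre_src = np.asarray(pre_src, dtype=np.int64)
        self.proj_post_pop = np.asarray(post_pop, dtype=np.int64)
        self.proj_u_dep = np.asarray(u_dep)
        self.proj_tau_rec = np.asarray(tau_rec)
        self.transmitter_ms = float(self.p["synapses"]["transmitter_ms"])

        # --- spike history ring buffers ----------------------------------
        self.hist_len = int(self.proj_delay.max()) + 1
        self.hist = {
            name: np.zeros((self.hist_len, n), dtype=np.uint8)
            for name in ["ctx_soma", "ctx_col", "intn", "stn", "gpe", "gpi", "tha"]
        }

        # --- inputs -------------------------------------------------------
        total_ms = cfg.duration_s * 1e3
        self.modulation = generate_beta_modulation(cfg.duration_s, cfg.modulation_seed) \
            if cfg.beta_modulation else None
        if self.modulation is not None:
            neurons.attach_bias_modulation(self.pops["ctx"], self.modulation, total_ms)
        self.striatal_trains = striatal_drive(
            n, cfg.striatal_rate_hz, cfg.duration_s, cfg.striatal_seed
        )
        rng = np.random.default_rng(cfg.entrainment_seed)
        self.entrainment_order = rng.permutation(n)
        self.gpe_mask = np.zeros(n, dtype=np.uint8)

        self.step_count = 0
        # cache of the striatal delay (steps) for the raster builder
        self._str_delay = max(
            1, int(round(proj_cfg["str_gpe"]["delay"] / self.dt))
        )

    # -- surrogate GPe stimulation ---------------------------------------

    def set_gpe_fraction(self, fraction: float) -> None:
        """Deliver the intracellular DBS surrogate to the first
        ``round(fraction*n)`` GPe neurons of the entrainment order."""
        k = int(round(float(np.clip(fraction, 0.0, 1.0)) * self.n))
        self.gpe_mask[:] = 0
        self.gpe_mask[self.entrainment_order[:k]] = 1

    # -- input trace builders --------------------------------------------

    def _ctx_bias_trace(self, t0: float, n_steps: int) -> np.ndarray:
        ctx = self.pops["ctx"]
        base = float(np.mean(ctx.bias))
        out = np.full(n_steps, base)
        if ctx.bias_schedule is not None:
            t = t0 + self.dt * np.arange(n_steps)
            burst = ctx.bias_schedule.is_burst(t)
            out[burst] = ctx.bias_burst
        return out - base  # offset applied on top of per-neuron bias

    def _striatal_raster(self, t0: float, n_steps: int) -> np.ndarray:
        out = np.zeros((n_steps, self.n), dtype=np.uint8)
        delay_ms = self._str_delay * self.dt
        for j, train in enumerate(self.striatal_trains):
            tt = train + delay_ms  # fold the projection delay in
            sel = tt[(tt >= t0) & (tt < t0 + n_steps * self.dt)]
            idx = ((sel - t0) / self.dt).astype(np.int64)
            out[np.clip(idx, 0, n_steps - 1), j] = 1
        return out

    # -- main advance ------------------------------------------------------

    def run_interval(
        self,
        i_dbs: np.ndarray,
        gpe_pulse: np.ndarray | None = None,
    ) -> dict:
        """Advance the model by ``len(i_dbs)`` steps.

        ``i_dbs`` is the signed DBS current (mA, cathodic negative) at
        each step; ``gpe_pulse`` the intracellular surrogate current
        (µA/cm²) delivered to the masked GPe subset.  Returns spike
        rasters (uint8, step × neuron) and the monopolar/bipolar LFP at
        the integration rate.
        """
        n_steps = len(i_dbs)
        t0 = self.step_count * self.dt
        if gpe_pulse is None:
            gpe_pulse = np.zeros(n_steps)
        ctx_bias_extra = self._ctx_bias_trace(t0, n_steps)
        str_spk = self._striatal_raster(t0, n_steps)

        out = {
            name: np.zeros((n_steps, self.n), dtype=np.uint8)
            for name in ["ctx_soma", "ctx_col", "intn", "stn", "gpe", "gpi", "tha"]
        }
        lfp_mono = np.zeros((2, n_steps))
        c, i_, s_, g_, p_, t_ = (
            self.pops["ctx"], self.pops["intn"], self.pops["stn"],
            self.pops["gpe"], self.pops["gpi"], self.pops["tha"],
        )
        _kernels.run_chunk(
            np.int64(n_steps), np.float64(self.dt), np.int64(self.step_count),
            # ctx
            c.v, c.gates["m"], c.gates["h"], c.gates["n"], c.gates["p"],
            c.gates["d1"], c.gates["d2"], c.bias, ctx_bias_extra,
            c.g_axial, c.gates["inv_area"], c.params,
            c.last_spike, c.gates["last_col"], self.ve_unit,
            # intn
            i_.v, i_.gates["m"], i_.gates["h"], i_.gates["n"], i_.bias, i_.params,
            i_.last_spike,
            # stn
            s_.v, s_.gates["n"], s_.gates["h"], s_.gates["r"], s_.gates["ca"],
            s_.bias, s_.params, s_.last_spike,
            # gpe
            g_.v, g_.gates["n"], g_.gates["h"], g_.gates["r"], g_.gates["ca"],
            g_.bias, g_.params, g_.last_spike, self.gpe_mask, gpe_pulse,
            # gpi
            p_.v, p_.gates["n"], p_.gates["h"], p_.gates["r"], p_.gates["ca"],
            p_.bias, p_.params, p_.last_spike,
            # tha
            t_.v, t_.gates["h"], t_.gates["r"], t_.bias, t_.params, t_.last_spike,
            # synapses
            self.syn_pre, self.syn_post, self.syn_r, self.syn_pulse_end,
            self.syn_x, self.syn_scale,
            self.proj_off, self.proj_alpha, self.proj_beta, self.proj_erev,
            self.proj_w, self.proj_delay, self.proj_pre_src, self.proj_post_pop,
            self.proj_u_dep, self.proj_tau_rec, np.float64(self.transmitter_ms),
            # inputs
            i_dbs.astype(np.float64), str_spk,
            # histories
            self.hist["ctx_soma"], self.hist["ctx_col"], self.hist["intn"],
            self.hist["stn"], self.hist["gpe"], self.hist["gpi"], self.hist["tha"],
            np.int64(self.hist_len),
            # outputs
            out["ctx_soma"], out["ctx_col"], out["intn"], out["stn"],
            out["gpe"], out["gpi"], out["tha"],
            self.lfp_w, lfp_mono,
        )
        self.step_count += n_steps
        for pop in self.pops.values():
            if not pop.state_finite():
                raise FloatingPointError(
                    f"integration diverged in population {pop.kind!r}"
                )
        out["lfp_mono"] = lfp_mono
        out["lfp_bipolar"] = lfp_mono[0] - lfp_mono[1]
        return out

    # -- snapshots ---------------------------------------------------------

    def snapshot(self) -> dict:
        """Deep copy of the full dynamic state (for steady-state reuse)."""
        return {
            "step_count": self.step_count,
            "pops": copy.deepcopy(
                {k: (p.v, p.gates, p.last_spike) for k, p in self.pops.items()}
            ),
            "syn_r": self.syn_r.copy(),
            "syn_pulse_end": self.syn_pulse_end.copy(),
            "syn_x": self.syn_x.copy(),
            "syn_scale": self.syn_scale.copy(),
            "hist": copy.deepcopy(self.hist),
            "gpe_mask": self.gpe_mask.copy(),
        }

    def restore(self, snap: dict) -> None:
        self.step_count = snap["step_count"]
        for k, (v, gates, last) in snap["pops"].items():
            self.pops[k].v[...] = v
            for gk, gv in gates.items():
                self.pops[k].gates[gk][...] = gv
            self.pops[k].last_spike[...] = last
        self.syn_r[...] = snap["syn_r"]
        self.syn_pulse_end[...] = snap["syn_pulse_end"]
        self.syn_x[...] = snap["syn_x"]
        self.syn_scale[...] = snap["syn_scale"]
        for k in self.hist:
            self.hist[k][...] = snap["hist"][k]
        self.gpe_mask[...] = snap["gpe_mask"]
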