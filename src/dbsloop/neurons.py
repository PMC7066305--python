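"""Conductance-based neuron populations.

Five single-compartment point models (STN, GPe, GPi, thalamic relay,
cortical fast-spiking interneuron) and a multi-compartment cortical
layer V pyramidal cell (soma → axon initial segment → main axon →
collateral).  All cells satisfy the compartmental membrane equation

    C_m dv/dt = −Σ_J I_ion − Σ_K I_syn + Σ_M I_app

with the ionic current sets of their respective source lineages:
Rubin–Terman-type basal-ganglia and thalamic cells (leak, Na, K,
T-type and high-threshold Ca, Ca-gated AHP), Pospischil-type
regular-spiking soma (leak, Na, delayed-rectifier K, slow M-type K)
and fast-spiking interneuron (no slow K), and axonal compartments with
Na, delayed-rectifier K and a slowly inactivating D-type K current
(no M current).  Parameters live in ``params.yaml``.

Integration is fixed-step semi-implicit (Crank–Nicolson voltage,
exponential gating) at 0.01 ms; spikes are upward 0 mV crossings with
a 1 ms refractory lockout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernels
from .network import BetaModulationSignal

__all__ = [
    "load_params",
    "NeuronPopulation",
    "create_population",
    "step_population",
    "attach_bias_modulation",
    "bias_at",
    "CTX_NCOMP",
]

CTX_NCOMP = 7
#: compartment labels of the cortical cell chain
CTX_COMPARTMENTS = ("soma", "ais", "axon1", "axon2", "col1", "col2", "col3")

_RT_KEYS = (
    "g_leak e_leak g_na e_na g_k e_k g_t g_ca e_ca g_ahp k1 eps k_ca "
    "phi_h phi_n phi_r cm".split()
)
_THA_KEYS = "g_leak e_leak g_na e_na g_k e_k g_t e_ca cm".split()
_INTN_KEYS = "g_leak e_leak g_na e_na g_k e_k v_t cm".split()
_CTX_KEYS = (
    "g_leak_soma e_leak g_na_soma e_na g_k_soma e_k g_m tau_max v_t "
    "g_leak_axon g_na_axon g_k_axon g_d cm h_slow_axon".split()
)


def load_params() -> dict:
    """Load the versioned parameter file shipped with the package."""
    ref = importlib.resources.files("dbsloop").joinpath("params.yaml")
    return yaml.safe_load(ref.read_text())


def _pack(cfg: dict, keys: list[str]) -> np.ndarray:
    return np.array([float(cfg[k]) for k in keys])


@dataclass
class NeuronPopulation:
    """State of one population; arrays are (n,) or (n, n_comp)."""

    kind: str
    n: int
    v: np.ndarray
    gates: dict = field(default_factory=dict)
    params: np.ndarray | None = None
    bias: np.ndarray | None = None
    last_spike: np.ndarray | None = None
    g_axial: np.ndarray | None = None
    bias_schedule: object = None
    bias_burst: float | None = None

    def state_finite(self) -> bool:
        ok = np.all(np.isfinite(self.v)) and np.all(np.abs(self.v) < 200.0)
        for g in self.gates.values():
            ok = ok and np.all(np.isfinite(g))
        return bool(ok)


def create_population(
    kind: str, n: int, params: dict | None = None, seed: int = 0
) -> NeuronPopulation:
    """Initialize a population of ``kind`` in {stn, gpe, gpi, tha, intn, ctx}."""
    cfg_all = params if params is not None else load_params()
    cfg = cfg_all["neurons"][kind]
    rng = np.random.default_rng(seed)
    if kind in ("stn", "gpe", "gpi"):
        pop = NeuronPopulation(
            kind=kind,
            n=n,
            v=np.full(n, -62.0) + rng.uniform(-5, 5, n),
            gates={
                "n": np.full(n, 0.1),
                "h": np.full(n, 0.7),
                "r": np.full(n, 0.2),
                "ca": np.full(n, 0.1),
            },
            params=_pack(cfg, _RT_KEYS),
            bias=np.full(n, float(cfg["bias"])),
            last_spike=np.full(n, -1e9),
        )
    elif kind == "tha":
        pop = NeuronPopulation(
            kind=kind,
            n=n,
            v=np.full(n, -65.0) + rng.uniform(-5, 5, n),
            gates={"h": np.full(n, 0.6), "r": np.full(n, 0.2)},
            params=_pack(cfg, _THA_KEYS),
            bias=np.full(n, float(cfg["bias"])),
            last_spike=np.full(n, -1e9),
        )
    elif kind == "intn":
        pop = NeuronPopulation(
            kind=kind,
            n=n,
            v=np.full(n, -70.0) + rng.uniform(-3, 3, n),
            gates={
                "m": np.zeros(n),
                "h": np.full(n, 0.9),
                "n": np.zeros(n),
            },
            params=_pack(cfg, _INTN_KEYS),
            bias=np.full(n, float(cfg["bias"])),
            last_spike=np.full(n, -1e9),
        )
    elif kind == "ctx":
        nc = CTX_NCOMP
        pop = NeuronPopulation(
            kind=kind,
            n=n,
            v=np.full((n, nc), -70.0) + rng.uniform(-3, 3, (n, nc)),
            gates={
                "m": np.zeros((n, nc)),
                "h": np.full((n, nc), 0.9),
                "n": np.zeros((n, nc)),
                "p": np.zeros(n),
                "d1": np.zeros((n, nc)),
                "d2": np.full((n, nc), 0.6),
            },
            params=_pack(cfg, _CTX_KEYS),
            bias=np.full(n, float(cfg["bias_baseline"]))
            + rng.normal(0.0, float(cfg["bias_jitter"]), n),
            last_spike=np.full(n, -1e9),
            g_axial=np.asarray(cfg["g_axial"], dtype=float),
            bias_burst=float(cfg["bias_burst"]),
        )
        pop.gates["last_col"] = np.full(n, -1e9)
        pop.gates["inv_area"] = 1.0 / np.asarray(cfg["area_rel"], dtype=float)
    else:
        raise ValueError(f"unknown population kind {kind!r}")
    return pop


def step_population(
    pop: NeuronPopulation,
    synaptic_input: tuple[np.ndarray, np.ndarray] | None,
    extracellular_potential: np.ndarray | None,
    dt: float,
    t: float = 0.0,
    i_app: np.ndarray | None = None,
) -> np.ndarray:
    """Advance a population one step; returns the boolean spike vector.

    ``synaptic_input`` is the per-neuron (conductance, conductance ×
    reversal) pair produced by the synapse banks; ``extracellular_potential``
    (mV per compartment) applies only to the cortical cell, where it
    couples through the axial activating-function source term.  For the
    cortical population the returned spikes are somatic; collateral
    terminal spikes are stored in ``pop.gates['spk_col']``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = pop.n
    gs = np.zeros(n) if synaptic_input is None else synaptic_input[0]
    ges = np.zeros(n) if synaptic_input is None else synaptic_input[1]
    iapp = pop.bias.copy() if pop.kind != "ctx" else None
    if i_app is not None and pop.kind != "ctx":
        iapp = iapp + i_app
    spk = np.zeros(n, dtype=np.bool_)
    g = pop.gates
    if pop.kind == "stn":
        _kernels.stn_step(
            pop.v, g["n"], g["h"], g["r"], g["ca"], gs, ges, iapp, dt,
            pop.params, pop.last_spike, t, spk,
        )
    elif pop.kind in ("gpe", "gpi"):
        _kernels.gp_step(
            pop.v, g["n"], g["h"], g["r"], g["ca"], gs, ges, iapp, dt,
            pop.params, pop.last_spike, t, spk,
        )
    elif pop.kind == "tha":
        _kernels.tha_step(
            pop.v, g["h"], g["r"], gs, ges, iapp, dt,
            pop.params, pop.last_spike, t, spk,
        )
    elif pop.kind == "intn":
        _kernels.intn_step(
            pop.v, g["m"], g["h"], g["n"], gs, ges, iapp, dt,
            pop.params, pop.last_spike, t, spk,
        )
    elif pop.kind == "ctx":
        if extracellular_potential is None:
            ve = np.zeros((n, CTX_NCOMP))
        else:
            ve = extracellular_potential
        bias = bias_at(pop, t)
        extra = np.zeros((n, CTX_NCOMP)) if i_app is None else i_app
        spk_col = np.zeros(n, dtype=np.bool_)
        _kernels.ctx_step(
            pop.v, g["m"], g["h"], g["n"], g["p"], g["d1"], g["d2"],
            gs, ges, bias, extra, ve, pop.g_axial, g["inv_area"], dt,
            pop.params, pop.last_spike, g["last_col"], t, spk, spk_col,
        )
        pop.gates["spk_col"] = spk_col
    if not pop.state_finite():
        bad = int(np.argmax(~np.isfinite(np.atleast_2d(pop.v)).all(axis=-1))) \
            if pop.v.ndim > 1 else int(np.argmax(~np.isfinite(pop.v)))
        raise FloatingPointError(
            f"integration diverged in population {pop.kind!r}, neuron {bad}"
        )
    return spk


def attach_bias_modulation(
    pop: NeuronPopulation, modulation: BetaModulationSignal, duration_ms: float | None = None
) -> NeuronPopulation:
    """Attach the beta-burst schedule to a cortical population's drive.

    During burst intervals the soma bias takes the high value,
    otherwise the baseline; intervals are half-open [start, end).
    """
    if pop.kind != "ctx":
        raise ValueError("bias modulation applies to the cortical population")
    if duration_ms is not None and modulation.duration_ms < duration_ms:
        raise ValueError("modulation schedule shorter than the simulation")
    pop.bias_schedule = modulation
    return pop


def bias_at(pop: NeuronPopulation, t_ms: float) -> np.ndarray:
    """Per-neuron somatic bias current at time ``t_ms``."""
    if pop.bias_schedule is None:
        return pop.bias
    if bool(pop.bias_schedule.is_burst(t_ms)[0]):
        return pop.bias + (pop.bias_burst - np.mean(pop.bias))
    return pop.bias
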