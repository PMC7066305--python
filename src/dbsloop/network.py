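"""Network wiring, synapse kinetics, and input signals.

Six populations — cortical pyramidal cells, cortical interneurons,
STN, GPe, GPi and thalamus — are wired with fixed per-projection
afferent counts drawn uniformly at random without replacement:

    cortex→STN 5, GPe→STN 2, striatum→GPe 1, GPe→GPe 1, STN→GPe 2,
    STN→GPi 1, GPe→GPi 1, GPi→thalamus 1, thalamus→cortex 1,
    interneuron→cortex 10, cortex→interneuron 10.

Synapses follow first-order transmitter-pulse kinetics: a presynaptic
spike opens a 1 ms transmitter pulse during which the gating state R
relaxes toward α/(α+β) with time constant 1/(α+β); outside the pulse R
decays as exp(−βt).  The synaptic current is ``I_syn = g R (V − E_rev)``
with AMPA (E_rev = 0 mV) and GABAa (E_rev = −80 mV) receptor types.

Striatal input to GPe is reduced to independent 3 Hz Poisson trains,
and the time-varying cortical drive is described by a stochastic
burst schedule alternating 100 ms "healthy" and 600–1000 ms
"pathological" beta bursts separated by fixed 300 ms gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PROJECTIONS",
    "ConnectivitySpec",
    "Projection",
    "build_network",
    "wiring_to_frame",
    "striatal_drive",
    "BetaModulationSignal",
    "generate_beta_modulation",
    "SynapseBank",
]

#: (pre population, post population) -> afferents per postsynaptic neuron.
CONNECTION_COUNTS: dict[tuple[str, str], int] = {
    ("ctx", "stn"): 5,
    ("gpe", "stn"): 2,
    ("str", "gpe"): 1,
    ("gpe", "gpe"): 1,
    ("stn", "gpe"): 2,
    ("stn", "gpi"): 1,
    ("gpe", "gpi"): 1,
    ("gpi", "tha"): 1,
    ("tha", "ctx"): 1,
    ("intn", "ctx"): 10,
    ("ctx", "intn"): 10,
}

#: Receptor type per projection (AMPA excitatory / GABAa inhibitory).
RECEPTORS: dict[tuple[str, str], str] = {
    ("ctx", "stn"): "ampa",
    ("gpe", "stn"): "gabaa",
    ("str", "gpe"): "gabaa",
    ("gpe", "gpe"): "gabaa",
    ("stn", "gpe"): "ampa",
    ("stn", "gpi"): "ampa",
    ("gpe", "gpi"): "gabaa",
    ("gpi", "tha"): "gabaa",
    ("tha", "ctx"): "ampa",
    ("intn", "ctx"): "gabaa",
    ("ctx", "intn"): "ampa",
}

PROJECTIONS = tuple(CONNECTION_COUNTS)


@dataclass(frozen=True)
class ConnectivitySpec:
    """Afferent counts, weights (µS-equivalent conductance scale) and
    transmission delays (ms) per projection."""

    counts: dict = field(default_factory=lambda: dict(CONNECTION_COUNTS))
    weights: dict = field(default_factory=dict)
    delays: dict = field(default_factory=dict)

    def receptor(self, projection: tuple[str, str]) -> str:
        return RECEPTORS[projection]


@dataclass
class Projection:
    """Edge list of one (pre → post) projection."""

    pre_pop: str
    post_pop: str
    pre_idx: np.ndarray
    post_idx: np.ndarray
    receptor: str
    weight: float
    delay_ms: float

    def __len__(self) -> int:
        return len(self.pre_idx)


def build_network(
    spec: ConnectivitySpec, sizes: dict[str, int], seed: int
) -> dict[tuple[str, str], Projection]:
    """Draw the random wiring for every projection.

    Each postsynaptic neuron receives exactly the specified number of
    presynaptic partners, sampled uniformly without replacement;
    GPe→GPe excludes self-connections.  Identical seeds give identical
    wiring.
    """
    rng = np.random.default_rng(seed)
    wiring: dict[tuple[str, str], Projection] = {}
    for (pre, post), count in spec.counts.items():
        n_pre = sizes[pre] if pre != "str" else sizes["gpe"]
        n_post = sizes[post]
        pool = n_pre - 1 if pre == post else n_pre
        if count > pool:
            raise ValueError(
                f"{pre}->{post}: {count} afferents requested from {pool} candidates"
            )
        pre_idx = np.empty(n_post * count, dtype=np.int64)
        post_idx = np.repeat(np.arange(n_post), count)
        for j in range(n_post):
            candidates = np.arange(n_pre)
            if pre == post:
                candidates = np.delete(candidates, j)
            pre_idx[j * count : (j + 1) * count] = rng.choice(
                candidates, size=count, replace=False
            )
        wiring[(pre, post)] = Projection(
            pre_pop=pre,
            post_pop=post,
            pre_idx=pre_idx,
            post_idx=post_idx,
            receptor=spec.receptor((pre, post)),
            weight=float(spec.weights.get((pre, post), 1.0)),
            delay_ms=float(spec.delays.get((pre, post), 1.0)),
        )
    return wiring


def striatal_drive(
    n_targets: int, rate_hz: float, duration_s: float, seed: int
) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains (times in ms).

    One train per GPe target; 3 Hz reproduces the reduced striatal
    drive of the dopamine-depleted network.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_targets):
        if rate_hz == 0:
            trains.append(np.empty(0))
            continue
        n_expect = int(rate_hz * duration_s * 3 + 20)
        isi = rng.exponential(1e3 / rate_hz, size=n_expect)
        t = np.cumsum(isi)
        while t.size and t[-1] < duration_s * 1e3:
            t = np.concatenate([t, t[-1] + np.cumsum(
                rng.exponential(1e3 / rate_hz, size=n_expect))])
        trains.append(t[t < duration_s * 1e3])
    return trains


#: Healthy burst duration (ms).
T_HB_MS = 100.0
#: Pathological burst duration range (ms).
T_PB_RANGE_MS = (600.0, 1000.0)
#: Fixed interburst gap (ms).
INTERBURST_MS = 300.0


@dataclass(frozen=True)
class BetaModulationSignal:
    """Stochastic beta-burst schedule.

    ``starts``/``durations`` in ms (half-open intervals
    [start, start+duration)), ``labels`` in {"healthy", "pathological"}.
    The final burst may be truncated by the signal duration.
    """

    starts: np.ndarray
    durations: np.ndarray
    labels: tuple
    duration_ms: float
    seed: int

    def is_burst(self, t_ms: np.ndarray) -> np.ndarray:
        """Boolean burst mask at the query times (half-open convention)."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        mask = np.zeros(t.shape, dtype=bool)
        for s, d in zip(self.starts, self.durations):
            mask |= (t >= s) & (t < s + d)
        return mask


def generate_beta_modulation(
    duration_s: float,
    seed: int,
    p_healthy: float = 0.5,
    initial_gap: bool = True,
) -> BetaModulationSignal:
    """Draw the alternating burst / interburst schedule.

    Each burst is labeled healthy with probability ``p_healthy``
    (duration 100 ms) or pathological (duration uniform on
    [600, 1000] ms); consecutive bursts are separated by exactly
    300 ms.  A burst overrunning the signal end is truncated.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    total_ms = duration_s * 1e3
    starts, durations, labels = [], [], []
    t = INTERBURST_MS if initial_gap else 0.0
    while t < total_ms:
        if rng.uniform() <= p_healthy:
            dur, label = T_HB_MS, "healthy"
        else:
            dur, label = rng.uniform(*T_PB_RANGE_MS), "pathological"
        dur = min(dur, total_ms - t)
        starts.append(t)
        durations.append(dur)
        labels.append(label)
        t += dur + INTERBURST_MS
    return BetaModulationSignal(
        starts=np.asarray(starts),
        durations=np.asarray(durations),
        labels=tuple(labels),
        duration_ms=total_ms,
        seed=seed,
    )


# Transmitter-pulse synapse kinetics (per-receptor constants):
# alpha (1/ms, at unit transmitter), beta (1/ms), reversal (mV).
SYNAPSE_KINETICS = {
    "ampa": {"alpha": 1.1, "beta": 0.19, "e_rev": 0.0},
    "gabaa": {"alpha": 5.0, "beta": 0.08, "e_rev": -80.0},
}
#: Transmitter pulse duration after each presynaptic spike (ms).
TRANSMITTER_MS = 1.0


class SynapseBank:
    """State of every synapse of one projection.

    Reference (pure-NumPy) implementation of the kinetics also used by
    the compiled simulation kernel; kept simple so it can serve as the
    oracle in tests.  Spikes are delivered with the projection delay
    through a pending-event list.  Optional short-term depression
    (release-resource scheme: each arriving spike scales its
    transmitter pulse by the available resource x, depleting it by a
    fraction ``u_dep``; x recovers toward 1 with ``tau_rec``).
    """

    def __init__(self, projection: Projection, alpha: float | None = None,
                 beta: float | None = None, e_rev: float | None = None,
                 u_dep: float = 0.0, tau_rec: float = 1.0) -> None:
        kin = SYNAPSE_KINETICS[projection.receptor]
        self.projection = projection
        self.alpha = kin["alpha"] if alpha is None else alpha
        self.beta = kin["beta"] if beta is None else beta
        self.e_rev = kin["e_rev"] if e_rev is None else e_rev
        self.u_dep = u_dep
        self.tau_rec = tau_rec
        n = len(projection)
        self.r = np.zeros(n)
        self.x = np.ones(n)  # release resource (depression)
        self.scale = np.ones(n)  # transmitter-pulse scale of the last spike
        self.pulse_end = np.full(n, -np.inf)  # transmitter pulse open until
        self._pending: list[tuple[float, int]] = []  # (arrival time, synapse)

    def deliver_spikes(self, pre_neuron_ids: np.ndarray, t_ms: float) -> None:
        """Queue presynaptic spikes fired at ``t_ms`` for delayed arrival."""
        pre_idx = self.projection.pre_idx
        for pid in np.atleast_1d(pre_neuron_ids):
            if pid < 0:
                raise KeyError(f"spike targets nonexistent synapse source {pid}")
            for s in np.nonzero(pre_idx == pid)[0]:
                self._pending.append((t_ms + self.projection.delay_ms, int(s)))

    def step(self, dt_ms: float, t_ms: float) -> None:
        """Advance the kinetic state by one time step ending at ``t_ms``."""
        arrivals = [s for (ta, s) in self._pending if ta <= t_ms]
        if arrivals:
            self._pending = [(ta, s) for (ta, s) in self._pending if ta > t_ms]
            for s in arrivals:
                self.pulse_end[s] = t_ms + TRANSMITTER_MS
                if self.u_dep > 0.0:
                    self.scale[s] = self.x[s]
                    self.x[s] *= 1.0 - self.u_dep
        open_ = t_ms < self.pulse_end
        r_inf = self.alpha / (self.alpha + self.beta)
        tau = 1.0 / (self.alpha + self.beta)
        target = r_inf * (self.scale if self.u_dep > 0.0 else 1.0)
        self.r[open_] = target[open_] + (self.r[open_] - target[open_]) * np.exp(-dt_ms / tau) \
            if self.u_dep > 0.0 else r_inf + (self.r[open_] - r_inf) * np.exp(-dt_ms / tau)
        self.r[~open_] *= np.exp(-self.beta * dt_ms)
        if self.u_dep > 0.0:
            self.x = 1.0 + (self.x - 1.0) * np.exp(-dt_ms / self.tau_rec)

    def currents(self, v_post: np.ndarray) -> np.ndarray:
        """Per-postsynaptic-neuron summed synaptic current.

        ``I_syn = w R (V_m − E_rev)`` summed over each neuron's
        afferent synapses (sign: positive current hyperpolarizes, as in
        a conductance-based membrane equation).
        """
        v = v_post[self.projection.post_idx]
        i_syn = self.projection.weight * self.r * (v - self.e_rev)
        out = np.zeros(v_post.shape[0])
        np.add.at(out, self.projection.post_idx, i_syn)
        return out


def wiring_to_frame(wiring: dict) -> "pandas.DataFrame":  # noqa: F821
    """Flatten a wiring dict to an edge-list table.

    Columns: pre_pop, pre_id, post_pop, post_id, weight, delay — one
    row per synapse; round-trips losslessly through CSV.
    """
    import pandas as pd

    rows = []
    for (pre, post), proj in wiring.items():
        rows.append(
            pd.DataFrame(
                {
                    "pre_pop": pre,
                    "pre_id": proj.pre_idx,
                    "post_pop": post,
                    "post_id": proj.post_idx,
                    "weight": proj.weight,
                    "delay": proj.delay_ms,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
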