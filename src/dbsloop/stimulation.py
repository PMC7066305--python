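"""Extracellular DBS: waveform, point-source field, and activation.

The electrode is idealized as three point sources in a homogeneous,
isotropic, purely resistive medium (quasi-static approximation): one
stimulating contact at the origin and two flanking recording contacts
forming a bipolar pair.  The stimulation waveform is a train of
periodic cathodic rectangular current pulses.  Cortical axon
collaterals run perpendicular to the electrode plane and are placed
uniformly at random in a 6 mm × 6 mm square around the lead, excluding
the lead cross-section itself (radius 0.7 mm).

This module also implements the bookkeeping the network model uses to
couple stimulation strength to the pallidum: the fraction of cortical
collaterals whose firing rate exceeds 60 Hz defines the fraction of
GPe neurons (in a fixed randomized entrainment order) that receive an
intracellular pulse train synchronized to the DBS waveform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElectrodeAssembly",
    "DBSWaveform",
    "place_collaterals",
    "extracellular_potential",
    "waveform_samples",
    "pulse_onsets",
    "detect_activation",
    "gpe_surrogate_targets",
]

logger = logging.getLogger(__name__)

#: Gray-matter conductivity (S/m).
SIGMA = 0.27
#: Electrode lead radius (mm): collaterals may not lie inside it.
LEAD_RADIUS = 0.7
#: Half-width of the collateral placement square (mm).
SQUARE_HALF_WIDTH = 3.0
#: Firing-rate threshold (Hz) above which a collateral counts as activated.
ACTIVATION_RATE_HZ = 60.0
#: Fraction of pulses that must evoke a response for "reliable" stimulation.
RELIABLE_FRACTION = 0.9

AMPLITUDE_BOUNDS_MA = (0.0, 3.0)
FREQUENCY_BOUNDS_HZ = (0.0, 250.0)
PULSE_WIDTH_US = 60.0


@dataclass(frozen=True)
class DBSWaveform:
    """Cathodic rectangular pulse train (amplitude mA, frequency Hz, width µs)."""

    amplitude_ma: float
    frequency_hz: float
    width_us: float = PULSE_WIDTH_US

    def clamped(self) -> "DBSWaveform":
        a = float(np.clip(self.amplitude_ma, *AMPLITUDE_BOUNDS_MA))
        f = float(np.clip(self.frequency_hz, *FREQUENCY_BOUNDS_HZ))
        if a != self.amplitude_ma or f != self.frequency_hz:
            logger.warning(
                "DBS parameters (%.3g mA, %.3g Hz) outside bounds; clamped",
                self.amplitude_ma,
                self.frequency_hz,
            )
        return DBSWaveform(a, f, self.width_us)


@dataclass(frozen=True)
class ElectrodeAssembly:
    """Stimulating contact at the origin plus a bipolar recording pair.

    Recording contacts sit symmetrically at ``±contact_offset_mm`` on
    the in-plane x axis; collateral coordinates are (x, y) positions in
    the electrode plane, each fiber running perpendicular to it.
    """

    collateral_xy: np.ndarray
    contact_offset_mm: float = 1.0
    sigma: float = SIGMA

    def __post_init__(self) -> None:
        xy = np.asarray(self.collateral_xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("collateral_xy must have shape (n, 2)")
        r = np.hypot(xy[:, 0], xy[:, 1])
        if np.any(r <= LEAD_RADIUS):
            raise ValueError("collateral inside the electrode lead")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def recording_contacts(self) -> np.ndarray:
        """(2, 3) xyz positions of the bipolar pair (+x first)."""
        d = self.contact_offset_mm
        return np.array([[d, 0.0, 0.0], [-d, 0.0, 0.0]])


def place_collaterals(
    n: int,
    seed: int,
    half_width: float = SQUARE_HALF_WIDTH,
    exclusion_radius: float = LEAD_RADIUS,
) -> np.ndarray:
    """Sample collateral (x, y) positions uniformly over the admissible square.

    Rejection sampling over the ``2*half_width`` square minus the lead
    disc; reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-half_width, half_width, size=(2 * (n - filled) + 8, 2))
        ok = cand[np.hypot(cand[:, 0], cand[:, 1]) > exclusion_radius]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def extracellular_potential(
    i_dbs_ma: float | np.ndarray,
    r_mm: np.ndarray,
    sigma: float = SIGMA,
) -> np.ndarray:
    """Point-source potential ``V_e = I_DBS / (4 π σ r)`` in volts.

    ``i_dbs_ma`` may be a scalar or a time series; ``r_mm`` the
    distances of the evaluation points from the source in mm.  With a
    time series the result has shape ``(n_times, n_points)``.
    """
    r = np.atleast_1d(np.asarray(r_mm, dtype=float))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if np.any(r <= 0):
        raise ValueError("singular geometry: point on the source")
    i_a = np.asarray(i_dbs_ma, dtype=float) * 1e-3
    r_m = r * 1e-3
    if i_a.ndim == 0:
        return i_a / (4.0 * np.pi * sigma * r_m)
    return i_a[:, None] / (4.0 * np.pi * sigma * r_m[None, :])


def pulse_onsets(frequency_hz: float, t0_ms: float, t1_ms: float) -> np.ndarray:
    """Onset times (ms) of pulses in [t0, t1): integer multiples of the period."""
    if t1_ms <= t0_ms:
        raise ValueError("t1 must exceed t0")
    if frequency_hz <= 0:
        return np.empty(0)
    period = 1e3 / frequency_hz
    k0 = int(np.ceil(t0_ms / period - 1e-9))
    k1 = int(np.ceil(t1_ms / period - 1e-9))
    return np.arange(k0, k1) * period


def waveform_samples(
    w: DBSWaveform, t0_ms: float, t1_ms: float, dt_ms: float
) -> np.ndarray:
    """Sample the cathodic pulse train on ``[t0, t1)`` at step ``dt``.

    Pulse onsets fall on integer multiples of the period (measured from
    t = 0); the waveform is ``-amplitude`` for one pulse width after
    each onset and zero elsewhere.  Zero frequency yields silence.
    Out-of-bound parameters are clamped with a warning — controllers
    are responsible for clamping, this is a safety net.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    w = w.clamped()
    t = t0_ms + dt_ms * np.arange(int(round((t1_ms - t0_ms) / dt_ms)))
    out = np.zeros_like(t)
    if w.frequency_hz <= 0 or w.amplitude_ma == 0:
        return out
    period = 1e3 / w.frequency_hz
    width_ms = w.width_us * 1e-3
    phase = t - np.floor(t / period + 1e-9) * period
    out[phase < width_ms - 1e-9] = -w.amplitude_ma
    return out


def detect_activation(
    spike_trains_ms: list[np.ndarray],
    stim_times_ms: np.ndarray,
    window_s: float,
    response_window_ms: float = 2.5,
) -> dict:
    """Classify collateral activation during a stimulation window.

    A collateral is *activated* when its firing rate over the window
    exceeds 60 Hz, and *reliably stimulated* when at least 90% of DBS
    pulses are followed by a collateral spike within
    ``response_window_ms``.  Returns per-neuron flags and the activated
    population fraction.
    """
    stim = np.asarray(stim_times_ms, dtype=float)
    if stim.size == 0:
        raise ValueError("empty stimulation train: fraction undefined")
    if stim.size > 1 and window_s * 1e3 < 10 * float(np.median(np.diff(stim))):
        raise ValueError("window must cover at least 10 stimulation pulses")
    activated = np.zeros(len(spike_trains_ms), dtype=bool)
    reliable = np.zeros(len(spike_trains_ms), dtype=bool)
    for i, train in enumerate(spike_trains_ms):
        train = np.asarray(train, dtype=float)
        activated[i] = train.size / window_s > ACTIVATION_RATE_HZ
        if train.size:
            idx = np.searchsorted(train, stim)
            hit = (idx < train.size) & (train[np.minimum(idx, train.size - 1)] - stim
                                        <= response_window_ms)
            reliable[i] = hit.mean() >= RELIABLE_FRACTION
    return {
        "activated": activated,
        "reliable": reliable,
        "fraction": float(activated.mean()) if len(activated) else 0.0,
    }


def gpe_surrogate_targets(
    fraction_activated: float, entrainment_order: np.ndarray, gpe_size: int
) -> np.ndarray:
    """GPe neurons receiving the intracellular DBS surrogate current.

    The first ``round(fraction * gpe_size)`` neurons of the fixed
    randomized entrainment order are selected, so the stimulated set is
    nested as the fraction grows.
    """
    if not 0.0 <= fraction_activated <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    order = np.asarray(entrainment_order)
    if order.size != gpe_size or set(order.tolist()) != set(range(gpe_size)):
        raise ValueError("entrainment_order must be a permutation of the population")
    k = int(round(fraction_activated * gpe_size))
    return order[:k].copy()
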