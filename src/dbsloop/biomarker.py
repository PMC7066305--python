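"""Beta-band biomarker extraction from the LFP.

The controller's measured variable is the average rectified value
(ARV) of the beta-band LFP: the LFP window is band-pass filtered with
a fourth-order Chebyshev type-I filter (8 Hz bandwidth centered on the
DBS-off spectral peak, 0.5 dB passband ripple, applied causally since
the controller runs online), full-wave rectified, the final 100 ms is
discarded to remove the filter edge artifact, and the mean of the last
100 ms of what remains is the ARV — i.e. the average over
[t − 200 ms, t − 100 ms] relative to the window end.

Targets are percentiles of the ARV series from a 30 s DBS-off epoch:
the 20th percentile is the single-threshold target and the 10th the
lower bound of the dual-threshold band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BetaFilterSpec",
    "design_beta_filter",
    "beta_arv",
    "arv_series",
    "estimate_targets",
    "band_power",
    "spectral_peak",
]

BETA_BAND = (13.0, 30.0)
#: Passband width of the ARV filter (Hz).
FILTER_BANDWIDTH = 8.0
#: Passband ripple of the Chebyshev type-I design (dB).
FILTER_RIPPLE_DB = 0.5
#: Epoch dropped from the end of the rectified signal (ms).
DISCARD_MS = 100.0
#: Averaging epoch for the ARV (ms).
AVERAGE_MS = 100.0
#: Minimum LFP window required per ARV evaluation (ms).
MIN_WINDOW_MS = 300.0


@dataclass(frozen=True)
class BetaFilterSpec:
    """Chebyshev band-pass specification for the beta ARV chain."""

    center_hz: float
    fs_hz: float
    bandwidth_hz: float = FILTER_BANDWIDTH
    ripple_db: float = FILTER_RIPPLE_DB

    def __post_init__(self) -> None:
        if self.center_hz - self.bandwidth_hz / 2 <= 0:
            raise ValueError("filter band extends below 0 Hz")
        if self.center_hz + self.bandwidth_hz / 2 >= self.fs_hz / 2:
            raise ValueError("filter band exceeds Nyquist")

    @property
    def band(self) -> tuple[float, float]:
        return (
            self.center_hz - self.bandwidth_hz / 2,
            self.center_hz + self.bandwidth_hz / 2,
        )


def design_beta_filter(spec: BetaFilterSpec) -> np.ndarray:
    """Second-order sections of the fourth-order Chebyshev band-pass."""
    # An order-2 prototype yields a 4th-order band-pass after the
    # low-pass -> band-pass transform.
    return signal.cheby1(
        2, spec.ripple_db, spec.band, btype="bandpass", fs=spec.fs_hz, output="sos"
    )


def filter_gain(spec: BetaFilterSpec, freq_hz: float) -> float:
    """Magnitude response of the designed filter at one frequency."""
    sos = design_beta_filter(spec)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=spec.fs_hz)
    return float(np.abs(h[0]))


def beta_arv(lfp_window: np.ndarray, spec: BetaFilterSpec) -> float:
    """Beta ARV of one LFP window (filter → rectify → trim → average)."""
    x = np.asarray(lfp_window, dtype=float)
    if x.size * 1e3 / spec.fs_hz < MIN_WINDOW_MS:
        raise ValueError(
            f"window shorter than {MIN_WINDOW_MS:.0f} ms: insufficient history"
        )
    sos = design_beta_filter(spec)
    rect = np.abs(signal.sosfilt(sos, x))
    n_discard = int(round(DISCARD_MS * 1e-3 * spec.fs_hz))
    n_avg = int(round(AVERAGE_MS * 1e-3 * spec.fs_hz))
    kept = rect[: rect.size - n_discard]
    return float(np.mean(kept[-n_avg:]))


def arv_series(
    lfp: np.ndarray,
    spec: BetaFilterSpec,
    hop_ms: float = 20.0,
    window_ms: float = MIN_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window ARV along a full LFP trace.

    Evaluates :func:`beta_arv` every ``hop_ms`` once ``window_ms`` of
    history is available, mirroring the online controller chain.
    Returns (times_ms, arv) with times referenced to the window end.
    To avoid re-filtering overlapping windows the whole trace is
    filtered causally once, which is exactly equivalent.
    """
    x = np.asarray(lfp, dtype=float)
    sos = design_beta_filter(spec)
    rect = np.abs(signal.sosfilt(sos, x))
    n_win = int(round(window_ms * 1e-3 * spec.fs_hz))
    n_hop = int(round(hop_ms * 1e-3 * spec.fs_hz))
    n_discard = int(round(DISCARD_MS * 1e-3 * spec.fs_hz))
    n_avg = int(round(AVERAGE_MS * 1e-3 * spec.fs_hz))
    ends = np.arange(n_win, x.size + 1, n_hop)
    arv = np.array(
        [np.mean(rect[e - n_discard - n_avg : e - n_discard]) for e in ends]
    )
    return ends * 1e3 / spec.fs_hz, arv


def estimate_targets(arv_series_dbs_off: np.ndarray) -> tuple[float, float]:
    """Target (20th percentile) and lower bound (10th) of the DBS-off ARV.

    Percentiles use the linear-interpolation convention.
    """
    a = np.asarray(arv_series_dbs_off, dtype=float)
    if a.size == 0:
        raise ValueError("empty ARV series")
    b_target = float(np.percentile(a, 20, method="linear"))
    b_lower = float(np.percentile(a, 10, method="linear"))
    return b_target, b_lower


def band_power(
    lfp: np.ndarray,
    fs_hz: float,
    band: tuple[float, float],
    nperseg_s: float = 1.0,
) -> float:
    """Averaged-periodogram power of a trace inside a frequency band.

    Welch PSD (Hann segments of ``nperseg_s`` seconds, 50% overlap)
    integrated over ``band`` by the trapezoidal rule.
    """
    x = np.asarray(lfp, dtype=float)
    if x.size < 2 * fs_hz:
        raise ValueError("trace must cover at least 2 s")
    f1, f2 = band
    if not 0 <= f1 < f2 <= fs_hz / 2:
        raise ValueError("band outside [0, Nyquist]")
    f, pxx = signal.welch(x, fs=fs_hz, nperseg=int(round(nperseg_s * fs_hz)))
    sel = (f >= f1) & (f <= f2)
    return float(np.trapezoid(pxx[sel], f[sel]))


def spectral_peak(
    lfp: np.ndarray,
    fs_hz: float,
    band: tuple[float, float] = BETA_BAND,
    nperseg_s: float = 2.0,
    detrend_aperiodic: bool = True,
) -> float:
    """Frequency (Hz) of the dominant spectral peak inside ``band``.

    By default the aperiodic (1/f-like) background is removed first by
    fitting a line to log-power vs log-frequency over 5–45 Hz and
    peak-picking the residual, so a sloping background cannot pull the
    detected peak to the band edge.
    """
    x = np.asarray(lfp, dtype=float)
    f, pxx = signal.welch(x, fs=fs_hz, nperseg=min(int(nperseg_s * fs_hz), x.size))
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise ValueError("no PSD bins inside the requested band")
    score = np.log10(np.maximum(pxx, 1e-300))
    if detrend_aperiodic:
        fit_sel = (f >= 5.0) & (f <= 45.0) & (f > 0)
        coef = np.polyfit(np.log10(f[fit_sel]), score[fit_sel], 1)
        score = score - np.polyval(coef, np.log10(np.maximum(f, f[1])))
    return float(f[sel][np.argmax(score[sel])])
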