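"""Closed-loop DBS controllers.

Implements the feedback laws used to modulate a single DBS parameter
(pulse amplitude in mA or pulse frequency in Hz) from the normalized
beta-ARV error signal:

* on-off control — fixed increment toward the upper/lower bound,
* dual-threshold control — fixed increment outside a target band,
* P control — proportional feedback,
* PI control — proportional-integral feedback with conditional
  integration (anti-windup),

together with the clinical rate-limit constraint (the full parameter
range may be traversed no faster than one ramp period ``T_Ramp``) and
the PI tuning rule that selects the largest proportional gain that
respects that rate limit on a DBS-off reference recording.

All controllers operate at a fixed sampling interval ``T_s`` (20 ms by
default) and clamp their output to ``[u_min, u_max]`` at every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateLimitSpec",
    "TuningResult",
    "controller_error",
    "rate_limit",
    "tune_pi",
    "OnOffController",
    "DualThresholdController",
    "PController",
    "PIController",
]

#: Controller sampling interval (s).
DEFAULT_TS = 0.020
#: Ramp period over which the full parameter range may be traversed (s).
DEFAULT_T_RAMP = 0.250


@dataclass(frozen=True)
class RateLimitSpec:
    """Clinical rate limit on a modulated DBS parameter.

    ``rate_limit`` is expressed in parameter units per second and
    ``u_delta`` is the maximum tolerated change per controller call,
    ``u_delta = T_s * (u_max - u_min) / T_Ramp``.
    """

    u_min: float
    u_max: float
    t_ramp: float = DEFAULT_T_RAMP
    t_s: float = DEFAULT_TS
    rate_limit: float = field(init=False)
    u_delta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.u_max < self.u_min:
            raise ValueError("u_max must be >= u_min")
        if self.t_ramp <= 0 or self.t_s <= 0:
            raise ValueError("t_ramp and t_s must be positive")
        object.__setattr__(
            self, "rate_limit", (self.u_max - self.u_min) / self.t_ramp
        )
        object.__setattr__(self, "u_delta", self.t_s * self.rate_limit)
        if self.rate_limit == 0.0:
            # Degenerate bound pair: controller can never move.
            import warnings

            warnings.warn("u_max == u_min gives a zero rate limit", stacklevel=2)


def rate_limit(
    u_max: float,
    u_min: float = 0.0,
    t_ramp: float = DEFAULT_T_RAMP,
    t_s: float = DEFAULT_TS,
) -> RateLimitSpec:
    """Build the rate-limit specification for a parameter range.

    With the default 250 ms ramp and 20 ms sampling this gives
    0.012 A/s (0.24 mA per call) for a 0–3 mA amplitude range and
    1000 Hz/s for a 0–250 Hz frequency range.
    """
    return RateLimitSpec(u_min=u_min, u_max=u_max, t_ramp=t_ramp, t_s=t_s)


def controller_error(b_measured: float, b_target: float) -> float:
    """Normalized biomarker error ``e = (b_measured - b_target) / b_target``."""
    if b_target <= 0:
        raise ValueError("b_target must be positive")
    return (b_measured - b_target) / b_target


class _BoundedController:
    """Common state for controllers clamping u to [u_min, u_max]."""

    def __init__(self, spec: RateLimitSpec, u0: float | None = None) -> None:
        self.spec = spec
        self.u = spec.u_min if u0 is None else float(np.clip(u0, spec.u_min, spec.u_max))
        self.saturated = False

    def _clamp(self, u: float) -> float:
        lo, hi = self.spec.u_min, self.spec.u_max
        self.saturated = u <= lo or u >= hi
        return float(min(max(u, lo), hi))

    def reset(self, u0: float | None = None) -> None:
        self.u = self.spec.u_min if u0 is None else u0
        self.saturated = False


class OnOffController(_BoundedController):
    """Single-threshold incremental controller.

    The parameter is stepped toward its upper bound by ``u_delta``
    while the beta ARV exceeds the target (e > 0) and toward its lower
    bound while it is below the target (e < 0).
    """

    def update(self, e: float) -> float:
        if e > 0:
            self.u = self._clamp(self.u + self.spec.u_delta)
        elif e < 0:
            self.u = self._clamp(self.u - self.spec.u_delta)
        return self.u


class DualThresholdController(_BoundedController):
    """Target-band incremental controller.

    The error is taken against the upper bound of the target band when
    the biomarker is above it and against the lower bound when below;
    inside the band the error is zero and the parameter is held.
    """

    def __init__(
        self,
        spec: RateLimitSpec,
        b_upper: float,
        b_lower: float,
        u0: float | None = None,
    ) -> None:
        if b_lower > b_upper:
            raise ValueError("b_lower must be <= b_upper")
        super().__init__(spec, u0)
        self.b_upper = b_upper
        self.b_lower = b_lower

    def band_error(self, b_measured: float) -> float:
        if b_measured > self.b_upper:
            return controller_error(b_measured, self.b_upper)
        if b_measured < self.b_lower:
            return controller_error(b_measured, self.b_lower)
        return 0.0

    def update(self, b_measured: float) -> float:
        e = self.band_error(b_measured)
        if e > 0:
            self.u = self._clamp(self.u + self.spec.u_delta)
        elif e < 0:
            self.u = self._clamp(self.u - self.spec.u_delta)
        return self.u


class PIController(_BoundedController):
    """Proportional-integral controller with conditional integration.

    ``u = K_p (e + (1/T_i) ∫ e dτ)`` discretized with rectangular
    accumulation at the sampling interval.  The integral accumulator is
    frozen whenever the pre-clamp output lies beyond a bound and the
    current error would drive it further outward (anti-windup).
    """

    def __init__(
        self,
        spec: RateLimitSpec,
        kp: float,
        ti: float,
        u0: float | None = None,
    ) -> None:
        if kp <= 0 or ti <= 0:
            raise ValueError("kp and ti must be positive")
        super().__init__(spec, u0)
        self.kp = kp
        self.ti = ti
        self.integral = 0.0

    def update(self, e: float) -> float:
        trial = self.integral + e * self.spec.t_s
        u_raw = self.kp * (e + trial / self.ti)
        windup = (u_raw > self.spec.u_max and e > 0) or (
            u_raw < self.spec.u_min and e < 0
        )
        if not windup:
            self.integral = trial
            self.u = self._clamp(u_raw)
        else:
            # Hold the accumulator; output from the frozen integral.
            self.u = self._clamp(self.kp * (e + self.integral / self.ti))
        return self.u

    def reset(self, u0: float | None = None) -> None:
        super().reset(u0)
        self.integral = 0.0


class PController(_BoundedController):
    """Proportional controller, ``u = K_p e`` clamped to the bounds."""

    def __init__(self, spec: RateLimitSpec, kp: float, u0: float | None = None) -> None:
        if kp <= 0:
            raise ValueError("kp must be positive")
        super().__init__(spec, u0)
        self.kp = kp

    def update(self, e: float) -> float:
        self.u = self._clamp(self.kp * e)
        return self.u


@dataclass(frozen=True)
class TuningResult:
    """Outcome of the PI tuning rule."""

    kp: float
    ti: float
    max_e: float
    max_dedt: float


def tune_pi(
    e_trace: np.ndarray,
    spec: RateLimitSpec,
    ti: float = 0.2,
    t_hb: float = 0.1,
    t_pb_min: float = 0.6,
) -> TuningResult:
    """Select PI gains from a DBS-off error recording.

    The integral time constant is taken between the healthy burst
    duration ``t_hb`` and the minimum pathological burst duration
    ``t_pb_min`` (0.2 s by default), and the proportional gain is the
    largest value for which the output slew cannot exceed the rate
    limit on the training trace:

        K_p_max = R_L / (max|de/dt| + max(e)/T_i)

    ``e_trace`` must be sampled at the controller interval ``spec.t_s``.
    """
    if not (t_hb <= ti <= t_pb_min):
        raise ValueError(f"ti must lie in [{t_hb}, {t_pb_min}]")
    e = np.asarray(e_trace, dtype=float)
    if e.size < 2:
        raise ValueError("e_trace needs at least two samples")
    max_e = float(np.max(e))
    max_dedt = float(np.max(np.abs(np.diff(e)))) / spec.t_s
    denom = max_dedt + max_e / ti
    if denom <= 0:
        raise ValueError("flat error trace: tuning rule is undefined")
    return TuningResult(kp=spec.rate_limit / denom, ti=ti, max_e=max_e, max_dedt=max_dedt)
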