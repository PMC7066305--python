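"""Controller algebra, rate limiting, anti-windup and the tuning rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsloop import control


class TestRateLimit:
    def test_amplitude_mode_matches_clinical_rate(self):
        spec = control.rate_limit(3.0, 0.0)
        # 3 mA over 250 ms = 12 mA/s = 0.012 A/s; 0.24 mA per 20 ms call
        assert spec.rate_limit * 1e-3 == pytest.approx(0.012)
        assert spec.u_delta == pytest.approx(0.24)

    def test_frequency_mode(self):
        spec = control.rate_limit(250.0, 0.0)
        assert spec.rate_limit == pytest.approx(1000.0)
        assert spec.u_delta == pytest.approx(20.0)

    def test_degenerate_bounds_flagged(self):
        with pytest.warns(UserWarning):
            spec = control.rate_limit(1.0, 1.0)
        assert spec.rate_limit == 0.0

    def test_identity_u_delta_equals_rl_times_ts(self):
        spec = control.rate_limit(2.0, 0.5, t_ramp=0.1, t_s=0.01)
        assert spec.u_delta == pytest.approx(spec.rate_limit * spec.t_s)


class TestControllerError:
    @pytest.mark.parametrize(
        "b,target,expected", [(1.0, 1.0, 0.0), (2.0, 1.0, 1.0), (0.0, 1.0, -1.0)]
    )
    def test_normalized_error_identities(self, b, target, expected):
        assert control.controller_error(b, target) == pytest.approx(expected)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            control.controller_error(1.0, 0.0)


class TestOnOff:
    def test_step_up_by_rate_limited_increment(self):
        ctl = control.OnOffController(control.rate_limit(3.0), u0=1.0)
        assert ctl.update(0.5) == pytest.approx(1.24)

    def test_clamped_at_upper_bound(self):
        ctl = control.OnOffController(control.rate_limit(3.0), u0=3.0)
        assert ctl.update(1.0) == pytest.approx(3.0)

    def test_clamped_at_lower_bound(self):
        ctl = control.OnOffController(control.rate_limit(3.0), u0=0.0)
        assert ctl.update(-1.0) == pytest.approx(0.0)

    def test_zero_error_holds(self):
        ctl = control.OnOffController(control.rate_limit(3.0), u0=1.0)
        assert ctl.update(0.0) == pytest.approx(1.0)


class TestDualThreshold:
    def setup_method(self):
        self.ctl = control.DualThresholdController(
            control.rate_limit(3.0), b_upper=2.0, b_lower=1.0, u0=1.0
        )

    def test_inside_band_holds(self):
        assert self.ctl.update(1.5) == pytest.approx(1.0)
        assert self.ctl.band_error(1.5) == 0.0

    def test_above_band_steps_up_against_upper_bound(self):
        assert self.ctl.band_error(3.0) == pytest.approx((3.0 - 2.0) / 2.0)
        assert self.ctl.update(3.0) == pytest.approx(1.24)

    def test_below_band_steps_down_against_lower_bound(self):
        assert self.ctl.band_error(0.5) == pytest.approx((0.5 - 1.0) / 1.0)
        assert self.ctl.update(0.5) == pytest.approx(0.76)

    def test_below_band_at_floor_stays_zero(self):
        ctl = control.DualThresholdController(
            control.rate_limit(3.0), b_upper=2.0, b_lower=1.0, u0=0.0
        )
        assert ctl.update(0.5) == 0.0


class TestPI:
    def test_hand_evaluated_first_call(self):
        # K_p (e + I/T_i) with I = e*T_s = 0.02 after one call
        ctl = control.PIController(control.rate_limit(3.0), kp=0.23, ti=0.2)
        assert ctl.update(1.0) == pytest.approx(0.23 * (1.0 + 0.02 / 0.2))

    def test_zero_error_gives_zero_output(self):
        ctl = control.PIController(control.rate_limit(3.0), kp=0.23, ti=0.2)
        for _ in range(10):
            assert ctl.update(0.0) == 0.0

    def test_anti_windup_freezes_integral_at_saturation(self):
        ctl = control.PIController(control.rate_limit(3.0), kp=5.0, ti=0.2)
        for _ in range(50):
            ctl.update(5.0)
        frozen = ctl.integral
        for _ in range(20):
            ctl.update(5.0)
        assert ctl.integral == frozen
        assert ctl.u == pytest.approx(3.0)

    def test_integral_resumes_after_desaturation(self):
        ctl = control.PIController(control.rate_limit(3.0), kp=5.0, ti=0.2)
        for _ in range(10):
            ctl.update(0.2)  # accumulate within bounds
        grown = ctl.integral
        assert grown > 0
        for _ in range(20):
            ctl.update(5.0)  # saturated: frozen
        assert ctl.integral == grown
        ctl.update(-0.1)  # output desaturates: integration resumes
        assert ctl.integral < grown

    def test_p_controller_is_pure_gain(self):
        ctl = control.PController(control.rate_limit(3.0), kp=5.0)
        assert ctl.update(0.3) == pytest.approx(1.5)
        assert ctl.update(-0.5) == 0.0  # clamped at zero


class TestTuning:
    def test_closed_form_kp_max(self):
        # R_L = 0.012 A/s, T_i = 0.2 s, max e = 2, max |de/dt| = 0.04/s
        spec = control.RateLimitSpec(u_min=0.0, u_max=3e-3, t_ramp=0.25, t_s=0.02)
        # ramp with known extremes: max e = 2.0, max slope 0.04 s^-1
        e = np.concatenate([np.linspace(0, 2.0, 2501), np.full(10, 2.0)])
        # max slope = 2/(2500*0.02) = 0.04 per second
        res = control.tune_pi(e, spec, ti=0.2)
        assert res.max_e == pytest.approx(2.0)
        assert res.max_dedt == pytest.approx(0.04, rel=1e-3)
        assert res.kp == pytest.approx(0.012 / (0.04 + 2.0 / 0.2), rel=1e-3)

    def test_homogeneity_doubling_errors_halves_gain(self):
        spec = control.rate_limit(3.0)
        rng = np.random.default_rng(0)
        e = np.abs(rng.standard_normal(500))
        k1 = control.tune_pi(e, spec).kp
        k2 = control.tune_pi(2 * e, spec).kp
        assert k2 == pytest.approx(k1 / 2)

    def test_flat_trace_rejected(self):
        with pytest.raises(ValueError):
            control.tune_pi(np.zeros(100), control.rate_limit(3.0))

    def test_ti_outside_burst_window_rejected(self):
        with pytest.raises(ValueError):
            control.tune_pi(np.ones(100), control.rate_limit(3.0), ti=0.9)

    def test_tuned_gain_respects_rate_limit_on_training_trace(self):
        """Replaying the tuning trace through the PI law never exceeds
        the per-call rate bound."""
        spec = control.rate_limit(3.0)
        rng = np.random.default_rng(1)
        # smooth random error trace
        from scipy.ndimage import uniform_filter1d

        e = uniform_filter1d(rng.standard_normal(2000), 25) * 3.0
        res = control.tune_pi(e, spec)
        ctl = control.PIController(spec, kp=res.kp, ti=res.ti)
        prev = ctl.u
        for ei in e:
            u = ctl.update(ei)
            assert abs(u - prev) <= spec.u_delta + 1e-9
            prev = u


class TestBoundsProperty:
    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=200),
           st.sampled_from(["onoff", "p", "pi"]))
    def test_all_controllers_stay_within_bounds(self, errors, kind):
        spec = control.rate_limit(3.0)
        if kind == "onoff":
            ctl = control.OnOffController(spec)
        elif kind == "p":
            ctl = control.PController(spec, kp=5.0)
        else:
            ctl = control.PIController(spec, kp=0.23, ti=0.2)
        for e in errors:
            u = ctl.update(e)
            assert 0.0 <= u <= 3.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=200))
    def test_incremental_controllers_step_exactly(self, errors):
        """On-off per-call change is exactly 0 or ±u_delta (clamping aside)."""
        spec = control.rate_limit(3.0)
        ctl = control.OnOffController(spec)
        prev = ctl.u
        for e in errors:
            u = ctl.update(e)
            step = abs(u - prev)
            assert step <= spec.u_delta + 1e-12
            interior = spec.u_min + 1e-9 < u < spec.u_max - 1e-9
            if interior and e != 0:
                assert step == pytest.approx(spec.u_delta)
            prev = u

    def test_p_gain_5_violates_amplitude_rate_limit_on_bursty_error(self):
        """The study-selected P amplitude gain exceeds the clinical slew
        bound on bursty inputs (it is not rate-limited by construction)."""
        spec = control.rate_limit(3.0)
        ctl = control.PController(spec, kp=5.0)
        # burst onset: error jumps from 0 to 1 in one 20 ms call
        ctl.update(0.0)
        u1 = ctl.u
        u2 = ctl.update(1.0)
        slew_a_per_s = abs(u2 - u1) * 1e-3 / spec.t_s
        assert slew_a_per_s > 0.012
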