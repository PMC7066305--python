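"""Experiment orchestration: pulse clock, surrogate plant, closed loop,
sweeps, and run persistence."""

import numpy as np
import pytest

from dbsloop import control, experiments, metrics
from dbsloop.experiments import (
    ScenarioConfig,
    SurrogatePlant,
    _PulseClock,
    run_closed_loop,
    run_dbs_off,
    run_pi_gain_sweep,
    run_surrogate_closed_loop,
    surrogate_reference,
)
from dbsloop.network import generate_beta_modulation


class TestPulseClock:
    def test_counts_and_amplitude(self):
        clock = _PulseClock(0.01, 60.0)
        trace = np.concatenate(
            [clock.interval(i * 20.0, 2000, 2.0, 130.0) for i in range(50)]
        )
        active = trace < 0
        onsets = np.flatnonzero(active & ~np.roll(active, 1))
        assert len(onsets) == 130
        assert trace.min() == -2.0

    def test_zero_frequency_silent_and_resumes(self):
        clock = _PulseClock(0.01, 60.0)
        a = clock.interval(0.0, 2000, 2.0, 0.0)
        assert not np.any(a)
        b = clock.interval(20.0, 2000, 2.0, 130.0)
        assert np.any(b < 0)

    def test_phase_continuity_across_calls(self):
        """Inter-pulse intervals are one period even across chunk
        boundaries."""
        clock = _PulseClock(0.01, 60.0)
        trace = np.concatenate(
            [clock.interval(i * 20.0, 2000, 1.0, 90.0) for i in range(25)]
        )
        active = trace < 0
        onsets = np.flatnonzero(active & ~np.roll(active, 1)) * 0.01
        np.testing.assert_allclose(np.diff(onsets), 1e3 / 90.0, atol=0.02)


class TestSurrogatePlant:
    def _plant(self, seed=0):
        mod = generate_beta_modulation(30.0, seed)
        return SurrogatePlant(modulation=mod, seed=seed)

    def test_multiplier_is_one_without_stimulation(self):
        plant = self._plant()
        assert plant.dose_multiplier(0.0, 0.0) == 1.0
        assert plant.dose_multiplier(0.5, 130.0) == 1.0  # below amp threshold
        assert plant.dose_multiplier(3.0, 20.0) == 1.0  # below freq threshold

    def test_multiplier_monotone_beyond_thresholds(self):
        plant = self._plant()
        amps = np.linspace(0, 3, 13)
        mults = [plant.dose_multiplier(a, 130.0) for a in amps]
        assert all(b <= a for a, b in zip(mults, mults[1:]))
        freqs = np.linspace(0, 250, 11)
        mults_f = [plant.dose_multiplier(2.5, f) for f in freqs]
        assert all(b <= a for a, b in zip(mults_f, mults_f[1:]))
        assert all(0 < m <= 1 for m in mults + mults_f)

    def test_arv_tracks_burst_schedule(self):
        plant, b_target, b_lower, arv_off = surrogate_reference(30.0, seed=1)
        assert b_lower <= b_target
        # pathological bursts push the ARV well above target
        assert np.percentile(arv_off, 90) > 2 * b_target

    def test_reset_reproduces_trace(self):
        plant = self._plant(seed=2)
        a = [plant.step(0.0, 0.0) for _ in range(100)]
        plant.reset()
        b = [plant.step(0.0, 0.0) for _ in range(100)]
        np.testing.assert_array_equal(a, b)


class TestSurrogateClosedLoop:
    def test_pi_amplitude_suppresses_error_and_beats_on_off_efficiency(self):
        """Across seeds, tuned PI amplitude control reduces the mean
        rectified error well below the DBS-off reference (100%) and
        achieves a higher suppression efficiency (% beta suppression
        per µW) than the on-off controller."""
        pi_err, pi_eff, oo_eff = [], [], []
        for seed in range(5):
            plant, b_target, b_lower, arv_off = surrogate_reference(30.0, seed)
            e_off = (arv_off - b_target) / b_target
            spec = control.rate_limit(3.0)
            res_pi = run_surrogate_closed_loop(
                plant, control.PIController(spec, 0.23, 0.2), b_target, 30.0
            )
            res_oo = run_surrogate_closed_loop(
                plant, control.OnOffController(spec), b_target, 30.0
            )
            pi_err.append(metrics.mean_rectified_error(res_pi["e"], e_off))
            pi_eff.append(metrics.suppression_efficiency(
                arv_off, res_pi["arv"], float(np.mean(res_pi["power_uw"]))))
            oo_eff.append(metrics.suppression_efficiency(
                arv_off, res_oo["arv"], float(np.mean(res_oo["power_uw"]))))
        assert np.mean(pi_err) < 100.0
        assert np.mean(pi_eff) > np.mean(oo_eff)

    def test_dual_threshold_holds_inside_band(self):
        plant, b_target, b_lower, _ = surrogate_reference(30.0, seed=3)
        spec = control.rate_limit(3.0)
        ctl = control.DualThresholdController(spec, b_target, b_lower)
        res = run_surrogate_closed_loop(plant, ctl, b_target, 30.0)
        assert np.all((res["u"] >= 0) & (res["u"] <= 3.0))
        assert np.any(res["e"] == 0.0)  # band interior visited


class TestPiGainSweep:
    def test_grid_shape_and_slow_corner(self):
        kp = np.array([0.1, 0.75, 3.0])
        ti = np.array([0.05, 0.19, 2.0])
        res = run_pi_gain_sweep(kp, ti, duration_s=20.0, seed=4)
        assert res["error_pct"].shape == (3, 3)
        assert res["power_uw"].shape == (3, 3)
        # long T_i + small K_p reduces error more slowly than the tuned
        # mid-grid point
        assert res["error_pct"][0, 2] > res["error_pct"][1, 1]

    def test_best_point_avoids_long_integral_times(self):
        """The best-performing grid point sits at short-to-intermediate
        integral time constants (T_i <= 0.8 s), not at the slow end."""
        kp = np.array([0.25, 0.75, 1.5])
        ti = np.logspace(np.log10(0.02), np.log10(6.0), 5)
        res = run_pi_gain_sweep(kp, ti, duration_s=20.0, seed=5)
        _, j = np.unravel_index(np.argmin(res["error_pct"]), res["error_pct"].shape)
        assert ti[j] <= 0.8


class TestNetworkClosedLoop:
    @pytest.fixture(scope="class")
    def tiny_cfg(self):
        return ScenarioConfig(n_per_pop=10, warmup_s=0.4, duration_s=1.2, seed=2)

    def test_controller_pinned_at_zero_matches_dbs_off(self, tiny_cfg):
        """An amplitude controller whose output never leaves zero
        produces trajectories identical to the DBS-off run with the
        same seeds (null stimulation)."""
        off = run_dbs_off(tiny_cfg)
        spec_f = experiments.biomarker.BetaFilterSpec(21.0, experiments.LFP_FS)
        with pytest.warns(UserWarning):  # degenerate bounds are flagged
            ctl = control.OnOffController(control.rate_limit(0.0, 0.0))
        run = run_closed_loop(tiny_cfg, ctl, spec_f, b_target=1.0)
        np.testing.assert_array_equal(run.lfp, off.lfp)
        np.testing.assert_array_equal(run.spikes["stn"], off.spikes["stn"])
        assert np.all(run.u == 0.0)

    def test_open_loop_power_matches_closed_form(self, tiny_cfg):
        import dataclasses

        cfg = dataclasses.replace(tiny_cfg, amplitude_ma=2.5, frequency_hz=130.0)
        run = experiments.run_open_loop(cfg)
        numeric = metrics.power_consumed(run.i_dbs)
        assert numeric == pytest.approx(
            metrics.power_consumed_rectangular(2.5, 130.0), rel=0.01
        )


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path):
        from dbsloop.io import load_run, save_run

        cfg = ScenarioConfig(n_per_pop=10, warmup_s=0.2, duration_s=0.6, seed=7)
        run = run_dbs_off(cfg)
        path = tmp_path / "run.h5"
        save_run(run, cfg, path)
        back, cfg2 = load_run(path)
        np.testing.assert_array_equal(back.lfp, run.lfp)
        np.testing.assert_array_equal(back.spikes["gpe"], run.spikes["gpe"])
        assert cfg2 == cfg

    def test_config_yaml_round_trip(self, tmp_path):
        from dbsloop.io import load_config, save_config

        cfg = ScenarioConfig(n_per_pop=12, seed=9, mode="frequency")
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        assert load_config(p) == cfg
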