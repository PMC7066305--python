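"""Wiring statistics, input signals, burst schedule, synapse kinetics."""

import numpy as np
import pytest
from scipy import stats

from dbsloop import network

SIZES = {k: 100 for k in ["ctx", "intn", "stn", "gpe", "gpi", "tha"]}


class TestWiring:
    def test_default_counts_per_postsynaptic_neuron(self):
        w = network.build_network(network.ConnectivitySpec(), SIZES, seed=1)
        for key, count in network.CONNECTION_COUNTS.items():
            proj = w[key]
            per_post = np.bincount(proj.post_idx, minlength=SIZES[key[1]])
            assert np.all(per_post == count), key

    def test_stn_receives_five_cortical_two_pallidal_afferents(self):
        w = network.build_network(network.ConnectivitySpec(), SIZES, seed=2)
        assert np.all(np.bincount(w[("ctx", "stn")].post_idx) == 5)
        assert np.all(np.bincount(w[("gpe", "stn")].post_idx) == 2)

    def test_no_self_connection_in_gpe(self):
        w = network.build_network(network.ConnectivitySpec(), SIZES, seed=3)
        proj = w[("gpe", "gpe")]
        assert np.all(proj.pre_idx != proj.post_idx)

    def test_no_duplicate_edges_within_projection(self):
        w = network.build_network(network.ConnectivitySpec(), SIZES, seed=4)
        for proj in w.values():
            edges = set(zip(proj.pre_idx.tolist(), proj.post_idx.tolist()))
            assert len(edges) == len(proj)

    def test_same_seed_identical_wiring(self):
        a = network.build_network(network.ConnectivitySpec(), SIZES, seed=5)
        b = network.build_network(network.ConnectivitySpec(), SIZES, seed=5)
        for key in a:
            np.testing.assert_array_equal(a[key].pre_idx, b[key].pre_idx)
            np.testing.assert_array_equal(a[key].post_idx, b[key].post_idx)

    def test_reduced_sizes_with_capped_counts(self):
        sizes = {k: 10 for k in SIZES}
        spec = network.ConnectivitySpec(
            counts={k: min(v, 9) for k, v in network.CONNECTION_COUNTS.items()}
        )
        w = network.build_network(spec, sizes, seed=6)
        assert np.all(np.bincount(w[("intn", "ctx")].post_idx) == 9)

    def test_insufficient_population_rejected(self):
        sizes = dict(SIZES, ctx=3)
        with pytest.raises(ValueError):
            network.build_network(network.ConnectivitySpec(), sizes, seed=7)

    def test_edge_table_round_trip(self, tmp_path):
        w = network.build_network(network.ConnectivitySpec(), SIZES, seed=8)
        df = network.wiring_to_frame(w)
        path = tmp_path / "edges.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        # per-projection edge counts conserved through serialization
        for (pre, post), proj in w.items():
            sel = (back.pre_pop == pre) & (back.post_pop == post)
            assert sel.sum() == len(proj)


class TestStriatalDrive:
    def test_zero_rate_empty_trains(self):
        trains = network.striatal_drive(5, 0.0, 10.0, seed=1)
        assert all(t.size == 0 for t in trains)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            network.striatal_drive(5, -1.0, 10.0, seed=1)

    def test_poisson_statistics_at_3hz(self):
        """100 s at 3 Hz: counts within 3 sigma of 300 and exponential
        inter-event intervals (KS test)."""
        trains = network.striatal_drive(20, 3.0, 100.0, seed=2)
        counts = np.array([t.size for t in trains])
        assert np.all(np.abs(counts - 300) < 3 * np.sqrt(300))
        isi = np.concatenate([np.diff(t) for t in trains]) / 1e3
        _, p = stats.kstest(isi, "expon", args=(0, 1 / 3.0))
        assert p > 0.01

    def test_same_seed_identical(self):
        a = network.striatal_drive(3, 3.0, 5.0, seed=9)
        b = network.striatal_drive(3, 3.0, 5.0, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestBetaSchedule:
    def test_interburst_gaps_are_exactly_300ms(self):
        sig = network.generate_beta_modulation(60.0, seed=1)
        gaps = sig.starts[1:] - (sig.starts[:-1] + sig.durations[:-1])
        np.testing.assert_allclose(gaps, 300.0)

    def test_burst_durations_by_label(self):
        sig = network.generate_beta_modulation(300.0, seed=2)
        # ignore the final (possibly truncated) burst
        for dur, label in zip(sig.durations[:-1], sig.labels[:-1]):
            if label == "healthy":
                assert dur == 100.0
            else:
                assert 600.0 <= dur <= 1000.0

    def test_healthy_fraction_converges_to_half(self):
        """Over 10^4 bursts the healthy fraction is 0.5 +/- 0.02."""
        n_bursts = 0
        n_healthy = 0
        seed = 0
        while n_bursts < 10_000:
            sig = network.generate_beta_modulation(600.0, seed=seed)
            n_bursts += len(sig.labels)
            n_healthy += sum(1 for l in sig.labels if l == "healthy")
            seed += 1
        assert n_healthy / n_bursts == pytest.approx(0.5, abs=0.02)

    def test_final_burst_truncated_at_duration(self):
        sig = network.generate_beta_modulation(1.0, seed=3)
        ends = sig.starts + sig.durations
        assert np.all(ends <= 1000.0 + 1e-9)

    def test_half_open_interval_semantics(self):
        sig = network.BetaModulationSignal(
            starts=np.array([100.0]), durations=np.array([50.0]),
            labels=("healthy",), duration_ms=1000.0, seed=0,
        )
        assert sig.is_burst(np.array([100.0]))[0]
        assert sig.is_burst(np.array([149.99]))[0]
        assert not sig.is_burst(np.array([150.0]))[0]
        assert not sig.is_burst(np.array([99.99]))[0]

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            network.generate_beta_modulation(0.0, seed=1)


class TestSynapseBank:
    def _bank(self, n_pre=2, delay=2.0, receptor="ampa", **kw):
        proj = network.Projection(
            "a", "b", np.arange(n_pre), np.zeros(n_pre, dtype=int),
            receptor, 1.0, delay,
        )
        return network.SynapseBank(proj, **kw)

    def test_silence_decays_to_zero(self):
        bank = self._bank()
        bank.r[:] = 0.5
        for k in range(20000):
            bank.step(0.01, (k + 1) * 0.01)
        assert np.all(bank.r < 1e-6)

    def test_delay_semantics_transient_starts_after_delay(self):
        bank = self._bank(delay=2.0)
        bank.deliver_spikes(np.array([0]), t_ms=10.0)
        dt = 0.01
        t = 0.0
        for k in range(int(11.9 / dt)):
            t = (k + 1) * dt
            bank.step(dt, t)
        assert bank.r[0] == 0.0  # t = 11.9 < 10 + 2
        for k in range(50):
            t += dt
            bank.step(dt, t)
        assert bank.r[0] > 0.0  # transient begun at exactly t0 + d

    def test_current_zero_at_reversal_potential(self):
        bank = self._bank(receptor="gabaa")
        bank.r[:] = 0.7
        v = np.full(1, bank.e_rev)
        assert bank.currents(v)[0] == 0.0

    def test_current_sign_excitatory_below_reversal(self):
        bank = self._bank(receptor="ampa")
        bank.r[:] = 0.5
        # V < E_rev: negative (inward/depolarizing) in this convention
        assert bank.currents(np.array([-65.0]))[0] < 0

    def test_r_bounded_in_unit_interval(self):
        bank = self._bank()
        for k in range(3000):
            t = (k + 1) * 0.01
            if k % 100 == 0:
                bank.deliver_spikes(np.array([0, 1]), t)
            bank.step(0.01, t)
            assert np.all(bank.r >= 0) and np.all(bank.r <= 1)

    def test_negative_source_rejected(self):
        bank = self._bank()
        with pytest.raises(KeyError):
            bank.deliver_spikes(np.array([-1]), 0.0)

    def test_depression_attenuates_high_rate_transmission(self):
        """At 130 Hz the depressing synapse transmits far less per spike
        than at 20 Hz (the substrate of STN suppression during DBS)."""
        def peak_r_at(rate_hz):
            bank = self._bank(n_pre=1, delay=1.0, u_dep=0.3, tau_rec=120.0)
            period = 1e3 / rate_hz
            peaks = []
            next_spk = 1.0
            t = 0.0
            for k in range(int(2000 / 0.05)):
                t = (k + 1) * 0.05
                if t >= next_spk:
                    bank.deliver_spikes(np.array([0]), t)
                    next_spk += period
                bank.step(0.05, t)
                peaks.append(bank.r[0])
            return max(peaks[-int(200 / 0.05):])

        assert peak_r_at(130.0) < 0.5 * peak_r_at(20.0)
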