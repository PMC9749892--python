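"""Spike detection, firing-frequency ratios, evoked-potential filtering
and basal metrics, checked against injected ground truth and closed
forms."""

import numpy as np
import pytest

from crylight import ephys, synth
from crylight.ephys import (
    SpikeTrain,
    basal_metrics,
    classify_firing_mode,
    detect_spikes,
    evoked_potential,
    firing_frequency_ratio,
)
from crylight.types import SweepProtocol, VoltageRecording
from conftest import with_ephys

FS = 5000.0


def flat_recording(level_mv=-40.0, n_sweeps=1, fs=FS):
    proto = SweepProtocol(n_sweeps=n_sweeps)
    v = np.full(proto.n_samples(fs), level_mv)
    return VoltageRecording("cell", "g", 8.0, fs, v, proto)


def regular_train(rate_hz, protocol=SweepProtocol()):
    """Stationary spike trains at a fixed rate, one per sweep."""
    times = np.arange(0.5 / rate_hz, protocol.sweep_s, 1.0 / rate_hz)
    return [SpikeTrain(k, times.copy())
            for k in range(protocol.n_sweeps)]


class TestDetectSpikes:
    def test_flat_trace_yields_no_spikes(self):
        trains = detect_spikes(flat_recording())
        assert all(t.spike_times_s.size == 0 for t in trains)

    def test_injected_templates_recovered_within_1ms(self, dm_preset):
        proto = SweepProtocol(n_sweeps=1)
        rec = flat_recording(n_sweeps=1)
        truth = np.array([5.0, 20.0, 40.0, 60.0, 80.0, 100.0, 140.0])
        tpl = np.zeros(int(0.002 * FS))
        tpl[: tpl.size // 2] = np.linspace(0, 60.0, tpl.size // 2)
        tpl[tpl.size // 2:] = np.linspace(60.0, 0, tpl.size - tpl.size // 2)
        v = rec.voltage_mv.copy()
        v += np.random.default_rng(0).normal(0, 1.0, v.size)
        for t in truth:
            i = int(t * FS)
            v[i:i + tpl.size] += tpl
        rec = VoltageRecording("c", "g", 8.0, FS, v, proto)
        det = detect_spikes(rec)[0].spike_times_s
        assert det.size == truth.size
        for t in truth:
            assert np.abs(det - t).min() <= 1e-3 + tpl.size / 2 / FS

    def test_refractory_merges_events_1ms_apart(self):
        proto = SweepProtocol(n_sweeps=1)
        v = np.full(proto.n_samples(FS), -40.0)
        i = int(10.0 * FS)
        for di in (0, int(0.001 * FS)):  # two peaks 1 ms apart
            v[i + di] += 60.0
        rec = VoltageRecording("c", "g", 8.0, FS, v, proto)
        det = detect_spikes(rec, refractory_ms=2.0)[0].spike_times_s
        assert det.size == 1

    def test_sensitivity_and_false_positives_on_default_preset(
            self, dm_preset):
        sv = synth.simulate_voltage(dm_preset, sampling_hz=FS, seed=21)
        trains = detect_spikes(sv.recording)
        tp = fp = n_true = 0
        for det, tru in zip(trains, sv.true_spike_times_s):
            n_true += tru.size
            for t in det.spike_times_s:
                if tru.size and np.abs(tru - t).min() <= 1e-3:
                    tp += 1
                else:
                    fp += 1
        assert tp / n_true >= 0.99
        assert fp / max(tp + fp, 1) <= 0.01

    def test_empty_trace_rejected(self):
        rec = flat_recording()
        rec.voltage_mv = rec.voltage_mv[:0]
        with pytest.raises(ValueError, match="empty"):
            detect_spikes(rec)


class TestFiringFrequencyRatio:
    def test_stationary_train_has_unit_ratios(self):
        summary = firing_frequency_ratio(regular_train(1.0))
        assert summary.ff_ratio == pytest.approx(1.0)
        np.testing.assert_allclose(summary.post_ratios, 1.0)
        np.testing.assert_allclose(summary.baseline_bin_rates_hz, 1.0)

    def test_doubled_stimulus_rate_gives_two(self):
        # one sweep: 1 Hz baseline (10 spikes / 10-s bin), 10 spikes in
        # the 5-s stimulus window = 2 Hz
        base = np.arange(0.5, 50.0, 1.0)
        stim = 50.0 + np.arange(10) * 0.45
        train = [SpikeTrain(0, np.concatenate([base, stim]))]
        proto = SweepProtocol(n_sweeps=1)
        summary = firing_frequency_ratio(train, proto)
        assert summary.baseline_rate_hz == pytest.approx(1.0)
        assert summary.ff_ratio == pytest.approx(2.0)

    def test_zero_baseline_flagged_undefined(self):
        train = [SpikeTrain(0, 50.0 + np.arange(5) * 0.5)]
        summary = firing_frequency_ratio(train, SweepProtocol(n_sweeps=1))
        assert not summary.defined
        assert summary.ff_ratio is None and summary.post_ratios is None

    def test_stationary_poisson_mean_ratio_is_one(self):
        # mean FF ratio over many simulated stationary cells ~ 1
        rng = np.random.default_rng(77)
        proto = SweepProtocol()
        ratios = []
        for _ in range(300):
            trains = [
                SpikeTrain(k, np.sort(rng.uniform(0, proto.sweep_s,
                                                  rng.poisson(150))))
                for k in range(proto.n_sweeps)
            ]
            s = firing_frequency_ratio(trains, proto)
            if s.defined:
                ratios.append(s.ff_ratio)
        m = np.mean(ratios)
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(m - 1.0) < 3 * sem + 1e-3


class TestEvokedPotential:
    def test_constant_trace_maps_to_zero(self):
        ev = evoked_potential(flat_recording(-40.0, n_sweeps=2))
        np.testing.assert_allclose(ev.delta_mv, 0.0, atol=1e-9)

    def test_dc_gain_is_unity_for_plateau_average(self):
        # two noiseless sweeps with +10 and +20 mV plateaus average to +15
        proto = SweepProtocol(n_sweeps=2)
        per = proto.sweep_samples(FS)
        t = np.arange(per) / FS
        plateau = (t >= proto.pre_dark_s + 1.0) & (t >= 60) & (t < 140)
        v = np.full(2 * per, -40.0)
        v[:per][(t >= proto.pre_dark_s)] += 10.0
        v[per:][(t >= proto.pre_dark_s)] += 20.0
        rec = VoltageRecording("c", "g", 8.0, FS, v, proto)
        ev = evoked_potential(rec)
        mid = ev.delta_mv[(ev.time_s >= 70) & (ev.time_s < 140)]
        assert np.allclose(mid, 15.0, rtol=0.02)

    def test_identical_sweeps_average_to_the_sweep(self):
        proto = SweepProtocol(n_sweeps=3)
        per = proto.sweep_samples(FS)
        t = np.arange(per) / FS
        sweep = -40.0 + 5.0 * ((t >= 50) & (t < 120))
        rec = VoltageRecording("c", "g", 8.0, FS, np.tile(sweep, 3),
                               proto)
        ev = evoked_potential(rec)
        mid = ev.delta_mv[(ev.time_s >= 60) & (ev.time_s < 110)]
        assert np.allclose(mid, 5.0, rtol=0.02)

    def test_synthetic_plateau_recovered_with_zero_baseline(self,
                                                            dm_preset):
        preset = with_ephys(dm_preset, depol_amplitude_mv=10.0,
                            tau_on_s=1.0)
        sv = synth.simulate_voltage(preset, sampling_hz=FS, seed=31)
        ev = evoked_potential(sv.recording)
        stim = ev.delta_mv[(ev.time_s >= ev.stim_onset_s)
                           & (ev.time_s < ev.stim_offset_s)]
        assert stim.max() == pytest.approx(10.0, rel=0.10)
        pre = ev.delta_mv[(ev.time_s >= 40.0) & (ev.time_s < 50.0)]
        assert abs(pre.mean()) <= 1e-9 * max(np.abs(ev.delta_mv).max(), 1)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            evoked_potential(flat_recording(), butter_cutoff_hz=3000.0)

    def test_last_60s_window(self):
        ev = evoked_potential(flat_recording(-40.0))
        t, v = ev.last_60s()
        assert t[-1] - t[0] == pytest.approx(60.0, abs=1e-3)


class TestBasalMetrics:
    def test_noiseless_trace_rmp_exact(self):
        basal = basal_metrics(flat_recording(-45.0))
        assert basal.rmp_mv == pytest.approx(-45.0, abs=0.5)
        assert basal.basal_rate_hz == 0.0

    def test_preset_rmp_recovered_within_1mv(self, dm_preset):
        sv = synth.simulate_voltage(dm_preset, sampling_hz=FS, seed=41)
        basal = basal_metrics(sv.recording)
        assert basal.rmp_mv == pytest.approx(-37.0, abs=1.0)

    def test_basal_rate_arithmetic(self):
        # 100 spikes pooled over 5 x 50 s of pre-stimulus time = 0.4 Hz
        rng = np.random.default_rng(3)
        trains = [SpikeTrain(k, np.sort(rng.uniform(0, 50.0, 20)))
                  for k in range(5)]
        rec = flat_recording(-40.0, n_sweeps=5)
        basal = basal_metrics(rec, trains)
        assert basal.basal_rate_hz == pytest.approx(0.4)


class TestFiringMode:
    def test_regular_train_is_tonic(self):
        assert classify_firing_mode(regular_train(1.0)) == "tonic"

    def test_triplets_every_two_seconds_are_burst(self):
        onsets = np.arange(1.0, 49.0, 2.0)
        times = np.sort(np.concatenate(
            [onsets, onsets + 0.05, onsets + 0.10]))
        assert classify_firing_mode([SpikeTrain(0, times)]) == "burst"

    def test_too_few_spikes_unclassified(self):
        t = np.arange(9) * 1.0 + 0.5
        assert classify_firing_mode([SpikeTrain(0, t)]) == "unclassified"
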