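"""Spike detection, mode segmentation, toggle statistics and presets."""

import numpy as np
import pytest

from purksim.engine import Trace
from purksim.protocols_analysis import (AnalysisError, complex_spike_pauses,
                                        detect_complex_spikes, detect_spikes,
                                        firing_epochs, preset, segment_modes,
                                        toggle_statistics, tonic_frequency)


def _trace_from_v(t, v):
    n = len(t)
    z = np.zeros((n, 1))
    return Trace(t=t, v=v.reshape(-1, 1), ca=z, y=z, w=z, r=z,
                 na_i=np.zeros(n), i_pump=np.zeros(n), gsk_live=np.zeros(n),
                 soma_spikes=np.zeros(0), dend_spikes=np.zeros(0))


class TestDetectSpikes:
    def test_flat_trace_yields_none(self):
        t = np.arange(0, 1000.0, 0.1)
        tr = _trace_from_v(t, np.full(len(t), -65.0))
        assert len(detect_spikes(tr)) == 0

    def test_synthetic_waveforms_recovered_within_tenth_ms(self):
        t = np.arange(0, 10000.0, 0.05)
        v = np.full(len(t), -65.0)
        truth = 50.0 + 100.0 * np.arange(100)
        for ts in truth:
            sel = np.abs(t - ts) < 2.0
            v[sel] = np.maximum(v[sel], -65.0 + 95.0
                                * np.exp(-((t[sel] - ts) / 0.5) ** 2))
        got = detect_spikes(_trace_from_v(t, v))
        assert len(got) == 100
        assert np.max(np.abs(got - truth)) <= 0.1

    def test_subthreshold_oscillation_ignored(self):
        t = np.arange(0, 2000.0, 0.1)
        v = -65.0 + 35.0 * np.sin(2 * np.pi * t / 100.0)   # peaks at -30
        assert len(detect_spikes(_trace_from_v(t, v))) == 0

    def test_missing_channel_raises(self):
        t = np.arange(0, 10.0, 0.1)
        tr = _trace_from_v(t, np.full(len(t), -65.0))
        with pytest.raises(AnalysisError):
            detect_spikes(tr, compartment=5)


class TestComplexSpikes:
    def test_no_cf_events_no_complex_spikes(self):
        assert len(detect_complex_spikes(np.array([1.0, 5.0]),
                                         np.zeros(0))) == 0

    def test_cf_gating_excludes_intrinsic_bursts(self):
        spikes = np.array([500.0, 503.0, 507.0,          # intrinsic burst
                           1001.0, 1004.0, 1008.0])      # CF-evoked
        cf = np.array([1000.0])
        dend = np.array([1000.5])
        got = detect_complex_spikes(spikes, cf, dend)
        assert np.allclose(got, [1001.0])

    def test_requires_multiple_spikelets(self):
        spikes = np.array([1001.0])                       # lone spike
        assert len(detect_complex_spikes(spikes, np.array([1000.0]),
                                         np.array([1000.5]))) == 0

    def test_pause_measurement(self):
        spikes = np.array([1001.0, 1004.0, 1030.0])
        pauses = complex_spike_pauses(spikes, np.array([1001.0]))
        assert pauses[0] == pytest.approx(26.0)


class TestSegmentation:
    def test_pure_tonic(self):
        spikes = np.arange(0.0, 5000.0, 10.0)
        seg = segment_modes(spikes, [], (0.0, 5000.0))
        assert seg.labels() == ["tonic"]

    def test_constructed_three_mode_fixture(self):
        """5 s tonic, 3 s of Ca-spike-paired bursting, 10 s silence."""
        tonic = np.arange(0.0, 5000.0, 10.0)
        burst = np.arange(5000.0, 8000.0, 25.0)
        spikes = np.concatenate([tonic, burst])
        ca_spikes = np.arange(5000.0, 8001.0, 100.0)
        seg = segment_modes(spikes, ca_spikes, (0.0, 18000.0))
        assert seg.labels() == ["tonic", "burst", "quiescent"]
        # boundaries land within one burst-association window (50 ms) plus
        # half an inter-spike interval of the construction marks
        s, e = seg.of_label("tonic")[0]
        assert (e - s) == pytest.approx(5000.0, abs=100.0)
        s, e = seg.of_label("burst")[0]
        assert (e - s) == pytest.approx(3000.0, abs=100.0)
        s, e = seg.of_label("quiescent")[0]
        assert (e - s) == pytest.approx(10000.0, abs=100.0)

    def test_idempotent_under_time_shift(self):
        spikes = np.concatenate([np.arange(0.0, 3000.0, 10.0),
                                 np.arange(4000.0, 6000.0, 10.0)])
        seg0 = segment_modes(spikes, [], (0.0, 6000.0))
        seg1 = segment_modes(spikes + 1.0, [], (1.0, 6001.0))
        assert seg0.labels() == seg1.labels()
        for (s0, e0, _), (s1, e1, _) in zip(seg0.intervals, seg1.intervals):
            assert s1 - s0 == pytest.approx(1.0)
            assert e1 - e0 == pytest.approx(1.0)

    def test_firing_epochs_and_repeats(self):
        spikes = np.concatenate([np.arange(0.0, 4000.0, 10.0),
                                 np.arange(9000.0, 13000.0, 10.0),
                                 np.arange(18000.0, 22000.0, 10.0)])
        seg = segment_modes(spikes, [], (0.0, 22000.0))
        firing, repeats = firing_epochs(seg)
        assert len(firing) == 3
        # only quiescent-to-firing transitions seed a repeat measurement,
        # so the first epoch (at the window edge) contributes no start
        assert repeats == pytest.approx([9000.0], abs=20.0)


class TestTonicFrequency:
    def test_single_interval(self):
        spikes = np.arange(0.0, 1000.0, 10.0)   # 100 spikes over 990 ms
        seg = segment_modes(spikes, [], (0.0, 1000.0))
        assert tonic_frequency(seg, spikes) == pytest.approx(101.0, abs=1.5)

    def test_pooling_across_intervals(self):
        a = np.arange(0.0, 1000.0, 1000.0 / 90)
        b = np.arange(2000.0, 3000.0, 1000.0 / 110)
        spikes = np.concatenate([a, b])
        seg = segment_modes(spikes, [], (0.0, 3000.0))
        # 200 spikes over ~2 s pooled
        assert tonic_frequency(seg, spikes) == pytest.approx(100.0, rel=0.05)

    def test_no_tonic_interval_raises(self):
        seg = segment_modes([], [], (0.0, 1000.0))
        with pytest.raises(AnalysisError):
            tonic_frequency(seg, [])


class TestToggleStatistics:
    def test_strict_alternation(self):
        cf = np.arange(0.0, 20000.0, 1000.0)
        spikes = []
        for i in range(0, 20, 2):       # fire only in even intervals
            spikes.extend(np.arange(i * 1000.0 + 50, i * 1000.0 + 950, 10.0))
        ts = toggle_statistics(np.array(spikes), cf)
        assert ts.flip_fraction == 1.0
        assert np.allclose(ts.up_durations_ms, 1000.0)
        assert np.allclose(ts.down_durations_ms, 1000.0)
        assert len(ts.pump_silences) == 0

    def test_continuous_firing_never_flips(self):
        cf = np.arange(0.0, 10000.0, 1000.0)
        spikes = np.arange(0.0, 10000.0, 10.0)
        ts = toggle_statistics(spikes, cf)
        assert ts.flip_fraction == 0.0
        assert len(ts.down_durations_ms) == 0

    def test_pump_silence_flagged(self):
        """One 12 s silence among 1 s alternations is flagged exactly
        once and excluded from the flip statistics."""
        cf = np.arange(0.0, 30000.0, 1000.0)
        spikes = []
        for i in range(30):
            if 10 <= i < 22:            # 12 s silent block
                continue
            if i % 2 == 0:
                spikes.extend(np.arange(i * 1000.0 + 50,
                                        i * 1000.0 + 950, 10.0))
        ts = toggle_statistics(np.array(spikes), cf)
        assert len(ts.pump_silences) == 1
        a, b = ts.pump_silences[0]
        assert (b - a) == pytest.approx(12000.0, abs=1001.0)


def test_preset_catalog():
    p = preset("cf_toggle")
    assert p.cf_on and p.g_sk == 0.72
    p = preset("cf_pause")
    assert p.g_sk == 0.62
    p = preset("ih_mask")
    assert p.g_ih_soma == 5.0
    p = preset("trimodal_k02")
    assert p.k == 0.2
    with pytest.raises(AnalysisError):
        preset("nope")
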