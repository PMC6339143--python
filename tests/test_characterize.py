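import numpy as np
import pytest

from oncoephys import (ASYNCHRONOUS, SYNCHRONOUS, DetectionConfig,
                       RecordingConfig, RegimeSegment, SpikeEvent, SyncParams,
                       WaveParams, detect_spikes, electrode_diameter_mm,
                       estimate_wave_speed, pair_biphasic, segment_regimes,
                       simulate_recording, spike_statistics)
from oncoephys.detect import BIPHASIC, UNIPOLAR


def unipolar(t, amp=-100.0):
    return SpikeEvent(peak_time_s=t, amplitude_pa=amp, width_s=0.1,
                      polarity=1 if amp > 0 else -1, kind=UNIPOLAR)


def pair(t, sep=0.3, amp=150.0, pair_id=0):
    a = SpikeEvent(peak_time_s=t, amplitude_pa=amp, width_s=0.1, polarity=1,
                   kind=BIPHASIC, pair_id=pair_id)
    b = SpikeEvent(peak_time_s=t + sep, amplitude_pa=-amp, width_s=0.1,
                   polarity=-1, kind=BIPHASIC, pair_id=pair_id)
    return [a, b]


class TestSegmentRegimes:
    def test_strictly_periodic_events_are_synchronous(self):
        events = [unipolar(t, amp=150.0) for t in np.arange(1.0, 99.0, 2.0)]
        segs = segment_regimes(events, (0.0, 100.0), window_s=25.0,
                               rate_cutoff_hz=0.25, cv_cutoff=0.5)
        assert [s.label for s in segs] == [SYNCHRONOUS]
        assert segs[0].spike_count == len(events)

    def test_sparse_events_are_asynchronous(self):
        events = [unipolar(t) for t in (10.0, 130.0, 320.0, 410.0, 570.0)]
        segs = segment_regimes(events, (0.0, 600.0))
        assert [s.label for s in segs] == [ASYNCHRONOUS]

    def test_no_events_gives_single_asynchronous_segment(self):
        segs = segment_regimes([], (0.0, 500.0))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.label, seg.start_s, seg.end_s, seg.spike_count) == \
            (ASYNCHRONOUS, 0.0, 500.0, 0)

    def test_segments_tile_span_without_overlap(self):
        rec, _ = simulate_recording(
            RecordingConfig(duration_s=600.0, seed=3),
            [(ASYNCHRONOUS, 300.0), (SYNCHRONOUS, 300.0)])
        cfg = DetectionConfig()
        events = pair_biphasic(detect_spikes(rec, cfg), cfg)
        segs = segment_regimes(events, (0.0, 600.0))
        assert segs[0].start_s == 0.0 and segs[-1].end_s == 600.0
        for a, b in zip(segs, segs[1:]):
            assert a.end_s == b.start_s
            assert a.label != b.label  # adjacent same labels are merged


class TestSpikeStatistics:
    def test_isi_mass_lands_in_the_two_to_three_second_bin(self):
        events = []
        t = 0.0
        for k, isi in enumerate([2.1, 2.4, 2.9, 2.2, 2.6, 2.8, 2.3, 2.5,
                                 2.7]):
            events += pair(t, pair_id=k)
            t += isi
        events += pair(t, pair_id=9)
        seg = RegimeSegment(0.0, 30.0, SYNCHRONOUS, 10, 10 / 30.0)
        stats = spike_statistics(events, [seg])[SYNCHRONOUS]
        hist = stats.isi_histogram
        assert hist.total == 9
        assert hist.modal_bin() == (2.0, 3.0)
        k = int(np.flatnonzero(hist.edges == 2.0)[0])
        assert hist.counts[k] == 9

    def test_unipolar_fraction_over_asynchronous_events(self):
        events = [unipolar(float(t)) for t in range(1, 8)]
        events += pair(10.0, pair_id=0) + [
            SpikeEvent(peak_time_s=12.0, amplitude_pa=100.0, width_s=0.1,
                       polarity=1, kind=BIPHASIC, pair_id=1)]
        seg = RegimeSegment(0.0, 20.0, ASYNCHRONOUS, 9, 0.45)
        stats = spike_statistics(events, [seg])[ASYNCHRONOUS]
        assert stats.unipolar_fraction == pytest.approx(0.7)

    def test_empty_events_give_zero_histograms(self):
        seg = RegimeSegment(0.0, 100.0, ASYNCHRONOUS, 0, 0.0)
        stats = spike_statistics([], [seg])[ASYNCHRONOUS]
        assert stats.amplitude_histogram.total == 0
        assert stats.width_histogram.total == 0
        assert stats.isi_histogram.total == 0
        assert stats.mean_rate_hz == 0.0

    def test_histogram_mass_is_conserved(self):
        rec, _ = simulate_recording(
            RecordingConfig(duration_s=600.0, seed=21),
            [(ASYNCHRONOUS, 300.0), (SYNCHRONOUS, 300.0)])
        cfg = DetectionConfig()
        events = pair_biphasic(detect_spikes(rec, cfg), cfg)
        segs = segment_regimes(events, (0.0, 600.0))
        stats = spike_statistics(events, segs)
        total = sum(s.n_events for s in stats.values())
        assert total == len(events)
        for s in stats.values():
            assert s.amplitude_histogram.total == s.n_events
            assert s.width_histogram.total == s.n_events


@pytest.fixture(scope="module")
def sync_run():
    sp = SyncParams()
    rec, _ = simulate_recording(RecordingConfig(duration_s=600.0, seed=1),
                                [(SYNCHRONOUS, 600.0)], sync_params=sp)
    cfg = DetectionConfig()
    events = pair_biphasic(detect_spikes(rec, cfg), cfg)
    segs = segment_regimes(events, (0.0, 600.0))
    return sp, events, segs


class TestGeneratorRecovery:
    """The characterization stage recovers the generator's parameters."""

    def test_whole_run_is_labelled_synchronous(self, sync_run):
        _, _, segs = sync_run
        assert [s.label for s in segs] == [SYNCHRONOUS]

    def test_median_amplitude_within_ten_percent(self, sync_run):
        sp, events, _ = sync_run
        med = np.median([abs(e.amplitude_pa) for e in events])
        assert med == pytest.approx(sp.amplitude_pa, rel=0.10)

    def test_rate_within_twenty_percent_of_reciprocal_mean_isi(self, sync_run):
        sp, events, segs = sync_run
        stats = spike_statistics(events, segs)[SYNCHRONOUS]
        assert stats.mean_rate_hz == pytest.approx(1.0 / sp.mean_isi_s,
                                                   rel=0.20)

    def test_modal_isi_bin_contains_mean_isi(self, sync_run):
        sp, events, segs = sync_run
        stats = spike_statistics(events, segs)[SYNCHRONOUS]
        lo, hi = stats.isi_histogram.modal_bin()
        assert lo <= sp.mean_isi_s < hi

    def test_count_disparity_matches_tenfold_within_factor_two(self):
        rec, _ = simulate_recording(
            RecordingConfig(duration_s=1200.0, seed=1),
            [(ASYNCHRONOUS, 600.0), (SYNCHRONOUS, 600.0)])
        cfg = DetectionConfig()
        events = pair_biphasic(detect_spikes(rec, cfg), cfg)
        segs = segment_regimes(events, (0.0, 1200.0))
        counts = {ASYNCHRONOUS: 0, SYNCHRONOUS: 0}
        for s in segs:
            counts[s.label] += s.spike_count
        ratio = counts[SYNCHRONOUS] / counts[ASYNCHRONOUS]
        assert 5.0 <= ratio <= 20.0


class TestWaveSpeed:
    def test_two_second_separation_on_one_millimetre_gives_500(self):
        events = pair(10.0, sep=2.0, pair_id=0)
        res = estimate_wave_speed(events, diameter_mm=1.0)
        assert res.median_um_s == pytest.approx(500.0)

    def test_printed_fast_separation(self):
        events = pair(10.0, sep=0.7, pair_id=0)
        res = estimate_wave_speed(events, diameter_mm=1.0)
        assert res.median_um_s == pytest.approx(1000.0 / 0.7, rel=1e-6)

    def test_doubling_diameter_doubles_every_speed(self):
        events = pair(1.0, sep=0.5, pair_id=0) + pair(5.0, sep=1.0, pair_id=1)
        one = estimate_wave_speed(events, diameter_mm=1.0)
        two = estimate_wave_speed(events, diameter_mm=2.0)
        np.testing.assert_allclose(two.speeds_um_s, 2 * one.speeds_um_s)

    def test_no_pairs_is_flagged_not_fatal(self):
        res = estimate_wave_speed([unipolar(1.0)])
        assert res.empty and res.n_pairs == 0

    def test_default_diameter_from_unit_area(self):
        assert electrode_diameter_mm(1.0) == pytest.approx(1.1284, abs=1e-4)

    @pytest.mark.parametrize("speed", [300.0, 500.0, 1000.0])
    def test_simulated_wave_speed_recovered_within_ten_percent(self, speed):
        wave = WaveParams(wave_speed_um_s=speed)
        sp = SyncParams(mean_isi_s=6.0, isi_jitter_sd_s=0.6, isi_low_s=4.5,
                        isi_high_s=10.0)
        rec, _ = simulate_recording(
            RecordingConfig(duration_s=600.0, seed=int(speed)),
            [(SYNCHRONOUS, 600.0)], sync_params=sp, wave=wave)
        cfg = DetectionConfig(pairing_window_s=4.5)
        events = pair_biphasic(detect_spikes(rec, cfg), cfg)
        res = estimate_wave_speed(events, diameter_mm=wave.diameter_mm)
        assert res.n_pairs > 50
        assert res.median_um_s == pytest.approx(speed, rel=0.10)
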