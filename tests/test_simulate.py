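import numpy as np
import pytest

from oncoephys import (ASYNCHRONOUS, SYNCHRONOUS, AsyncParams,
                       InhibitionProtocol, InputError, ParameterError,
                       RecordingConfig, ResolutionError, SyncParams,
                       WaveParams, biphasic_template, simulate_baseline,
                       simulate_inhibition_experiment, simulate_recording)


class TestBaseline:
    def test_default_noise_stays_below_one_picoampere(self):
        for seed in (1, 2, 3):
            rec = simulate_baseline(RecordingConfig(duration_s=60.0,
                                                    seed=seed))
            assert np.abs(rec.values_pa).max() < 1.0

    def test_zero_noise_gives_identically_zero_trace(self):
        rec = simulate_baseline(RecordingConfig(duration_s=10.0, seed=0,
                                                baseline_noise_pp_pa=0.0))
        assert not rec.values.any()

    def test_same_seed_reproduces_trace(self):
        a = simulate_baseline(RecordingConfig(duration_s=5.0, seed=42))
        b = simulate_baseline(RecordingConfig(duration_s=5.0, seed=42))
        np.testing.assert_array_equal(a.values, b.values)


class TestBiphasicTemplate:
    def peak_separation(self, ts):
        i_pos = int(np.argmax(ts.values))
        i_neg = int(np.argmin(ts.values))
        return (i_neg - i_pos) * ts.dt

    def test_wave_transit_sets_lobe_separation(self):
        # 1-mm diameter crossed at 500 µm/s: lobes 2.0 s apart
        wave = WaveParams(wave_speed_um_s=500.0, electrode_area_mm2=None,
                          electrode_diameter_mm=1.0)
        ts = biphasic_template(wave=wave, sync=SyncParams(mean_isi_s=4.0))
        assert self.peak_separation(ts) == pytest.approx(2.0, abs=2e-3)

    def test_doubling_speed_halves_separation(self):
        seps = []
        for speed in (400.0, 800.0):
            wave = WaveParams(wave_speed_um_s=speed, electrode_area_mm2=None,
                              electrode_diameter_mm=1.0)
            seps.append(self.peak_separation(
                biphasic_template(wave=wave, sync=SyncParams(mean_isi_s=4.0))))
        assert seps[0] == pytest.approx(2 * seps[1], abs=2e-3)

    def test_sync_separation_used_without_wave_params(self):
        ts = biphasic_template(sync=SyncParams(biphasic_separation_s=0.3))
        assert self.peak_separation(ts) == pytest.approx(0.3, abs=2e-3)

    def test_waveform_is_charge_balanced(self):
        ts = biphasic_template()
        lobe_area = ts.values[ts.values > 0].sum()
        assert abs(ts.values.sum()) < 0.01 * lobe_area

    def test_equal_opposite_lobe_magnitudes(self):
        ts = biphasic_template(sync=SyncParams(amplitude_pa=150.0))
        assert ts.values_pa.max() == pytest.approx(150.0, rel=1e-3)
        assert ts.values_pa.min() == pytest.approx(-150.0, rel=1e-3)

    def test_unresolvable_separation_rejected(self):
        with pytest.raises(ResolutionError):
            biphasic_template(sync=SyncParams(biphasic_separation_s=0.3),
                              sampling_rate_hz=5.0)


class TestSimulateRecording:
    def test_async_event_count_matches_poisson_expectation(self):
        cfg = RecordingConfig(duration_s=600.0, seed=11)
        _, gt = simulate_recording(cfg, [(ASYNCHRONOUS, 600.0)],
                                   AsyncParams(event_rate_hz=0.05))
        expected = 0.05 * 600
        assert abs(len(gt) - expected) <= 3 * np.sqrt(expected)
        assert (gt.events["kind"] == "unipolar").all()

    def test_sync_event_count_tracks_mean_isi(self):
        cfg = RecordingConfig(duration_s=100.0, seed=5)
        sp = SyncParams(mean_isi_s=2.0, isi_jitter_sd_s=0.0)
        _, gt = simulate_recording(cfg, [(SYNCHRONOUS, 100.0)],
                                   sync_params=sp)
        assert abs(len(gt) - 50) <= 10
        assert (gt.events["kind"] == "biphasic").all()

    def test_empty_schedule_rejected(self):
        cfg = RecordingConfig(duration_s=10.0)
        with pytest.raises(InputError):
            simulate_recording(cfg, [])

    def test_schedule_must_fill_duration(self):
        cfg = RecordingConfig(duration_s=100.0)
        with pytest.raises(InputError):
            simulate_recording(cfg, [(ASYNCHRONOUS, 60.0)])

    def test_unknown_regime_label_rejected(self):
        cfg = RecordingConfig(duration_s=10.0)
        with pytest.raises(InputError):
            simulate_recording(cfg, [("mystery", 10.0)])

    def test_reproducible_from_seed(self):
        cfg = RecordingConfig(duration_s=120.0, seed=9)
        sched = [(ASYNCHRONOUS, 60.0), (SYNCHRONOUS, 60.0)]
        (rec_a, gt_a) = simulate_recording(cfg, sched)
        (rec_b, gt_b) = simulate_recording(cfg, sched)
        np.testing.assert_array_equal(rec_a.values, rec_b.values)
        assert gt_a.events.equals(gt_b.events)

    def test_ground_truth_sorted_and_inside_span(self):
        cfg = RecordingConfig(duration_s=300.0, seed=2)
        _, gt = simulate_recording(
            cfg, [(SYNCHRONOUS, 150.0), (ASYNCHRONOUS, 150.0)])
        t = gt.events["time_s"].to_numpy()
        assert (np.diff(t) >= 0).all()
        assert t.min() > 0 and t.max() < 300.0

    def test_inserted_lobe_peaks_match_drawn_amplitudes(self, quiet_config):
        rec, gt = simulate_recording(
            quiet_config, [(SYNCHRONOUS, 600.0)], sync_params=SyncParams())
        # a few far-tail (≥3σ) support touches are fine; they cannot move
        # a neighbour's peak by more than a fraction of a pA
        assert gt.overlap_count <= 5
        x = rec.values_pa
        for row in gt.events.itertuples(index=False):
            k = int(round(row.time_s / rec.dt))
            lo, hi = max(0, k - 5), k + 5
            assert np.abs(x[lo:hi]).max() == pytest.approx(
                row.amplitude_pa, rel=0.02)

    def test_wave_params_set_groundtruth_pairing_geometry(self, quiet_config):
        wave = WaveParams(wave_speed_um_s=1000.0)
        rec, gt = simulate_recording(quiet_config, [(SYNCHRONOUS, 600.0)],
                                     wave=wave)
        # positive and negative extrema around an event sit sep apart
        sep = wave.separation_s
        row = gt.events.iloc[0]
        k = int(round(row.time_s / rec.dt))
        k2 = int(round((row.time_s + sep) / rec.dt))
        assert rec.values_pa[k] == pytest.approx(row.amplitude_pa, rel=0.02)
        assert rec.values_pa[k2] == pytest.approx(-row.amplitude_pa, rel=0.02)

    def test_low_sampling_rate_rejected(self):
        cfg = RecordingConfig(duration_s=10.0, sampling_rate_hz=100.0)
        with pytest.raises(ParameterError):
            simulate_recording(cfg, [(ASYNCHRONOUS, 10.0)],
                               AsyncParams(width_low_s=0.02))


class TestAsyncWidthCalibration:
    def test_about_80_percent_of_widths_fall_in_30_to_200_ms(self):
        rng = np.random.default_rng(0)
        p = AsyncParams()
        draws = np.exp(rng.uniform(np.log(p.width_low_s),
                                   np.log(p.width_high_s), 5000))
        frac = ((draws >= 0.03) & (draws <= 0.2)).mean()
        assert 0.75 < frac < 0.85


class TestWaveParams:
    def test_diameter_derived_from_area(self):
        assert WaveParams().diameter_mm == pytest.approx(1.1284, abs=1e-4)

    def test_inconsistent_diameter_and_area_rejected(self):
        with pytest.raises(ParameterError):
            WaveParams(electrode_area_mm2=1.0, electrode_diameter_mm=1.0)


class TestInhibitionExperiment:
    def make(self, seed, **kw):
        prot = InhibitionProtocol(**kw)
        cfg = RecordingConfig(duration_s=prot.total_duration_s, seed=seed)
        return simulate_inhibition_experiment(cfg, prot)

    def test_block_phase_stays_below_five_picoamperes(self):
        rec, _, phases = self.make(seed=1)
        during = next(p for p in phases if p.label == "during")
        sub = rec.slice_time(during.start_s, during.end_s)
        assert np.abs(sub.values_pa).max() < 5.0

    def test_zero_residual_and_noise_gives_flat_block(self):
        prot = InhibitionProtocol(residual_amplitude_pa=0.0)
        cfg = RecordingConfig(duration_s=prot.total_duration_s, seed=1,
                              baseline_noise_pp_pa=0.0)
        rec, _, phases = simulate_inhibition_experiment(cfg, prot)
        during = next(p for p in phases if p.label == "during")
        sub = rec.slice_time(during.start_s, during.end_s)
        assert not sub.values.any()

    def test_pre_and_post_phases_share_event_statistics(self):
        rec, gt, phases = self.make(seed=4, pre_duration_s=600.0,
                                    post_duration_s=600.0)
        df = gt.events
        t_before = df[df["regime"] != "blocked"]["time_s"]
        before = (t_before < 600.0).sum()
        after = (t_before >= phases[2].start_s).sum()
        assert abs(after - before) <= 0.2 * before

    def test_phase_annotations_tile_the_recording(self):
        rec, _, phases = self.make(seed=2)
        assert [p.label for p in phases] == ["before", "during", "after"]
        assert phases[0].start_s == 0.0
        assert phases[2].end_s == pytest.approx(rec.duration)
        for a, b in zip(phases, phases[1:]):
            assert a.end_s == b.start_s

    def test_protocol_must_match_recording_duration(self):
        with pytest.raises(InputError):
            simulate_inhibition_experiment(
                RecordingConfig(duration_s=100.0), InhibitionProtocol())
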