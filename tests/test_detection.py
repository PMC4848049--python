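"""Filtering, QRS referencing, beat assessment, and the 4-consecutive rule."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import make_window, synthetic_map_window
from mapgap.config import DetectorConfig, SimulationConfig
from mapgap.detection import (
    BeatAssessment,
    analyze_trace,
    assess_beat,
    bandpass_filter,
    detect_qrs,
    find_consistent_run,
    qrs_onsets,
    segment_beats,
)
from mapgap.errors import NoBeatsError, WindowTooShortError
from mapgap.synth import SitePhysiology, constant_profile, draw_site_physiology, generate_trace
from mapgap.trace import Trace


def make_trace(map_mv, ecg_mv=None, fs=1000.0):
    n = len(map_mv)
    return Trace(
        sample_rate=fs,
        time=np.arange(n) / fs,
        map_mv=np.asarray(map_mv, dtype=float),
        ecg_mv=np.zeros(n) if ecg_mv is None else np.asarray(ecg_mv, dtype=float),
    )


def ecg_with_r_peaks(r_times, fs=1000.0, duration=None, amp=1.0):
    duration = duration or (max(r_times) + 0.5)
    n = int(duration * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for r in r_times:
        x += amp * np.exp(-0.5 * ((t - r) / 0.008) ** 2)
    return x


class TestBandpass:
    def test_in_band_tone_preserved(self):
        fs = 1000.0
        t = np.arange(int(5 * fs)) / fs
        tone = np.sin(2 * np.pi * 60 * t)
        out = bandpass_filter(make_trace(tone, fs=fs))
        core = slice(int(fs), int(4 * fs))
        ratio = np.sqrt(np.mean(out.map_mv[core] ** 2) / np.mean(tone[core] ** 2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_dc_offset_rejected(self):
        out = bandpass_filter(make_trace(np.full(5000, 10.0)))
        assert np.max(np.abs(out.map_mv[1000:-1000])) < 0.5

    def test_out_of_band_tone_attenuated_like_analytic_response(self):
        """A 500 Hz tone at 2 kHz sampling is attenuated by at least 20 dB,
        and the measured attenuation matches |H(f)|^2 of the designed filter
        (zero-phase filtering applies the response twice)."""
        fs, f0 = 2000.0, 500.0
        cfg = DetectorConfig()
        t = np.arange(int(6 * fs)) / fs
        tone = np.sin(2 * np.pi * f0 * t)
        out = bandpass_filter(make_trace(tone, fs=fs), cfg)
        core = slice(int(fs), int(5 * fs))
        measured = np.sqrt(np.mean(out.map_mv[core] ** 2) / np.mean(tone[core] ** 2))
        from mapgap.detection import corrected_band

        b, a = sps.butter(2, corrected_band(cfg, fs), btype="bandpass", fs=fs)
        _, h = sps.freqz(b, a, worN=[f0], fs=fs)
        analytic = np.abs(h[0]) ** 2  # zero-phase filtering applies |H| twice
        assert measured < 10 ** (-20 / 20)
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(make_trace(np.zeros(1000), fs=500.0),
                            DetectorConfig(band_high=400.0))

    def test_force_channel_untouched(self, sim_config):
        site = SitePhysiology("s", False)
        tr = generate_trace(site, constant_profile(5.0, 6, sim_config), sim_config)
        tr = tr.with_force(np.full(len(tr), 5.0))
        out = bandpass_filter(tr)
        np.testing.assert_array_equal(out.force_g, tr.force_g)


class TestDetectQRS:
    def test_regular_rhythm_peak_times(self, sim_config):
        site = SitePhysiology("s", False)
        trace = generate_trace(site, constant_profile(3.0, 10, sim_config), sim_config)
        filt = bandpass_filter(trace)
        qrs = detect_qrs(filt)
        truth = trace.truth.qrs_times
        assert len(qrs) == len(truth)
        assert np.max(np.abs(qrs - truth)) < 0.010
        rr = np.diff(qrs)
        assert np.allclose(rr, 60.0 / sim_config.heart_rate_bpm, atol=0.010)

    def test_single_beat_is_an_error(self):
        x = ecg_with_r_peaks([0.5], duration=1.2)
        with pytest.raises(NoBeatsError):
            detect_qrs(make_trace(np.zeros_like(x), ecg_mv=x))

    def test_flatline_is_an_error(self):
        with pytest.raises(NoBeatsError):
            detect_qrs(make_trace(np.zeros(4000), ecg_mv=np.zeros(4000)))

    def test_drifting_rate_matched_one_to_one(self):
        """Heart rate drifting 60→100 bpm: every ground-truth beat is
        recovered, matched by nearest-time brute force."""
        rr = 60.0 / np.linspace(60, 100, 40)
        r_times = 0.5 + np.concatenate([[0], np.cumsum(rr)])
        x = ecg_with_r_peaks(r_times)
        qrs = detect_qrs(make_trace(np.zeros_like(x), ecg_mv=x))
        assert len(qrs) == len(r_times)
        for r in r_times:  # brute-force nearest-time match
            assert np.min(np.abs(qrs - r)) < 0.010


class TestSegmentation:
    def test_windows_partition_interior(self):
        r_times = np.array([0.5, 1.25, 2.0, 2.75])
        x = ecg_with_r_peaks(r_times, duration=3.6)
        trace = make_trace(np.zeros_like(x), ecg_mv=x)
        cfg = DetectorConfig()
        windows = segment_beats(trace, r_times, cfg)
        assert len(windows) == 4
        lengths = [len(w.map_mv) for w in windows]
        assert lengths[0] == lengths[1] == lengths[2] == lengths[3] == 750
        starts = [w.start_time for w in windows]
        for w, r in zip(windows, r_times):
            assert w.start_time == pytest.approx(r - cfg.pre_qrs_offset_s, abs=1e-9)
        # contiguous: each window starts where the previous one ends
        for w, nxt in zip(windows, windows[1:]):
            assert nxt.start_time == pytest.approx(
                w.start_time + len(w.map_mv) / trace.sample_rate, abs=1e-9
            )

    def test_irregular_rr_boundaries_by_enumeration(self):
        r_times = np.array([0.5, 1.1, 2.1, 2.8, 3.2])
        x = ecg_with_r_peaks(r_times, duration=4.2)
        trace = make_trace(np.zeros_like(x), ecg_mv=x)
        cfg = DetectorConfig()
        windows = segment_beats(trace, r_times, cfg)
        med_rr = np.median(np.diff(r_times))
        expected_bounds = list(r_times - cfg.pre_qrs_offset_s) + [
            r_times[-1] - cfg.pre_qrs_offset_s + med_rr
        ]
        for w, lo, hi in zip(windows, expected_bounds, expected_bounds[1:]):
            assert w.start_time == pytest.approx(lo, abs=1e-9)
            assert len(w.map_mv) == int(round(hi * 1000)) - int(round(lo * 1000))

    def test_needs_two_references(self):
        trace = make_trace(np.zeros(2000))
        with pytest.raises(NoBeatsError):
            segment_beats(trace, np.array([0.5]))


class TestAssessBeat:
    def test_clean_map_detected_with_correct_metrics(self, detector):
        window, eat = synthetic_map_window(4.0, 200.0)
        b = assess_beat(window, eat, detector)
        assert b.map_present
        assert b.amplitude == pytest.approx(4.0)
        assert b.map_duration_mapdur == pytest.approx(200.0)
        assert b.activation_time_at == pytest.approx(60.0)
        assert b.end_of_repolarization_eor == pytest.approx(260.0)

    def test_amplitude_exactly_two_mv_is_not_a_map(self, detector):
        """The amplitude criterion is strictly 'more than 2 mV'."""
        window, eat = synthetic_map_window(2.0, 200.0)
        b = assess_beat(window, eat, detector)
        assert b.amplitude == 2.0
        assert not b.map_present
        assert b.map_duration_mapdur is None

    def test_duration_exactly_100_ms_is_a_map(self, detector):
        """The duration criterion is 'a hundred milliseconds or greater',
        inclusive."""
        window, eat = synthetic_map_window(4.0, 100.0)
        b = assess_beat(window, eat, detector)
        assert b.map_present
        assert b.map_duration_mapdur == 100.0

    def test_duration_just_below_100_ms_is_not_a_map(self, detector):
        window, eat = synthetic_map_window(4.0, 99.0)
        b = assess_beat(window, eat, detector)
        assert not b.map_present

    def test_mapdur_is_eor_minus_at_identically(self, detector):
        for amp, dur in [(3.0, 150.0), (4.5, 101.0), (6.0, 240.0)]:
            window, eat = synthetic_map_window(amp, dur)
            b = assess_beat(window, eat, detector)
            assert b.map_duration_mapdur == b.end_of_repolarization_eor - b.activation_time_at

    def test_amplitude_scaling_never_unflags_a_map(self, detector):
        window, eat = synthetic_map_window(3.0, 150.0)
        for c in (1.0, 1.3, 2.0, 5.0, 20.0):
            scaled = make_window(window.map_mv * c)
            assert assess_beat(scaled, eat, detector).map_present

    def test_short_window_is_an_error(self, detector):
        with pytest.raises(WindowTooShortError):
            assess_beat(make_window(np.zeros(50)), 0.0, detector)

    def test_generator_waveform_metrics_close_to_truth(self, quiet_config, detector):
        """Full chain on a clean synthetic site: measured MAPDUR within
        10 ms of the generated duration."""
        site = SitePhysiology("s", True, cf_threshold=4.0, map_amplitude=4.0,
                              map_duration=200.0)
        trace = generate_trace(site, constant_profile(9.0, 10, quiet_config), quiet_config)
        result = analyze_trace(trace, detector)
        durs = [b.map_duration_mapdur for b in result.beats if b.map_present]
        assert len(durs) >= 8
        assert abs(np.mean(durs) - 200.0) < 10.0


def beat(present, amp=4.0, dur=200.0, cf=None, i=0):
    return BeatAssessment(
        beat_index=i, qrs_time=float(i), earliest_activation_time=float(i),
        map_present=present, amplitude=amp,
        activation_time_at=30.0 if present else None,
        end_of_repolarization_eor=30.0 + dur if present else None,
        map_duration_mapdur=dur if present else None,
        cf_at_beat=cf,
    )


def oracle_first_run(beats, run, tol):
    """Independent exhaustive scan over all windows of length ``run``."""
    def sim(a, b):
        for x, y in ((a.amplitude, b.amplitude),
                     (a.map_duration_mapdur, b.map_duration_mapdur)):
            if x is None or y is None:
                return False
            if max(abs(x), abs(y)) and abs(x - y) / max(abs(x), abs(y)) > tol:
                return False
        return True

    for s in range(len(beats) - run + 1):
        w = beats[s : s + run]
        if all(b.map_present for b in w) and all(
            sim(w[i], w[j]) for i in range(run) for j in range(i + 1, run)
        ):
            return s
    return None


class TestConsistentRun:
    def test_uniform_run_detected_at_start(self):
        beats = [beat(True, cf=float(5 + i), i=i) for i in range(10)]
        res = find_consistent_run(beats)
        assert res.first_consistent_run_start == 0
        assert res.cf_at_detection == 8.0  # CF at the last beat of the run
        assert res.max_cf_applied == 14.0

    def test_broken_runs_yield_null(self):
        beats = []
        for i in range(12):
            beats.append(beat(i % 3 != 2, cf=1.0, i=i))
        res = find_consistent_run(beats)
        assert res.first_consistent_run_start is None
        assert res.cf_at_detection is None

    def test_dissimilar_waveforms_do_not_qualify(self):
        beats = [beat(True, amp=4.0, i=0), beat(True, amp=4.0, i=1),
                 beat(True, amp=8.0, i=2), beat(True, amp=4.0, i=3),
                 beat(True, amp=4.0, i=4)]
        res = find_consistent_run(beats)
        assert res.first_consistent_run_start is None

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_scan_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        beats = []
        for i in range(n):
            present = bool(rng.random() < 0.6)
            amp = float(rng.uniform(2.5, 6.0))
            dur = float(rng.uniform(110, 250))
            beats.append(beat(present, amp=amp, dur=dur, cf=float(i), i=i))
        cfg = DetectorConfig()
        res = find_consistent_run(beats, cfg)
        expected = oracle_first_run(beats, cfg.consistency_run, cfg.similarity_tolerance)
        assert res.first_consistent_run_start == expected
        if expected is not None:
            assert res.cf_at_detection == beats[expected + 3].cf_at_beat


class TestGroundTruthConcordance:
    def test_per_beat_agreement_at_default_noise(self):
        """Across 1000+ synthetic beats spanning sub- and supra-threshold
        forces, per-beat detection matches the generator truth >= 95%."""
        cfg = SimulationConfig(seed=11)
        sites = draw_site_physiology(12, 1.0, cfg)
        agree = total = 0
        for k, site in enumerate(sites):
            # constant forces around each site's threshold, plus clear extremes
            for f in (0.25 * site.cf_threshold, 0.9 * site.cf_threshold,
                      1.1 * site.cf_threshold, site.cf_threshold + 3.0):
                rng = np.random.default_rng(1000 + k)
                trace = generate_trace(site, constant_profile(f, 22, cfg), cfg, rng=rng)
                result = analyze_trace(trace)
                truth = trace.truth.beat_elicited
                for b in result.beats:
                    total += 1
                    agree += b.map_present == bool(truth[b.beat_index])
        assert total >= 1000
        assert agree / total >= 0.95
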