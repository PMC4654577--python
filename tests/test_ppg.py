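"""Beat detection, artifact rules and interval statistics."""

import numpy as np
import pytest

from triadstress import intervals as iv
from triadstress.ppg import (ArtifactAnnotation, BeatSeries, SegmentMap,
                             WaveformTrace, apply_artifacts,
                             brute_force_amplitudes, detect_beats,
                             interval_means, normalize_session, read_waveform,
                             write_waveform)
from triadstress.synthetic import SubjectPhysio, synth_ppg
from triadstress.turns import Turn, TurnTrack


def sinusoid(freq_hz=1.2, amp=1.0, dur=60.0, fs=100.0):
    t = np.arange(int(dur * fs)) / fs
    return WaveformTrace("sin", fs, amp * np.sin(2 * np.pi * freq_hz * t))


class TestWaveformIO:
    def test_round_trip(self, tmp_path):
        tr = sinusoid()
        p = tmp_path / "w.csv"
        write_waveform(tr, p)
        back = read_waveform(p, subject_id="sin")
        assert back.sampling_rate_hz == pytest.approx(tr.sampling_rate_hz)
        np.testing.assert_allclose(back.samples, tr.samples, atol=1e-5)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("time_s,signal\n")
        with pytest.raises(Exception):
            read_waveform(p)

    def test_duplicate_timestamp_names_row(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("time_s,signal\n0.00,0.1\n0.01,0.2\n0.01,0.3\n0.02,0.4\n")
        with pytest.raises(ValueError, match="row 4"):
            read_waveform(p)

    def test_non_uniform_sampling_errors(self, tmp_path):
        p = tmp_path / "jit.csv"
        p.write_text("time_s,signal\n0.00,0.1\n0.01,0.2\n0.05,0.3\n0.06,0.4\n")
        with pytest.raises(ValueError, match="non-uniform"):
            read_waveform(p)


class TestDetectBeats:
    def test_sinusoid_rate_and_amplitude(self):
        beats = detect_beats(sinusoid(freq_hz=1.2, amp=1.0, dur=60.0))
        assert beats.bpm.mean() == pytest.approx(72.0, abs=0.5)
        assert beats.amplitudes.mean() == pytest.approx(2.0, abs=0.05)

    def test_piecewise_rate_recovery(self, segments):
        # 70 BPM during video, 90 during conversation (always "speaking")
        pp = SubjectPhysio("S", 70.0, 90.0, 90.0, 1.0, 1.0, 1.0)
        tr = synth_ppg(pp, segments, [segments.conversation], seed=1,
                       bpm_jitter_sd=0.0, noise_sd=0.0)
        beats = detect_beats(tr)
        bpm_v, _ = interval_means(beats, [segments.video])
        bpm_c, _ = interval_means(beats, [segments.conversation])
        assert bpm_v == pytest.approx(70.0, abs=1.0)
        assert bpm_c == pytest.approx(90.0, abs=1.0)

    def test_flat_line_errors(self):
        tr = WaveformTrace("flat", 100.0, np.ones(6000))
        with pytest.raises(ValueError, match="[Ff]lat|no beats"):
            detect_beats(tr)

    def test_out_of_bounds_rates_flagged_not_dropped(self):
        beats = detect_beats(sinusoid(freq_hz=0.5, amp=1.0, dur=120.0),
                             min_bpm=40.0)
        # 30 BPM < min_bpm: all flagged invalid but retained
        assert len(beats) > 0
        assert not beats.valid.any()

    def test_amplitude_matches_brute_force_scan(self, segments):
        pp = SubjectPhysio("S", 75.0, 80.0, 85.0, 1.0, 0.8, 0.7)
        turn = [(300.0, 400.0)]
        tr = synth_ppg(pp, segments, turn, seed=5, bpm_jitter_sd=1.0,
                       noise_sd=0.0)
        beats = detect_beats(tr)
        oracle = brute_force_amplitudes(tr, beats.times.tolist()
                                        + [beats.times[-1] + 60 / beats.bpm[-1]])
        # cycles straddling a state transition change amplitude mid-cycle
        # and have no single programmed value; exclude them
        bounds = [segments.video[1], segments.conversation[0], 300.0, 400.0]
        steady = np.all(
            [np.abs(beats.times - b) > 1.5 for b in bounds], axis=0)
        np.testing.assert_allclose(beats.amplitudes[steady], oracle[steady],
                                   rtol=0.02)


class TestApplyArtifacts:
    def make_beats(self, amp=1.0, n=120, spacing=1.0):
        t = np.arange(n) * spacing
        return BeatSeries("S", t, np.full(n, amp), np.full(n, 60.0 / spacing))

    def test_no_annotations_is_identity(self):
        beats = self.make_beats()
        out = apply_artifacts(beats, [])
        assert out is beats

    def test_excision_removes_beats(self):
        beats = self.make_beats()
        out = apply_artifacts(beats, [ArtifactAnnotation("excise", 10.0, 25.0)])
        assert len(out) == len(beats) - 15
        assert not ((out.times >= 10.0) & (out.times < 25.0)).any()

    def test_step_correction_restores_level(self, rng):
        beats = self.make_beats()
        amps = beats.amplitudes * (1 + 0.05 * rng.standard_normal(len(beats)))
        amps[beats.times >= 60.0] *= 2.0  # injected x2 step
        stepped = BeatSeries("S", beats.times, amps, beats.bpm)
        out = apply_artifacts(stepped, [ArtifactAnnotation("step", 60.0)])
        post = out.amplitudes[out.times >= 60.0]
        assert post.mean() == pytest.approx(1.0, abs=0.02)

    def test_step_too_close_to_start_errors(self):
        beats = self.make_beats()
        with pytest.raises(ValueError, match="empty"):
            apply_artifacts(beats, [ArtifactAnnotation("step", 5.0)],
                            window_s=20.0)

    def test_beat_times_unchanged_by_step(self):
        beats = self.make_beats()
        out = apply_artifacts(beats, [ArtifactAnnotation("step", 60.0)])
        np.testing.assert_array_equal(out.times, beats.times)

    def test_step_idempotent_on_stationary_data(self, rng):
        # correction on step-free data barely moves the means
        amps = 1.0 + 0.05 * rng.standard_normal(200)
        beats = BeatSeries("S", np.arange(200.0), amps, np.full(200, 60.0))
        out = apply_artifacts(beats, [ArtifactAnnotation("step", 100.0)])
        se = 0.05 / np.sqrt(20)
        assert abs(out.amplitudes.mean() - beats.amplitudes.mean()) < 2 * se


class TestIntervalMeans:
    def test_single_interval_gives_global_means(self):
        beats = BeatSeries("S", np.arange(10.0), np.linspace(1, 2, 10),
                           np.full(10, 60.0))
        bpm, amp = interval_means(beats, [(0.0, 10.0)])
        assert bpm == pytest.approx(60.0)
        assert amp == pytest.approx(np.linspace(1, 2, 10).mean())

    def test_empty_union_errors(self):
        beats = BeatSeries("S", np.arange(10.0), np.ones(10), np.full(10, 60.0))
        with pytest.raises(ValueError):
            interval_means(beats, [(100.0, 200.0)])

    def test_disjoint_intervals_equal_their_union(self):
        t = np.sort(np.random.default_rng(3).uniform(0, 100, 200))
        beats = BeatSeries("S", t, 1 + t / 100, np.full(200, 60.0))
        parts = interval_means(beats, [(0.0, 30.0), (50.0, 90.0)])
        merged = interval_means(beats, iv.union([(0.0, 30.0)], [(50.0, 90.0)]))
        assert parts == pytest.approx(merged)


class TestNormalizeSession:
    def make_session(self, segments, pp, seed=0):
        turns = TurnTrack(
            [Turn("S", 250.0, 300.0), Turn("O", 320.0, 380.0),
             Turn("S", 420.0, 470.0), Turn("O", 500.0, 560.0)],
            segments.conversation, speakers=["S", "O"])
        tr = synth_ppg(pp, segments,
                       [(250.0, 300.0), (420.0, 470.0)], seed=seed,
                       bpm_jitter_sd=0.0, noise_sd=0.0)
        return detect_beats(tr), turns

    def test_constant_physiology_gives_unit_ratios(self, segments, flat_physio):
        beats, turns = self.make_session(segments, flat_physio)
        m = normalize_session(beats, segments, turns, "S")
        assert m.tbv_conv_video_ratio == pytest.approx(1.0, abs=0.02)
        assert m.tbv_speak_listen_ratio == pytest.approx(1.0, abs=0.02)
        assert m.bpm_speak_listen_ratio == pytest.approx(1.0, abs=0.02)

    def test_programmed_speak_listen_amplitude_ratio(self, segments):
        pp = SubjectPhysio("S", 72, 72, 72, 1.0, 1.0, 0.9)
        beats, turns = self.make_session(segments, pp)
        m = normalize_session(beats, segments, turns, "S")
        assert m.tbv_speak_listen_ratio == pytest.approx(0.90, abs=0.03)

    def test_subject_without_turns_flags_ratios_missing(self, segments,
                                                        flat_physio):
        beats, _ = self.make_session(segments, flat_physio)
        turns = TurnTrack([Turn("O", 300.0, 400.0)], segments.conversation,
                          speakers=["S", "O"])
        m = normalize_session(beats, segments, turns, "S")
        assert np.isnan(m.tbv_speak_listen_ratio)
        assert np.isfinite(m.tbv_conv_video_ratio)

    def test_gain_invariance_of_all_ratios(self, segments):
        # multiplying the whole trace by c > 0 (cuff tightness / sensor
        # gain) must leave every ratio unchanged
        pp = SubjectPhysio("S", 70, 78, 85, 1.0, 0.8, 0.7)
        own = [(250.0, 300.0), (420.0, 470.0)]
        turns = TurnTrack(
            [Turn("S", 250.0, 300.0), Turn("O", 320.0, 380.0),
             Turn("S", 420.0, 470.0), Turn("O", 500.0, 560.0)],
            segments.conversation, speakers=["S", "O"])
        tr = synth_ppg(pp, segments, own, seed=4, bpm_jitter_sd=1.0,
                       noise_sd=0.01)
        m1 = normalize_session(detect_beats(tr), segments, turns, "S")
        scaled = WaveformTrace("S", tr.sampling_rate_hz, tr.samples * 37.2)
        m2 = normalize_session(detect_beats(scaled), segments, turns, "S")
        for attr in ("tbv_conv_video_ratio", "tbv_speak_listen_ratio",
                     "bpm_speak_listen_ratio", "bpm_conv_video_ratio"):
            assert getattr(m1, attr) == pytest.approx(getattr(m2, attr),
                                                      abs=1e-9)


class TestSegmentMap:
    def test_video_must_precede_conversation(self):
        with pytest.raises(ValueError):
            SegmentMap(video=(100.0, 300.0), conversation=(200.0, 800.0))
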