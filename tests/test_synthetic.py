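"""Generator determinism, null calibration and parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from triadstress.ppg import detect_beats, interval_means, normalize_session
from triadstress.stats import pearson_r
from triadstress.status import aggregate_ranks
from triadstress.synthetic import (SimulationConfig, SubjectPhysio,
                                   simulate_session, synth_ppg, synth_saliva,
                                   synth_status_components, synth_turns,
                                   write_session)
from triadstress.turns import build_turns, turn_statistics


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("video_duration_s", -1.0),
        ("sampling_rate_hz", 10.0),
        ("conv_amp_factor", 0.0),
        ("lnT_prior_post_r", 1.5),
        ("n_study1", 99),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SimulationConfig(**{field: value})


class TestDeterminism:
    def test_same_seed_identical_bundles(self, small_config, tmp_path):
        b1 = simulate_session(small_config, 0)
        b2 = simulate_session(dataclasses.replace(small_config), 0)
        for sid in b1.subjects:
            np.testing.assert_array_equal(b1.traces[sid].samples,
                                          b2.traces[sid].samples)
        pd.testing.assert_frame_equal(b1.saliva, b2.saliva)
        assert b1.ground_truth == b2.ground_truth
        # bitwise identity of the serialized session
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_session(b1, d1)
        write_session(b2, d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_different_seed_differs(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        b1 = simulate_session(small_config, 0)
        b2 = simulate_session(other, 0)
        sid = b1.subjects[0]
        assert not np.array_equal(b1.traces[sid].samples,
                                  b2.traces[sid].samples)


class TestSynthPPG:
    def test_constant_schedule_recovers_programmed_rate(self, segments):
        pp = SubjectPhysio("S", 72.0, 72.0, 72.0, 1.0, 1.0, 1.0)
        tr = synth_ppg(pp, segments, [], seed=0, bpm_jitter_sd=0.0,
                       noise_sd=0.0)
        beats = detect_beats(tr)
        assert beats.bpm.mean() == pytest.approx(72.0, abs=1.0)

    def test_injected_step_scales_envelope(self, segments, flat_physio):
        from triadstress.ppg import ArtifactAnnotation

        ann = [ArtifactAnnotation("step", 400.0)]
        tr = synth_ppg(flat_physio, segments, [], seed=1, bpm_jitter_sd=0.0,
                       noise_sd=0.0, artifacts=ann,
                       artifact_params={0: {"factor": 1.5}})
        beats = detect_beats(tr)
        pre = beats.amplitudes[(beats.times > 200) & (beats.times < 395)]
        post = beats.amplitudes[beats.times > 405]
        assert post.mean() / pre.mean() == pytest.approx(1.5, rel=0.02)

    def test_zero_amplitude_is_invalid_physiology(self, segments):
        pp = SubjectPhysio("S", 72, 72, 72, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="physiology"):
            synth_ppg(pp, segments, [], seed=0)

    def test_turn_outside_conversation_errors(self, segments, flat_physio):
        with pytest.raises(ValueError, match="outside"):
            synth_ppg(flat_physio, segments, [(100.0, 120.0)], seed=0)


class TestSynthTurns:
    def test_equal_scores_give_equal_floor_shares(self):
        totals = np.zeros(3)
        for rep in range(200):
            _, schedule = synth_turns([0.0, 0.0, 0.0], 600.0, seed=rep)
            stats = turn_statistics(schedule).set_index("speaker_id")
            totals += stats.loc[["A", "B", "C"], "floor_seconds"].to_numpy()
        shares = totals / totals.sum()
        np.testing.assert_allclose(shares, 1 / 3, atol=0.03)

    def test_dominant_score_holds_largest_share(self):
        wins = 0
        for rep in range(200):
            _, schedule = synth_turns([3.0, 0.0, 0.0], 600.0, seed=1000 + rep)
            stats = turn_statistics(schedule).set_index("speaker_id")
            fl = stats.loc[["A", "B", "C"], "floor_seconds"].to_numpy()
            wins += fl.argmax() == 0
        assert wins >= 0.95 * 200

    def test_zero_duration_gives_empty_track(self):
        utts, schedule = synth_turns([0.0, 0.0, 0.0], 0.0, seed=0)
        assert utts.utterances == []
        assert schedule.turns == []

    def test_turn_counts_in_observed_range(self):
        # the study observed 3 to 13 turns per subject
        for rep in range(20):
            _, schedule = synth_turns([0.5, 0.0, -0.5], 600.0, seed=rep)
            counts = turn_statistics(schedule)["turn_count"]
            assert counts.between(3, 13).all()

    def test_wrong_number_of_scores_errors(self):
        with pytest.raises(ValueError):
            synth_turns([1.0, 2.0], 600.0, seed=0)


class TestSynthSaliva:
    def test_prior_post_correlation_matches_configured(self):
        cfg = SimulationConfig()
        frames = [synth_saliva(cfg, [1, 2, 3], seed=i, triad_id=f"T{i}")
                  for i in range(167)]  # ~500 subjects
        panel = pd.concat(frames, ignore_index=True)
        r = pearson_r(np.log(panel["T_prior"]), np.log(panel["T_post"]))
        assert r == pytest.approx(0.69, abs=0.08)

    def test_rank_lnaa_slope_recovery(self):
        cfg = SimulationConfig(rank_lnaa_slope=0.29)
        frames = [synth_saliva(cfg, [1, 2, 3], seed=i, triad_id=f"T{i}")
                  for i in range(167)]
        panel = pd.concat(frames, ignore_index=True)
        lnaa = np.log(panel["AA_prior"])
        rank = panel["rank"]
        slope = np.polyfit(rank, lnaa, 1)[0]
        assert slope == pytest.approx(0.29, abs=0.08)

    def test_zero_sds_give_exact_means(self):
        cfg = SimulationConfig(lnT_sd=0.0, C_sd=0.0, lnAA_sd=0.0,
                               lnT_post_shift=0.0, lnAA_post_shift=0.0,
                               rank_lnaa_slope=0.0)
        df = synth_saliva(cfg, [1, 2, 3], seed=0)
        assert np.allclose(np.log(df["T_prior"]), cfg.lnT_mean)
        assert np.allclose(df["C_prior"], cfg.C_mean)
        assert np.allclose(np.log(df["AA_prior"]), cfg.lnAA_mean)

    def test_values_positive_within_assay_bounds(self):
        cfg = SimulationConfig(lnT_sd=2.0, lnAA_sd=2.0, C_sd=0.5)
        frames = [synth_saliva(cfg, [1, 2, 3], seed=i) for i in range(50)]
        panel = pd.concat(frames)
        assert (panel[["T_prior", "T_post"]].to_numpy() >= 1.0).all()
        assert (panel[["T_prior", "T_post"]].to_numpy() <= 600.0).all()
        assert (panel[["C_prior", "C_post"]].to_numpy() >= 0.007).all()
        assert (panel[["AA_prior", "AA_post"]].to_numpy() > 0).all()

    def test_invalid_ranks_error(self):
        with pytest.raises(ValueError):
            synth_saliva(SimulationConfig(), [0, 1, 2], seed=0)


class TestSynthStatusComponents:
    def test_zero_noise_reproduces_latent_order(self):
        sc = synth_status_components([1, 2, 3], 0.0, seed=0)
        for v in sc.components.values():
            assert v == (1.0, 2.0, 3.0)
        assert aggregate_ranks(sc).ranks == (1.0, 2.0, 3.0)

    def test_tied_latent_round_trip(self):
        sc = synth_status_components([1.5, 1.5, 3], 0.0, seed=0)
        sr = aggregate_ranks(sc)
        assert sr.ranks == (1.5, 1.5, 3.0)
        assert sr.hierarchy_class == "top-tie"

    def test_noise_increases_tie_frequency(self):
        def tie_rate(noise, n=300):
            ties = 0
            for i in range(n):
                sc = synth_status_components([1, 2, 3], noise, seed=i)
                r = aggregate_ranks(sc).ranks
                ties += len(set(r)) < 3
            return ties / n

        assert tie_rate(1.0) > tie_rate(0.0)


class TestSimulateSession:
    def test_structure(self, small_config):
        b = simulate_session(small_config, 0)
        assert len(b.subjects) == 3
        assert set(b.traces) == set(b.subjects)
        assert b.saliva.shape[0] == 3
        assert len(b.components.components) == 7
        assert set(b.ground_truth["latent_ranks"]) <= {1.0, 2.0, 3.0}

    def test_null_config_gives_unit_ratios(self, segments):
        cfg = SimulationConfig.null(n_triads=1, n_study1=1, seed=5,
                                    waveform_noise_sd=0.01)
        b = simulate_session(cfg, 0)
        turn_track = build_turns(b.utterances)
        for sid in b.subjects:
            beats = detect_beats(b.traces[sid])
            m = normalize_session(beats, b.segments, turn_track, sid)
            assert m.tbv_speak_listen_ratio == pytest.approx(1.0, abs=0.02)
            assert m.tbv_conv_video_ratio == pytest.approx(1.0, abs=0.02)

    def test_programmed_conversation_amplitude_factor_recovered(self):
        # programmed conversation/video amplitude factor, no speak effect
        cfg = SimulationConfig.null(n_triads=15, n_study1=10, seed=11,
                                    conv_amp_factor=0.77)
        ratios = []
        for i in range(cfg.n_triads):
            b = simulate_session(cfg, i)
            for sid in b.subjects:
                beats = detect_beats(b.traces[sid])
                bpm_v, tbv_v = interval_means(beats, [b.segments.video])
                bpm_c, tbv_c = interval_means(beats,
                                              [b.segments.conversation])
                ratios.append(tbv_c / tbv_v)
        assert np.mean(ratios) == pytest.approx(0.77, abs=0.03)

    def test_missingness_emulation(self):
        cfg = SimulationConfig(seed=2)
        b0 = simulate_session(cfg, 0)  # among the first 5 no-reward triads
        assert b0.saliva["AA_prior"].isna().all()
        b9 = simulate_session(cfg, 9)
        assert b9.saliva["AA_prior"].notna().all()
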