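"""Trace analyzers: train detection, CSA/specific-force normalization, NMTF
time course, initial NMTF, intratrain fatigue, and oracle equivalence against
the generator's closed forms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmtflab as nl
from nmtflab.trace import TrainEvent, compute_intratrain_fatigue

from conftest import make_recording


def _single_train_recording(droop, plateau=1.0):
    proto = nl.StimulationProtocol()
    t, env = nl.render_nerve_train(plateau, droop, proto)
    zeros = np.zeros(len(t), dtype=np.uint8)
    rec = nl.ForceRecording(1000.0, t, env, zeros, zeros,
                           nl.PrepMetadata(), proto)
    ev = TrainEvent(0.0, proto.train_duration_s, "nerve_only",
                    (0.0, proto.train_duration_s), None, plateau, plateau)
    return ev, rec


class TestDetectTrains:
    def test_counts_default_protocol(self, vehicle_recording):
        trains = nl.detect_trains(vehicle_recording[0])
        assert len(trains) == 121
        assert sum(t.kind == "superimposed" for t in trains) == 9

    def test_counts_truncated_protocol(self):
        proto = nl.StimulationProtocol(total_duration_s=30.0)
        rec, _ = nl.simulate_recording(protocol=proto)
        trains = nl.detect_trains(rec)
        assert len(trains) == 31
        assert sum(t.kind == "superimposed" for t in trains) == 3

    def test_force_fallback_matches_markers(self, vehicle_recording):
        rec, _ = vehicle_recording
        marker_onsets = [t.onset_s for t in nl.detect_trains(rec)]
        blind = dataclasses.replace(
            make_recording(rec, rec.force_n),
            nerve_stim_marker=np.zeros_like(rec.nerve_stim_marker),
            muscle_stim_marker=np.zeros_like(rec.muscle_stim_marker),
        )
        fallback_onsets = [t.onset_s for t in nl.detect_trains(blind)]
        assert len(fallback_onsets) == len(marker_onsets)
        dt = 1.0 / rec.sampling_rate_hz
        np.testing.assert_allclose(fallback_onsets, marker_onsets, atol=2 * dt)

    def test_no_trains_is_an_error(self, vehicle_recording):
        rec, _ = vehicle_recording
        empty = dataclasses.replace(
            make_recording(rec, np.zeros_like(rec.force_n)),
            nerve_stim_marker=np.zeros_like(rec.nerve_stim_marker),
            muscle_stim_marker=np.zeros_like(rec.muscle_stim_marker),
        )
        with pytest.raises(ValueError, match="no stimulus trains"):
            nl.detect_trains(empty)

    def test_off_grid_markers_warn(self, vehicle_recording):
        rec, _ = vehicle_recording
        odd_proto = nl.StimulationProtocol(train_period_s=2.0,
                                           superimpose_interval_s=16.0)
        odd = dataclasses.replace(make_recording(rec, rec.force_n),
                                  protocol=odd_proto)
        with pytest.warns(UserWarning, match="grid"):
            nl.detect_trains(odd)


class TestNormalization:
    @pytest.mark.parametrize("weight, lo, expected", [
        (0.04224, 2.0, 0.0200),    # hand arithmetic: 0.04224/2.112
        (1.056, 1.0, 1.0),         # density-cancelling identity
        (0.0422, 2.0, 0.019981),   # hand arithmetic
    ])
    def test_muscle_csa(self, weight, lo, expected):
        assert nl.compute_muscle_csa(weight, lo) == pytest.approx(expected, rel=1e-3)

    def test_csa_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nl.compute_muscle_csa(0.0, 2.0)
        with pytest.raises(ValueError):
            nl.compute_muscle_csa(0.04, -2.0)

    @pytest.mark.parametrize("force, csa, expected", [
        (0.446, 0.0200, 22.3),
        (0.0, 0.02, 0.0),
        (1.0, 1.0, 1.0),
    ])
    def test_specific_force(self, force, csa, expected):
        assert nl.compute_specific_force(force, csa) == pytest.approx(expected)


class TestNMTFTimecourse:
    def test_equal_declines_give_zero(self):
        epochs = np.arange(0, 121, 15.0)
        mf = 1.0 - 0.3 * epochs / 120.0
        series = nl.compute_nmtf_timecourse(epochs, mf * 2.0, mf * 0.5)
        np.testing.assert_allclose(series.nmtf_t, 0.0, atol=1e-12)

    @pytest.mark.parametrize("mfn, nfn, expected", [
        (0.8, 0.2, -75.0),         # (0.8-0.2)/0.8 x 100
        (0.700, 0.2422, -65.4),    # control-group calibration arithmetic
    ])
    def test_hand_computed_final_values(self, mfn, nfn, expected):
        epochs = np.array([0.0, 120.0])
        series = nl.compute_nmtf_timecourse(
            epochs, np.array([1.0, mfn]), np.array([1.0, nfn]))
        assert series.final_nmtf == pytest.approx(expected, abs=1e-9)
        assert series.nmtf_t[0] == 0.0  # epoch 0 identically zero

    def test_zero_initial_force_rejected(self):
        with pytest.raises(ValueError):
            nl.compute_nmtf_timecourse([0, 15], [0.0, 1.0], [1.0, 1.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            nl.compute_nmtf_timecourse([0, 15], [1.0, 0.9], [1.0])

    @given(st.lists(st.tuples(
        st.floats(min_value=0.01, max_value=1.0),   # muscle normalized decline
        st.floats(min_value=0.0, max_value=1.0),    # nerve relative to muscle
    ), min_size=1, max_size=12))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_sign_and_bounds_when_nerve_declines_faster(self, pairs):
        """Whenever NF declines at least as fast as MF, NMTF lies in [-100, 0]."""
        mfn = np.array([1.0] + [m for m, _ in pairs])
        nfn = np.array([1.0] + [m * r for (m, _), (_, r) in zip(pairs, pairs)])
        series = nl.compute_nmtf_timecourse(
            np.arange(len(mfn), dtype=float), mfn, nfn)
        assert np.all(series.nmtf_t <= 1e-12)
        assert np.all(series.nmtf_t >= -100.0 - 1e-9)


class TestInitialNMTF:
    @pytest.mark.parametrize("nf, mf, expected", [
        (1.0, 1.0, 0.0),
        (0.874, 1.0, -12.6),
        (0.0, 1.0, -100.0),
    ])
    def test_examples(self, nf, mf, expected):
        assert nl.compute_initial_nmtf(nf, mf) == pytest.approx(expected)

    def test_zero_muscle_force_rejected(self):
        with pytest.raises(ValueError):
            nl.compute_initial_nmtf(1.0, 0.0)


class TestIntratrainFatigue:
    def test_flat_plateau_is_zero(self, vehicle_recording):
        rec, _ = vehicle_recording
        proto = rec.protocol
        flat = np.zeros_like(rec.force_n)
        flat[:int(proto.train_duration_s * rec.sampling_rate_hz)] = 1.0
        ev = TrainEvent(0.0, proto.train_duration_s, "nerve_only",
                        (0.0, proto.train_duration_s), None, 1.0, 1.0)
        assert compute_intratrain_fatigue(ev, make_recording(rec, flat)) == 0.0

    @pytest.mark.parametrize("droop, expected", [
        (0.019, -1.9),    # control-level droop
        (0.201, -20.1),   # acute-inhibition-level droop
    ])
    def test_rendered_droop_recovered(self, droop, expected):
        ev, rec = _single_train_recording(droop)
        assert compute_intratrain_fatigue(ev, rec) == pytest.approx(expected, abs=0.05)

    def test_zero_force_rejected(self, vehicle_recording):
        rec, _ = vehicle_recording
        ev = TrainEvent(0.0, 0.33, "nerve_only", (0.0, 0.33), None, 0.0, 0.0)
        with pytest.raises(ValueError, match="zero"):
            compute_intratrain_fatigue(ev, make_recording(rec, np.zeros_like(rec.force_n)))


class TestAnalyzeRecording:
    def test_oracle_equivalence_noise_free(self, vehicle_recording):
        """Every recovered statistic matches the generator closed form < 0.1."""
        rec, gt = vehicle_recording
        res = nl.analyze_recording(rec)
        assert res.final_nmtf == pytest.approx(gt.true_final_nmtf, abs=0.1)
        assert res.initial_nmtf == pytest.approx(gt.true_initial_nmtf, abs=0.1)
        assert res.final_intratrain_fatigue == pytest.approx(
            gt.true_intratrain_fatigue_at_end, abs=0.1)
        assert res.specific_force_n_per_cm2 == pytest.approx(
            gt.true_specific_force, abs=0.1)

    def test_noisy_cohort_mean_within_one_point(self):
        finals, truths = [], []
        for seed in range(1, 9):
            model = nl.FailureModel.from_normalized_forces(
                0.700, 0.2422, f0=0.126, d120=0.019, noise_sd=0.005, seed=seed)
            rec, gt = nl.simulate_recording(model=model)
            finals.append(nl.analyze_recording(rec).final_nmtf)
            truths.append(gt.true_final_nmtf)
        assert np.mean(finals) == pytest.approx(np.mean(truths), abs=1.0)

    def test_truncated_recording_names_missing_epoch(self):
        proto = nl.StimulationProtocol()
        rec, _ = nl.simulate_recording(protocol=proto)
        n_keep = int(90 * rec.sampling_rate_hz)
        cut = nl.ForceRecording(
            rec.sampling_rate_hz, rec.time_s[:n_keep], rec.force_n[:n_keep],
            rec.nerve_stim_marker[:n_keep], rec.muscle_stim_marker[:n_keep],
            rec.metadata, proto)
        with pytest.raises(ValueError, match="120-s epoch"):
            nl.analyze_recording(cut)

    def test_cohort_tables_tidy(self):
        cohort = nl.simulate_cohort(1, base_seed=5)
        wide, long = nl.analyze_trace_cohort([rec for rec, _ in cohort])
        assert len(wide) == 4
        assert set(wide["group"]) == set(nl.GROUPS)
        assert len(long) == 4 * 9  # 9 epochs per animal
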