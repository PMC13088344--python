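"""Synthetic-session generator: pulse train, gait, full stream assembly."""

import numpy as np
import pytest
from scipy import signal

from pulseband.artifact import ArtifactParams, simulate_artifact
from pulseband.preprocess import STANDARD_GRAVITY, reference_acceleration
from pulseband.simulate import (
    ExerciseProtocol,
    NoiseConfig,
    calibration_protocol,
    default_protocol,
    physio_profiles,
    synth_gait_accel,
    synth_pulse_train,
    synth_session,
)


class TestProtocol:
    def test_validation(self):
        with pytest.raises(ValueError):
            ExerciseProtocol(segments=[("rest", -1.0, 0.0)])
        with pytest.raises(ValueError):
            ExerciseProtocol(segments=[("rest", 10.0, -0.5)])
        with pytest.raises(ValueError):
            ExerciseProtocol(segments=[])

    def test_labels_at(self):
        proto = default_protocol(segment_s=60.0)
        labels = proto.labels_at(np.array([5.0, 65.0, 359.0]))
        assert list(labels) == ["rest", "walk_4kmh", "rest_post"]

    def test_physio_profiles_ranges(self):
        hr, met, temp = physio_profiles(default_protocol(segment_s=60.0))
        assert hr.min() >= 40 and hr.max() <= 220
        assert met.min() >= 1.0
        assert 36.0 < temp.min() and temp.max() < 39.0


class TestPulseTrain:
    def test_exact_beat_count_at_60_bpm(self):
        _, onsets = synth_pulse_train(np.full(1000, 60.0), fs=100, seed=0)
        assert len(onsets) == 10

    def test_dominant_line_at_1p2_hz_for_72_bpm(self):
        pulse, _ = synth_pulse_train(np.full(6000, 72.0), fs=100, seed=1)
        spec = np.abs(np.fft.rfft(pulse - pulse.mean()))
        freqs = np.fft.rfftfreq(6000, 0.01)
        assert freqs[np.argmax(spec)] == pytest.approx(1.2, abs=0.02)

    def test_seed_reproducibility(self):
        a, _ = synth_pulse_train(np.full(2000, 75.0), fs=100, seed=42)
        b, _ = synth_pulse_train(np.full(2000, 75.0), fs=100, seed=42)
        assert np.array_equal(a, b)

    def test_rejects_out_of_range_hr(self):
        with pytest.raises(ValueError):
            synth_pulse_train(np.full(100, 30.0))
        with pytest.raises(ValueError):
            synth_pulse_train(np.array([60.0, np.nan]))


class TestGait:
    def test_rest_is_gravity_plus_noise(self):
        proto = ExerciseProtocol(segments=[("rest", 30.0, 0.0)])
        acc = synth_gait_accel(proto, seed=0)
        mag = np.linalg.norm(acc, axis=1)
        assert abs(np.mean(mag) - STANDARD_GRAVITY) < 0.1
        assert np.std(mag) < 0.5

    def test_running_has_cadence_peak(self):
        proto = ExerciseProtocol(segments=[("run", 60.0, 0.8)])
        acc = synth_gait_accel(proto, seed=0)
        a = reference_acceleration(acc)
        f, p = signal.welch(a, fs=100, nperseg=1024)
        cadence = 1.5 + 1.6 * 0.8
        in_peak = p[(f > cadence - 0.3) & (f < cadence + 0.3)].max()
        background = np.median(p[(f > 0.5) & (f < 10)])
        assert in_peak > 10 * background

    def test_two_seeds_same_spectral_envelope(self):
        proto = ExerciseProtocol(segments=[("run", 60.0, 0.8)])
        psds = []
        for seed in (0, 1):
            a = reference_acceleration(synth_gait_accel(proto, seed=seed))
            f, p = signal.welch(a, fs=100, nperseg=512)
            psds.append(p[(f > 0.3) & (f < 12)])
        r = np.corrcoef(np.log(psds[0]), np.log(psds[1]))[0, 1]
        assert r > 0.85


class TestSession:
    def test_zero_gain_leaves_pure_pulse(self, true_params):
        p0 = ArtifactParams(K=0.0, zeta=0.4, omega_n=true_params.omega_n, fs=100)
        s = synth_session(
            calibration_protocol(30.0), p0, NoiseConfig(hf_sd=0, cf_sd=0), seed=1
        )
        np.testing.assert_allclose(
            s.hf - s.truth.baseline, s.truth.clean_pulse, atol=1e-12
        )

    def test_zero_noise_conservation(self, clean_cal_stream):
        s = clean_cal_stream
        resid = s.hf - s.truth.clean_pulse - s.truth.baseline - s.truth.artifact
        assert np.max(np.abs(resid)) < 1e-12

    def test_artifact_channel_single_source_of_truth(self, clean_cal_stream, true_params):
        s = clean_cal_stream
        ma = simulate_artifact(reference_acceleration(s.acc), true_params)
        np.testing.assert_array_equal(ma, s.truth.artifact)

    def test_six_five_minute_segments_length(self, true_params):
        s = synth_session(
            default_protocol(segment_s=300.0), true_params, NoiseConfig(), seed=0
        )
        assert len(s.t) == 180_000

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(hf_sd=-0.1)

    def test_seeded_determinism(self, true_params):
        a = synth_session(calibration_protocol(20.0), true_params, NoiseConfig(), seed=9)
        b = synth_session(calibration_protocol(20.0), true_params, NoiseConfig(), seed=9)
        assert np.array_equal(a.hf, b.hf) and np.array_equal(a.acc, b.acc)
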