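"""Synthetic multimodal sensor-stream simulator.

Generates hot-film, cold-film and 3-axis acceleration channels for a
scripted exercise protocol, with full ground truth, so every downstream
stage (artifact calibration, vitals extraction, metabolic estimation)
can be exercised and scored without recorded data.

Signal model
------------
* Heart rate, metabolic rate and core temperature relax toward
  intensity-dependent set points with first-order dynamics (time
  constants 30 s, 30 s and 300 s respectively).
* The clean pulse waveform is a sum of Gaussian bumps on the unit beat
  interval (systolic peak + reflective peak), phase-warped so the beat
  period tracks 60/HR instant by instant, with a slow amplitude
  envelope.
* Gait acceleration is quasi-periodic at a cadence that rises with
  intensity, plus gravity on one axis and band-limited noise; rest
  segments produce gravity + noise only.
* The motion artifact in the hot-film channel is the second-order model
  of :mod:`pulseband.artifact` driven by the gravity-subtracted
  acceleration magnitude — the same code path later used to remove it.
* The hot-film channel is clean pulse + a slow perfusion baseline
  proportional to metabolic rate + artifact + white noise; the cold film
  is an affine map of core temperature plus noise.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .artifact import ArtifactParams, simulate_artifact
from .preprocess import STANDARD_GRAVITY, reference_acceleration

__all__ = [
    "ExerciseProtocol",
    "PhysioGroundTruth",
    "SensorStream",
    "NoiseConfig",
    "PulseTemplate",
    "default_protocol",
    "calibration_protocol",
    "physio_profiles",
    "synth_pulse_train",
    "synth_gait_accel",
    "synth_session",
    "CF_GAIN_V_PER_C",
    "CF_OFFSET_V",
]

# Cold-film sensor model: output volts = gain * temperature + offset.
CF_GAIN_V_PER_C = 0.05
CF_OFFSET_V = -1.0

# Intensity -> set-point maps (dimensionless intensity in [0, 1]).
HR_REST_BPM = 62.0
HR_SPAN_BPM = 110.0
MET_REST_W_PER_KG = 1.2
MET_SPAN_W_PER_KG = 15.0
TEMP_REST_C = 36.6
TEMP_SPAN_C = 1.8
HR_TAU_S = 30.0
MET_TAU_S = 30.0
TEMP_TAU_S = 300.0

# Perfusion baseline of the hot film: b0 + b1 * metabolic_rate (a.u.).
BASELINE_OFFSET = 0.5
BASELINE_PER_W_PER_KG = 0.15


@dataclass(frozen=True)
class ExerciseProtocol:
    """Ordered (label, duration_s, intensity) segments at a sampling rate."""

    segments: Sequence[tuple[str, float, float]]
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for label, dur, inten in self.segments:
            if dur <= 0:
                raise ValueError(f"segment {label!r} duration must be > 0")
            if inten < 0:
                raise ValueError(f"segment {label!r} intensity must be >= 0")
        if self.sampling_rate <= 2 * 5.0:
            raise ValueError("sampling_rate must exceed twice the pulse band top")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d, _ in self.segments))

    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def intensity_profile(self) -> np.ndarray:
        """Per-sample intensity, piecewise constant over segments."""
        fs = self.sampling_rate
        parts = [
            np.full(int(round(d * fs)), i, float) for _, d, i in self.segments
        ]
        return np.concatenate(parts)

    def labels_at(self, t: np.ndarray) -> np.ndarray:
        """Segment label for each time in ``t`` (seconds from start)."""
        edges = np.cumsum([d for _, d, _ in self.segments])
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, len(self.segments) - 1)
        labels = np.array([s[0] for s in self.segments])
        return labels[idx]


def default_protocol(segment_s: float = 300.0, fs: float = 100.0) -> ExerciseProtocol:
    """Six-segment daily-exercise routine: rest, two walking speeds,
    jogging, running, final rest."""
    return ExerciseProtocol(
        segments=[
            ("rest", segment_s, 0.0),
            ("walk_4kmh", segment_s, 0.30),
            ("walk_6kmh", segment_s, 0.45),
            ("jog_7kmh", segment_s, 0.60),
            ("run_9kmh", segment_s, 0.85),
            ("rest_post", segment_s, 0.0),
        ],
        sampling_rate=fs,
    )


def calibration_protocol(duration_s: float = 120.0, fs: float = 100.0) -> ExerciseProtocol:
    """Two minutes of natural running, the calibration condition."""
    return ExerciseProtocol(segments=[("run_cal", duration_s, 0.80)], sampling_rate=fs)


@dataclass(frozen=True)
class PulseTemplate:
    """Beat morphology: Gaussian bumps (amplitude, center, width) on the
    unit beat interval.  Defaults give a systolic peak at phase 0.30 and
    a smaller reflective peak at 0.62, wide enough that the diastolic
    trough is a well-defined minimum at resting heart rates (very narrow
    bumps leave a flat inter-beat region whose minimum is noise-located,
    and an isolated reflective bump can be double-detected as a beat)."""

    peaks: Sequence[tuple[float, float, float]] = (
        (1.0, 0.30, 0.10),
        (0.50, 0.62, 0.14),
    )

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ValueError("template needs at least one peak")
        for amp, c, w in self.peaks:
            if w <= 0 or not (0.0 <= c <= 1.0):
                raise ValueError("peak centers in [0,1], widths > 0")

    def evaluate(self, phase_frac: np.ndarray) -> np.ndarray:
        """Waveform value at fractional beat phase in [0, 1)."""
        out = np.zeros_like(phase_frac)
        for amp, c, w in self.peaks:
            # include wrapped images so the waveform is periodic-continuous
            for shift in (-1.0, 0.0, 1.0):
                out += amp * np.exp(-0.5 * ((phase_frac - c - shift) / w) ** 2)
        return out


@dataclass
class PhysioGroundTruth:
    heart_rate: np.ndarray          # BPM
    metabolic_rate: np.ndarray      # W/kg
    core_temp: np.ndarray           # deg C
    clean_pulse: np.ndarray         # a.u., the component added to hf
    artifact: np.ndarray            # a.u., the component added to hf
    baseline: np.ndarray            # a.u., slow perfusion component of hf
    onset_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


@dataclass
class SensorStream:
    t: np.ndarray                   # seconds, uniform grid
    hf: np.ndarray                  # hot film, a.u.
    cf: np.ndarray                  # cold film, volts
    acc: np.ndarray                 # (n, 3) m/s^2
    fs: float
    truth: Optional[PhysioGroundTruth] = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.hf) == len(self.cf) == self.acc.shape[0] == n):
            raise ValueError("all channels must have the same length")
        if n > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs, rtol=0, atol=1e-9 / self.fs):
                raise ValueError("time grid must be uniform at 1/fs")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs


@dataclass(frozen=True)
class NoiseConfig:
    hf_sd: float = 0.08             # a.u.; visible beat distortion at default
    cf_sd: float = 0.002            # volts (~0.04 deg C)
    acc_sd: float = 0.0             # extra white accel noise on top of gait noise

    def __post_init__(self) -> None:
        if min(self.hf_sd, self.cf_sd, self.acc_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _relax(setpoint: np.ndarray, tau: float, fs: float, x0: float) -> np.ndarray:
    """First-order relaxation x' = (setpoint - x)/tau, exact per-step decay."""
    alpha = float(np.exp(-1.0 / (tau * fs)))
    out = np.empty_like(setpoint)
    x = x0
    for i, s in enumerate(setpoint):
        x = s + (x - s) * alpha
        out[i] = x
    return out


def physio_profiles(protocol: ExerciseProtocol):
    """Heart-rate (BPM), metabolic-rate (W/kg) and core-temperature (degC)
    trajectories for a protocol: first-order relaxation toward
    intensity-dependent set points."""
    fs = protocol.sampling_rate
    inten = protocol.intensity_profile()
    hr = _relax(HR_REST_BPM + HR_SPAN_BPM * inten, HR_TAU_S, fs, HR_REST_BPM)
    met = _relax(
        MET_REST_W_PER_KG + MET_SPAN_W_PER_KG * inten, MET_TAU_S, fs, MET_REST_W_PER_KG
    )
    temp = _relax(TEMP_REST_C + TEMP_SPAN_C * inten, TEMP_TAU_S, fs, TEMP_REST_C)
    return hr, met, temp


def synth_pulse_train(
    hr_profile: np.ndarray,
    template: PulseTemplate | None = None,
    fs: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous pulse waveform whose beat period tracks 60/HR.

    The beat phase is the integral of HR/60; the template is evaluated at
    the fractional phase, which warps the fixed morphology to the
    instantaneous period.  A slow (<0.1 Hz) multiplicative envelope with
    a seeded phase modulates the amplitude.

    Returns ``(pulse, onset_indices)`` where onsets are the samples at
    which the integer beat count increments (start of each beat).
    """
    hr_profile = np.asarray(hr_profile, float)
    if not np.isfinite(hr_profile).all():
        raise ValueError("hr_profile contains non-finite values")
    if np.any((hr_profile < 40.0) | (hr_profile > 220.0)):
        raise ValueError("hr_profile must lie within [40, 220] BPM")
    if template is None:
        template = PulseTemplate()
    rng = np.random.default_rng(seed)
    # phase[i] = integral of HR/60 over samples strictly before i, so the
    # first sample starts beat 0 exactly
    phase = np.concatenate([[0.0], np.cumsum(hr_profile[:-1] / 60.0)]) / fs
    frac = np.mod(phase, 1.0)
    wave = template.evaluate(frac)
    env_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.08 * np.sin(2 * np.pi * 0.04 * np.arange(len(wave)) / fs + env_phase)
    beat_idx = np.floor(phase)
    onsets = np.flatnonzero(np.diff(beat_idx, prepend=beat_idx[0] - 1) > 0)
    return wave * envelope, onsets


def _cadence_hz(intensity: np.ndarray) -> np.ndarray:
    """Step cadence map: 0 at rest, ~2.0 Hz walking, ~2.8-2.9 Hz running."""
    out = np.where(intensity > 0, 1.5 + 1.6 * intensity, 0.0)
    return out


def synth_gait_accel(protocol: ExerciseProtocol, seed: int = 0) -> np.ndarray:
    """Quasi-periodic 3-axis gait acceleration for a protocol.

    The vertical axis carries gravity, a cadence-locked fundamental and
    second harmonic, and one broadband heel-strike transient per step (a
    short half-sine impact with jittered amplitude and duration — head
    acceleration during running is far from a pure line spectrum).  The
    cadence itself is slowly frequency-modulated to emulate step-to-step
    variability.  Horizontal axes carry weaker components at half and
    full cadence plus scaled-down impacts.  Band-limited (<10 Hz)
    Gaussian noise, rising with intensity above a resting floor, is
    added on all axes; rest segments produce gravity + noise floor only.
    """
    fs = protocol.sampling_rate
    rng = np.random.default_rng(seed)
    inten = protocol.intensity_profile()
    n = inten.size
    cad = _cadence_hz(inten)
    # slow cadence jitter (~3% RMS, <0.2 Hz) so harmonic lines broaden
    sos_slow = signal.butter(2, 0.2, btype="lowpass", fs=fs, output="sos")
    jitter = signal.sosfilt(sos_slow, rng.standard_normal(n))
    jitter *= 0.03 / max(np.std(jitter), 1e-12)
    phase = 2 * np.pi * np.cumsum(cad * (1.0 + jitter)) / fs
    phi = rng.uniform(0, 2 * np.pi, size=4)

    # step-to-step amplitude variability (~15% RMS, <1 Hz): real gait is
    # quasi-periodic, never a constant-amplitude line spectrum
    def slow_mod() -> np.ndarray:
        m = signal.sosfilt(sos_slow, rng.standard_normal(n))
        return 1.0 + 0.15 * m / max(np.std(m), 1e-12)

    amp_v = 4.0 * inten
    # half-cadence vertical component = left/right step asymmetry, a
    # universal feature of real gait
    az = STANDARD_GRAVITY + amp_v * slow_mod() * np.sin(phase + phi[0]) \
        + 0.4 * amp_v * slow_mod() * np.sin(2 * phase + phi[1]) \
        + 0.3 * amp_v * slow_mod() * np.sin(0.5 * phase + phi[2])
    ax = 0.35 * amp_v * slow_mod() * np.sin(0.5 * phase + phi[2])
    ay = 0.25 * amp_v * slow_mod() * np.sin(phase + phi[3])

    # heel-strike impacts: one half-sine pulse per step (phase wrap),
    # duration 40-80 ms, amplitude ~0.9 x harmonic amplitude +-50%, and
    # +-30 ms foot-strike timing jitter — the jittered impact train is
    # the main broadband component of head acceleration while running
    steps = np.flatnonzero(np.diff(np.floor(phase / (2 * np.pi))) > 0)
    impact = np.zeros(n)
    for s_idx in steps:
        if inten[s_idx] <= 0:
            continue
        s_jit = s_idx + int(rng.uniform(-0.03, 0.03) * fs)
        if not (0 <= s_jit < n):
            continue
        dur = int(rng.uniform(0.04, 0.08) * fs)
        amp = 0.9 * 4.0 * inten[s_idx] * (1.0 + 0.5 * rng.standard_normal())
        kern = amp * np.sin(np.pi * np.arange(dur) / dur)
        stop = min(s_jit + dur, n)
        impact[s_jit:stop] += kern[: stop - s_jit]
    az = az + impact
    ax = ax + 0.3 * impact
    ay = ay + 0.2 * impact

    # band-limited broadband component (tissue wobble, strap vibration,
    # sensor noise), SD rising with intensity above a resting floor; a
    # large broadband fraction is what measured head acceleration shows,
    # and it is what makes the skin model identifiable at all
    # frequencies rather than only at the cadence lines
    sos = signal.butter(4, 10.0, btype="lowpass", fs=fs, output="sos")
    noise_sd = 0.15 + 1.8 * inten
    noise = signal.sosfilt(sos, rng.standard_normal((n, 3)), axis=0)
    noise = noise / np.std(noise, axis=0, keepdims=True).clip(1e-12) * noise_sd[:, None]

    return np.column_stack([ax, ay, az]) + noise


def synth_session(
    protocol: ExerciseProtocol,
    true_params: ArtifactParams,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    template: PulseTemplate | None = None,
    pulse_amp: float = 1.0,
) -> SensorStream:
    """Full synthetic session with ground truth.

    hf = pulse + perfusion baseline + artifact + white noise, where the
    artifact is the second-order model applied to the gravity-subtracted
    acceleration magnitude; cf is an affine map of core temperature plus
    noise.
    """
    if noise_cfg is None:
        noise_cfg = NoiseConfig()
    fs = protocol.sampling_rate
    if true_params.fs != fs:
        raise ValueError("true_params.fs must match the protocol sampling rate")
    rng = np.random.default_rng(seed)
    sub = rng.spawn(3)

    hr, met, temp = physio_profiles(protocol)
    pulse, onsets = synth_pulse_train(
        hr, template=template, fs=fs, seed=int(sub[0].integers(2**31))
    )
    pulse = pulse_amp * pulse
    acc = synth_gait_accel(protocol, seed=int(sub[1].integers(2**31)))
    if noise_cfg.acc_sd > 0:
        acc = acc + noise_cfg.acc_sd * rng.standard_normal(acc.shape)

    a_ref = reference_acceleration(acc)
    artifact = simulate_artifact(a_ref, true_params)
    baseline = BASELINE_OFFSET + BASELINE_PER_W_PER_KG * met

    n = len(pulse)
    hf = pulse + baseline + artifact + noise_cfg.hf_sd * sub[2].standard_normal(n)
    cf = CF_GAIN_V_PER_C * temp + CF_OFFSET_V + noise_cfg.cf_sd * rng.standard_normal(n)

    truth = PhysioGroundTruth(
        heart_rate=hr,
        metabolic_rate=met,
        core_temp=temp,
        clean_pulse=pulse,
        artifact=artifact,
        baseline=baseline,
        onset_indices=onsets,
    )
    t = np.arange(n) / fs
    return SensorStream(t=t, hf=hf, cf=cf, acc=acc, fs=fs, truth=truth)
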