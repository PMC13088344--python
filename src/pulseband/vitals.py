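"""Clean-pulse extraction and vital-sign readout.

Applies the recognized second-order artifact model to produce clean
pulse waveforms, extracts heart rate from a windowed FFT, and converts
the cold-film voltage to forehead temperature through a two-point linear
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .artifact import ArtifactParams, simulate_artifact
from .preprocess import bandpass_pulse, reference_acceleration, segment_beats
from .simulate import SensorStream

__all__ = [
    "TempCalibration",
    "remove_artifact",
    "heart_rate_fft",
    "cold_film_temperature",
    "sliding_vitals",
]

HR_VALID_RANGE = (24.0, 300.0)
TEMP_VALID_RANGE = (25.0, 45.0)


@dataclass(frozen=True)
class TempCalibration:
    """Linear cold-film reading: temperature = gain * volts + offset."""

    gain: float  # deg C per volt
    offset: float  # deg C

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise ValueError("gain must be nonzero")

    @classmethod
    def from_two_points(
        cls, v1: float, t1: float, v2: float, t2: float
    ) -> "TempCalibration":
        if v1 == v2:
            raise ValueError("calibration voltages must differ")
        gain = (t2 - t1) / (v2 - v1)
        return cls(gain=gain, offset=t1 - gain * v1)


def remove_artifact(
    hf: np.ndarray,
    acc: np.ndarray,
    params: ArtifactParams,
    band: tuple[float, float] = (0.5, 5.0),
    zero_phase: bool = False,
) -> np.ndarray:
    """Clean pulse waveform: band-passed hot film minus the band-passed
    reconstructed artifact.

    The artifact is reconstructed from the gravity-subtracted
    acceleration magnitude through the second-order model, then passed
    through the same band-pass as the hot film so that the subtraction
    cancels the artifact's in-band energy exactly (the out-of-band part
    is already rejected by the filter).  Linear in ``hf`` for fixed
    ``acc`` and ``params``.
    """
    hf = np.asarray(hf, float)
    acc = np.asarray(acc, float)
    if acc.shape[0] != hf.shape[0]:
        raise ValueError("hf and acc must be aligned sample-for-sample")
    fs = params.fs
    ma = simulate_artifact(reference_acceleration(acc), params)
    return bandpass_pulse(hf - ma, fs, *band, zero_phase=zero_phase)


def heart_rate_fft(
    pw_window: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.5, 5.0),
    peak_snr: float = 4.0,
) -> float:
    """Heart rate (BPM) from the dominant in-band spectral line.

    Hann-windowed magnitude spectrum restricted to the pulse band; the
    peak bin is refined by quadratic interpolation over its neighbours,
    which lifts the resolution well below the raw bin width (6 BPM for a
    10 s window).  Returns NaN when no peak stands above the noise floor
    (peak < ``peak_snr`` times the median in-band magnitude).
    """
    x = np.asarray(pw_window, float)
    if x.size < 10 * fs:
        raise ValueError("window must be at least 10 s long")
    x = x - np.mean(x)
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * w))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    mag = spec[sel]
    f_band = freqs[sel]
    if mag.size < 3:
        return np.nan
    floor = np.median(mag)
    k = int(np.argmax(mag))
    if floor <= 0 or mag[k] < peak_snr * floor:
        return np.nan
    # quadratic interpolation around the peak bin
    if 0 < k < mag.size - 1:
        a, b, c = mag[k - 1], mag[k], mag[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = f_band[1] - f_band[0]
    return float(60.0 * (f_band[k] + delta * df))


def cold_film_temperature(
    cf: np.ndarray, cal: TempCalibration, fs: float = 100.0, smooth_s: float = 1.0
) -> np.ndarray:
    """Forehead temperature (deg C) from the cold-film voltage.

    Affine conversion followed by a 1 s moving average to suppress
    quantization and thermal noise.
    """
    temp = cal.gain * np.asarray(cf, float) + cal.offset
    win = max(1, int(round(smooth_s * fs)))
    if win > 1:
        # causal moving average with edge correction at the start
        csum = np.cumsum(temp)
        out = np.empty_like(temp)
        out[:win] = csum[:win] / np.arange(1, win + 1)
        out[win:] = (csum[win:] - csum[:-win]) / win
        return out
    return temp


def sliding_vitals(
    stream: SensorStream,
    params: ArtifactParams,
    cal: TempCalibration,
    window_s: float = 10.0,
    hop_s: float = 1.0,
    band: tuple[float, float] = (0.5, 5.0),
    beat_length: int = 100,
) -> pd.DataFrame:
    """One vitals record per second from a trailing 10 s window.

    Artifact removal runs once over the full stream; heart rate is then
    extracted per overlapping window and the per-beat pulse amplitude
    (peak minus trough of each normalized beat in the window) is
    averaged.  Records before the first full window are flagged
    ``warmup``; windows without a credible spectral peak or with a rate
    outside the physiological range are flagged ``invalid_hr``.

    Returns a DataFrame with columns t, hr_bpm, temp_c, pulse_amp,
    flags, at exactly 1/hop_s Hz cadence.
    """
    fs = stream.fs
    pw = remove_artifact(stream.hf, stream.acc, params, band=band)
    temp = cold_film_temperature(stream.cf, cal, fs=fs)
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    n = len(pw)

    rows = []
    for end in range(hop, n + 1, hop):
        t_rec = stream.t[end - 1] + 1.0 / fs
        if end < win:
            rows.append((t_rec, np.nan, temp[end - 1], np.nan, "warmup"))
            continue
        seg = pw[end - win : end]
        hr = heart_rate_fft(seg, fs, band=band)
        flags = ""
        if not np.isfinite(hr) or not (HR_VALID_RANGE[0] <= hr <= HR_VALID_RANGE[1]):
            flags = "invalid_hr"
            hr = np.nan
        t_c = temp[end - 1]
        if not (TEMP_VALID_RANGE[0] <= t_c <= TEMP_VALID_RANGE[1]):
            flags = (flags + ",invalid_temp").lstrip(",")
        beats = segment_beats(seg, fs, n=beat_length)
        amp = float(np.mean(np.ptp(beats.beats, axis=1))) if beats.N else np.nan
        rows.append((t_rec, hr, t_c, amp, flags))

    return pd.DataFrame(rows, columns=["t", "hr_bpm", "temp_c", "pulse_amp", "flags"])
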