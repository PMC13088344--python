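"""Signal conditioning: reference acceleration, band-pass, beat segmentation.

The pulse band of interest is 0.5-5 Hz.  Beats are delimited by the local
minimum immediately preceding each systolic upstroke and time-normalized
to a common length so that beats are directly comparable by Euclidean
distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

STANDARD_GRAVITY = 9.80665  # m/s^2

__all__ = [
    "STANDARD_GRAVITY",
    "BeatSet",
    "reference_acceleration",
    "bandpass_pulse",
    "segment_beats",
]


@dataclass
class BeatSet:
    """Segmented pulse beats, each resampled to a common length ``n``.

    ``beats`` is an (N, n) array; ``onsets`` are the sample indices of
    beat onsets in the source stream (one more than N when the trailing
    onset closed the last beat).
    """

    beats: np.ndarray
    n: int
    onsets: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, float).reshape(-1, self.n)
        self.onsets = np.asarray(self.onsets, int)
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def N(self) -> int:
        return self.beats.shape[0]

    @property
    def empty(self) -> bool:
        return self.N == 0

    def to_csv(self, path) -> None:
        pd.DataFrame(self.beats).to_csv(path, index=False, header=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n": self.n, "onsets": self.onsets.tolist(), "beats": self.beats.tolist()},
                fh,
            )


def reference_acceleration(acc: np.ndarray) -> np.ndarray:
    """Scalar reference acceleration: ||a||_2 minus standard gravity.

    Subtracting gravity from the magnitude (rather than from one axis)
    makes the reference independent of wearing orientation.  The result
    is signed and unclipped: a stationary device reads 0, free fall reads
    -g.
    """
    acc = np.asarray(acc, float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError(f"acc must have shape (n, 3), got {acc.shape}")
    if not np.isfinite(acc).all():
        raise ValueError("acc contains non-finite values")
    return np.linalg.norm(acc, axis=1) - STANDARD_GRAVITY


def _design_bandpass(fs: float, lo: float, hi: float):
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"invalid band [{lo}, {hi}] Hz at fs={fs} Hz")
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_pulse(
    x: np.ndarray,
    fs: float,
    lo: float = 0.5,
    hi: float = 5.0,
    zero_phase: bool = False,
) -> np.ndarray:
    """Band-pass a channel to the pulse band (default 0.5-5 Hz).

    Butterworth design, 4 poles per skirt: rejects baseline drift and DC
    below the band and high-frequency noise above it (>= 20 dB at lo/2
    and 2*hi) with a maximally flat passband.  Causal by default; the
    zero-phase mode (forward-backward filtering) exists for offline
    analysis where group delay matters.
    """
    sos = _design_bandpass(fs, lo, hi)
    x = np.asarray(x, float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def segment_beats(
    pw: np.ndarray,
    fs: float,
    n: int = 100,
    min_period_s: float = 60.0 / 220.0,
    prominence_frac: float = 0.5,
) -> BeatSet:
    """Segment a band-passed pulse waveform into length-normalized beats.

    Systolic peaks are located with a minimum inter-peak distance of
    ``min_period_s`` (default the period of a 220 BPM ceiling) and an
    adaptive prominence threshold (``prominence_frac`` times the median
    prominence of distance-qualified peaks).  Each beat onset is the
    local minimum immediately preceding a systolic peak; the samples
    between successive onsets are linearly resampled to exactly ``n``
    points.

    Returns an empty, flagged :class:`BeatSet` when fewer than two beats
    are detectable (e.g. a constant input).
    """
    pw = np.asarray(pw, float)
    if pw.ndim != 1:
        raise ValueError("pw must be a 1-D series")
    empty = BeatSet(beats=np.empty((0, n)), n=n)
    if pw.size < 3 or np.ptp(pw) == 0.0:
        return empty

    distance = max(1, int(round(min_period_s * fs)))
    peaks, _ = signal.find_peaks(pw, distance=distance)
    if peaks.size < 2:
        return empty
    prominences = signal.peak_prominences(pw, peaks)[0]
    med = np.median(prominences)
    if med <= 0:
        return empty
    keep = prominences >= prominence_frac * med
    peaks = peaks[keep]
    if peaks.size < 2:
        return empty

    # Onset = minimum between the previous kept peak and this peak.
    onsets = []
    for prev, cur in zip(peaks[:-1], peaks[1:]):
        seg = pw[prev:cur]
        onsets.append(prev + int(np.argmin(seg)))
    onsets = np.asarray(onsets, int)
    if onsets.size < 2:
        return empty

    beats = np.empty((onsets.size - 1, n))
    grid = np.arange(n)
    for k, (a, b) in enumerate(zip(onsets[:-1], onsets[1:])):
        src = pw[a : b + 1]
        beats[k] = np.interp(grid * (src.size - 1) / (n - 1), np.arange(src.size), src)
    return BeatSet(beats=beats, n=n, onsets=onsets)
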