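"""Second-order motion-artifact model.

The mechanical coupling between head acceleration and the pressure
disturbance seen by the skin-mounted hot film is modelled as a
spring-damper (second-order LTI) system with transfer function

    MA(s) = K * wn^2 / (s^2 + 2*zeta*wn*s + wn^2) * A(s)

where ``A`` is the scalar reference acceleration (gravity-subtracted
norm of the 3-axis accelerometer), ``K`` a dimensionless gain, ``zeta``
the damping ratio and ``wn`` the undamped natural frequency of the
skin/sensor interface in rad/s.  The model is realized digitally by a
bilinear (Tustin) discretization at the stream sampling rate and run
causally with zero initial state, matching real-time operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["ArtifactParams", "DiscreteFilter", "discretize", "simulate_artifact"]


@dataclass(frozen=True)
class ArtifactParams:
    """Parameters (K, zeta, omega_n) of the artifact transfer function.

    Parameters
    ----------
    K : float
        Dimensionless gain (>= 0).  Absorbs the units of the reference
        acceleration, which this package fixes as m/s^2.
    zeta : float
        Damping ratio (> 0); zeta < 1 gives an underdamped resonance.
    omega_n : float
        Undamped natural frequency in rad/s; its corresponding frequency
        omega_n / (2*pi) must lie below the Nyquist rate.
    fs : float
        Sampling rate in Hz of the streams the filter runs on.
    """

    K: float
    zeta: float
    omega_n: float
    fs: float = 100.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.K, self.zeta, self.omega_n, self.fs]).all():
            raise ValueError("artifact parameters must be finite")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.zeta <= 0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")
        if self.omega_n <= 0:
            raise ValueError(f"omega_n must be > 0, got {self.omega_n}")
        if self.omega_n / (2.0 * np.pi) >= self.fs / 2.0:
            raise ValueError(
                "resonance frequency omega_n/(2*pi) = "
                f"{self.omega_n / (2 * np.pi):.3g} Hz must be below Nyquist "
                f"({self.fs / 2:.3g} Hz)"
            )

    def to_json(self) -> str:
        return json.dumps(
            {"K": self.K, "zeta": self.zeta, "omega_n": self.omega_n, "fs": self.fs}
        )

    @classmethod
    def from_json(cls, text: str) -> "ArtifactParams":
        d = json.loads(text)
        return cls(K=d["K"], zeta=d["zeta"], omega_n=d["omega_n"], fs=d["fs"])


@dataclass
class DiscreteFilter:
    """Digital realization (b, a) of an :class:`ArtifactParams` prototype."""

    b: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        poles = np.roots(self.a)
        if poles.size and np.max(np.abs(poles)) >= 1.0:
            raise ValueError("discretized filter is unstable")

    @property
    def dc_gain(self) -> float:
        return float(np.sum(self.b) / np.sum(self.a))


def discretize(params: ArtifactParams) -> DiscreteFilter:
    """Bilinear-transform discretization of the continuous prototype.

    No pre-warping is applied: at 100 Hz the artifact band sits far below
    Nyquist, where the Tustin frequency warp is negligible, and the
    transform maps the stable prototype to a stable digital filter while
    preserving the DC gain K exactly.
    """
    wn = params.omega_n
    # discretize at unit gain and scale the numerator by K afterwards, so
    # the K = 0 edge case (no artifact) stays well-defined
    num = [wn**2]
    den = [1.0, 2.0 * params.zeta * wn, wn**2]
    b, a = signal.bilinear(num, den, fs=params.fs)
    return DiscreteFilter(b=params.K * np.asarray(b, float), a=np.asarray(a, float))


def simulate_artifact(accel_ref: np.ndarray, params: ArtifactParams) -> np.ndarray:
    """Reconstruct the motion artifact from the reference acceleration.

    Applies the discretized second-order model causally with zero initial
    state, so MA depends only on past samples of ``accel_ref``.
    """
    accel_ref = np.asarray(accel_ref, float)
    if accel_ref.ndim != 1:
        raise ValueError("accel_ref must be a 1-D series")
    if not np.isfinite(accel_ref).all():
        raise ValueError("accel_ref contains non-finite values")
    filt = discretize(params)
    return signal.lfilter(filt.b, filt.a, accel_ref)
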