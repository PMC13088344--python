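import numpy as np
import pytest

from pulseband.artifact import ArtifactParams
from pulseband.simulate import (
    NoiseConfig,
    calibration_protocol,
    default_protocol,
    synth_session,
)

# canonical study conditions used across the suite: artifact with in-band
# RMS comparable to the pulse, moderately damped skin resonance at 6 Hz
TRUE_K = 0.12
TRUE_ZETA = 0.4
TRUE_OMEGA = 2 * np.pi * 6.0


@pytest.fixture(scope="session")
def true_params() -> ArtifactParams:
    return ArtifactParams(K=TRUE_K, zeta=TRUE_ZETA, omega_n=TRUE_OMEGA, fs=100.0)


@pytest.fixture(scope="session")
def cal_stream(true_params):
    """Two minutes of natural running with moderate noise."""
    return synth_session(
        calibration_protocol(), true_params, NoiseConfig(), seed=0
    )


@pytest.fixture(scope="session")
def clean_cal_stream(true_params):
    """Noise-free calibration stream for exact-cancellation checks."""
    return synth_session(
        calibration_protocol(), true_params,
        NoiseConfig(hf_sd=0.0, cf_sd=0.0), seed=0,
    )


@pytest.fixture(scope="session")
def exercise_session(true_params):
    """Six-segment routine, 60 s per segment (desk-scale)."""
    return synth_session(
        default_protocol(segment_s=60.0), true_params, NoiseConfig(), seed=7
    )
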