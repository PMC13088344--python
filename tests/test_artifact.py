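"""Second-order artifact model: discretization and time-domain response."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from pulseband.artifact import ArtifactParams, discretize, simulate_artifact


def make_params(K=1.0, zeta=0.5, omega_hz=5.0, fs=100.0):
    return ArtifactParams(K=K, zeta=zeta, omega_n=2 * np.pi * omega_hz, fs=fs)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"K": -0.1},
            {"zeta": 0.0},
            {"zeta": -0.5},
            {"omega_hz": 0.0},
            {"omega_hz": 60.0},  # above Nyquist at fs=100
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_params(**kwargs)

    def test_json_round_trip(self):
        p = make_params(K=2.5, zeta=0.3, omega_hz=4.0)
        q = ArtifactParams.from_json(p.to_json())
        assert q == p
        assert set(json.loads(p.to_json())) == {"K", "zeta", "omega_n", "fs"}


class TestDiscretize:
    def test_dc_gain_equals_K(self):
        filt = discretize(ArtifactParams(K=2.0, zeta=0.7, omega_n=20.0, fs=100.0))
        assert filt.dc_gain == pytest.approx(2.0, abs=1e-9)

    @given(
        K=st.floats(0.01, 10.0),
        zeta=st.floats(0.1, 2.0),
        omega_hz=st.floats(0.5, 40.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_poles_inside_unit_circle(self, K, zeta, omega_hz):
        filt = discretize(make_params(K=K, zeta=zeta, omega_hz=omega_hz))
        assert np.max(np.abs(np.roots(filt.a))) < 1.0

    @pytest.mark.parametrize("omega_hz,tol", [(2.0, 0.02), (4.0, 0.02), (6.0, 0.02)])
    def test_magnitude_at_resonance_matches_continuous(self, omega_hz, tol):
        """Tustin response at the resonance agrees with the analytic
        continuous |H(j*omega_n)| for resonances well below Nyquist."""
        p = make_params(K=1.0, zeta=0.5, omega_hz=omega_hz)
        filt = discretize(p)
        _, hz = signal.freqz(filt.b, filt.a, worN=np.array([omega_hz]), fs=100)
        s = 1j * p.omega_n
        hc = p.K * p.omega_n**2 / (s**2 + 2 * p.zeta * p.omega_n * s + p.omega_n**2)
        assert abs(abs(hz[0]) - abs(hc)) / abs(hc) < tol


class TestSimulateArtifact:
    def test_zero_input_gives_zero_output(self):
        ma = simulate_artifact(np.zeros(500), make_params())
        assert np.all(ma == 0.0)

    def test_constant_input_reaches_K_times_a(self):
        p = make_params(K=1.5, zeta=0.7, omega_hz=3.0)
        ma = simulate_artifact(np.full(3000, 2.0), p)
        assert ma[-1] == pytest.approx(3.0, rel=1e-6)

    @pytest.mark.parametrize("zeta", [0.3, 0.5, 0.7])
    def test_underdamped_step_overshoot(self, zeta):
        """Peak of the step response matches the closed-form overshoot
        K*(1 + exp(-pi*zeta/sqrt(1-zeta^2))) within 1%."""
        K = 1.3
        p = make_params(K=K, zeta=zeta, omega_hz=2.0)
        ma = simulate_artifact(np.ones(1500), p)
        expected = K * (1 + np.exp(-np.pi * zeta / np.sqrt(1 - zeta**2)))
        assert ma.max() == pytest.approx(expected, rel=0.01)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 800))
        p = make_params(K=0.8, zeta=0.4, omega_hz=5.0)
        lhs = simulate_artifact(2.5 * x - 1.2 * y, p)
        rhs = 2.5 * simulate_artifact(x, p) - 1.2 * simulate_artifact(y, p)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_rejects_non_1d_and_non_finite(self):
        with pytest.raises(ValueError):
            simulate_artifact(np.zeros((10, 2)), make_params())
        with pytest.raises(ValueError):
            simulate_artifact(np.array([0.0, np.nan]), make_params())

    def test_matches_rk4_integration_of_ode(self):
        """Causal digital filter agrees with high-resolution RK4
        integration of the underlying ODE for band-limited input."""
        rng = np.random.default_rng(0)
        x = signal.sosfilt(
            signal.butter(4, 2.5, fs=100, output="sos"), rng.standard_normal(1500)
        )
        p = make_params(K=0.5, zeta=0.4, omega_hz=5.0)
        ma = simulate_artifact(x, p)

        over = 100
        fs_hi = 100 * over
        t_lo = np.arange(len(x)) / 100
        t_hi = np.arange(len(x) * over) / fs_hi
        x_hi = np.interp(t_hi, t_lo, x)
        dt = 1.0 / fs_hi
        w2, z2 = p.omega_n**2, 2 * p.zeta * p.omega_n
        state = np.zeros(2)
        out = np.empty(len(x_hi))
        for i in range(len(x_hi)):
            u = x_hi[i]

            def d(s):
                return np.array([s[1], p.K * w2 * u - z2 * s[1] - w2 * s[0]])

            k1 = d(state)
            k2 = d(state + dt / 2 * k1)
            k3 = d(state + dt / 2 * k2)
            k4 = d(state + dt * k3)
            state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            out[i] = state[0]
        ma_ref = out[::over]
        rel = np.sqrt(np.mean((ma - ma_ref) ** 2) / np.mean(ma_ref**2))
        assert rel < 0.005
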