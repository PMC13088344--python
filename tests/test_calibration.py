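"""Beat-distance objective, GP surrogate, Expected Improvement, calibrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pulseband.artifact import ArtifactParams
from pulseband.calibration import (
    ArtifactCalibrator,
    CalibConfig,
    InsufficientBeatsError,
    SearchSpace,
    SurrogateState,
    evaluate_candidate,
    expected_improvement,
    fit_gp_hyperparams,
    gp_posterior,
    matern52_ard,
    normalized_distance,
    objective,
)
from pulseband.preprocess import BeatSet


def random_beats(n_beats, n=20, seed=0):
    rng = np.random.default_rng(seed)
    return BeatSet(beats=rng.standard_normal((n_beats, n)), n=n)


class TestNormalizedDistance:
    def test_identity_is_zero(self):
        p = np.arange(5.0)
        assert normalized_distance(p, p, 5) == 0.0

    def test_hand_computed_example(self):
        d = normalized_distance(np.zeros(4), np.ones(4), 4)
        assert d == pytest.approx(0.5)  # ||1,1,1,1|| / 4 = 2/4

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 10))
        assert normalized_distance(a, b, 10) == normalized_distance(b, a, 10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalized_distance(np.zeros(4), np.zeros(5), 4)


class TestObjective:
    def test_identical_beats_give_zero(self):
        beats = BeatSet(beats=np.tile(np.arange(10.0), (6, 1)), n=10)
        assert objective(beats, m=20, seed=0) == 0.0

    def test_two_beats_closed_form(self):
        u, v = np.zeros(8), np.ones(8)
        beats = BeatSet(beats=np.vstack([u, v]), n=8)
        d_uv = normalized_distance(u, v, 8)
        assert objective(beats, m=20, seed=0) == pytest.approx(d_uv / 2)

    @pytest.mark.parametrize("n_beats", [3, 10, 25, 50])
    def test_full_subsample_equals_brute_force(self, n_beats):
        """With m = N the objective is the plain double-sum mean."""
        beats = random_beats(n_beats, seed=n_beats)
        brute = np.mean(
            [
                np.linalg.norm(beats.beats[i] - beats.beats[j]) / beats.n
                for i in range(n_beats)
                for j in range(n_beats)
            ]
        )
        assert objective(beats, m=n_beats, seed=1) == pytest.approx(brute, abs=1e-14)

    def test_reordering_invariance_at_full_subsample(self):
        beats = random_beats(12, seed=4)
        perm = np.random.default_rng(0).permutation(12)
        shuffled = BeatSet(beats=beats.beats[perm], n=beats.n)
        assert objective(beats, m=12, seed=2) == pytest.approx(
            objective(shuffled, m=12, seed=2), abs=1e-14
        )

    def test_uniform_shift_invariance(self):
        """Rolling every beat by the same offset leaves all pairwise
        distances, hence the objective, unchanged."""
        beats = random_beats(15, seed=5)
        rolled = BeatSet(beats=np.roll(beats.beats, 7, axis=1), n=beats.n)
        assert objective(beats, m=20, seed=3) == pytest.approx(
            objective(rolled, m=20, seed=3), abs=1e-14
        )

    def test_single_beat_rejected(self):
        with pytest.raises(InsufficientBeatsError):
            objective(random_beats(1), m=20, seed=0)


def random_state(t, seed):
    rng = np.random.default_rng(seed)
    return SurrogateState(
        X=rng.uniform(size=(t, 3)),
        y=rng.standard_normal(t),
        length_scales=rng.uniform(0.1, 2.0, 3),
        signal_var=float(rng.uniform(0.5, 2.0)),
        noise_var=float(rng.uniform(1e-4, 1e-2)),
    )


class TestGP:
    def test_interpolates_training_point_at_tiny_noise(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(5, 3))
        y = rng.standard_normal(5)
        st_ = SurrogateState(X, y, np.full(3, 0.5), 1.0, 1e-12)
        mu, var = gp_posterior(st_, X[2])
        assert mu == pytest.approx(y[2], abs=1e-4)
        assert var < 1e-6

    def test_reverts_to_prior_far_away(self):
        st_ = random_state(6, seed=1)
        far = st_.X[0] + 100.0
        mu, var = gp_posterior(st_, far)
        assert abs(mu) < 1e-6                      # zero prior mean
        assert var == pytest.approx(st_.signal_var, rel=1e-6)

    def test_matches_dense_solve_oracle(self):
        """Posterior mean/variance equal the direct matrix-inversion
        formulas on small random states."""
        for seed in range(10):
            st_ = random_state(3 + seed, seed)
            xs = np.random.default_rng(seed + 100).uniform(size=3)
            mu, var = gp_posterior(st_, xs)
            K = matern52_ard(st_.X, st_.X, st_.length_scales, st_.signal_var)
            ks = matern52_ard(st_.X, xs[None, :], st_.length_scales, st_.signal_var).ravel()
            A_inv = np.linalg.inv(K + st_.noise_var * np.eye(len(st_.y)))
            mu_ref = ks @ A_inv @ st_.y
            var_ref = st_.signal_var - ks @ A_inv @ ks
            assert mu == pytest.approx(mu_ref, abs=1e-8)
            assert var == pytest.approx(max(var_ref, 0.0), abs=1e-8)

    def test_variance_clamped_nonnegative(self):
        st_ = random_state(12, seed=3)
        _, var = gp_posterior(st_, st_.X)
        assert np.all(var >= 0.0)

    def test_hyperparameter_fit_returns_valid_state(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(15, 3))
        y = np.sin(3 * X[:, 0]) + 0.1 * rng.standard_normal(15)
        st_ = fit_gp_hyperparams(X, y - y.mean(), seed=0)
        assert np.all(st_.length_scales > 0)
        assert st_.signal_var > 0 and st_.noise_var > 0


class TestExpectedImprovement:
    def test_deterministic_improvement_branch(self):
        assert expected_improvement(0.5, 0.0, 1.0) == pytest.approx(0.5)

    def test_no_improvement_branch(self):
        assert expected_improvement(1.5, 0.0, 1.0) == 0.0

    def test_at_incumbent_with_unit_sigma(self):
        # EI = sigma * phi(0) = 1/sqrt(2*pi)
        assert expected_improvement(1.0, 1.0, 1.0) == pytest.approx(
            1.0 / np.sqrt(2 * np.pi), abs=1e-6
        )

    @given(
        mu=st.floats(-3, 3),
        sigma=st.floats(0, 2),
        f_min=st.floats(-3, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_everywhere(self, mu, sigma, f_min):
        assert expected_improvement(mu, sigma, f_min) >= 0.0

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            mu, sigma = rng.normal(), rng.uniform(0.1, 2.0)
            f_min = rng.normal()
            draws = rng.normal(mu, sigma, size=200_000)
            imp = np.maximum(f_min - draws, 0.0)
            mc, se = imp.mean(), imp.std() / np.sqrt(len(imp))
            # absolute epsilon covers the far-tail case where no draw improves
            assert abs(expected_improvement(mu, sigma, f_min) - mc) < 3 * se + 1e-9


class TestEvaluateCandidate:
    def test_zero_gain_equals_raw_objective(self, true_params):
        """On an artifact-free stream, a K=0 candidate reproduces the
        objective of the raw stream (subtracting nothing)."""
        from pulseband.simulate import NoiseConfig, calibration_protocol, synth_session

        p0 = ArtifactParams(K=0.0, zeta=0.4, omega_n=true_params.omega_n, fs=100)
        s = synth_session(calibration_protocol(60.0), p0, NoiseConfig(), seed=2)
        cfg = CalibConfig(seed=0)
        f_k0 = evaluate_candidate(s, [0.0, 0.7, 2 * np.pi * 10], cfg)
        f_k0b = evaluate_candidate(s, [0.0, 0.2, 2 * np.pi * 3], cfg)
        assert f_k0 == pytest.approx(f_k0b, abs=1e-14)

    def test_determinism(self, cal_stream):
        cfg = CalibConfig(seed=5)
        x = [0.1, 0.5, 2 * np.pi * 5]
        assert evaluate_candidate(cal_stream, x, cfg) == evaluate_candidate(
            cal_stream, x, cfg
        )

    def test_true_parameters_beat_perturbations(self, cal_stream, true_params):
        cfg = CalibConfig(seed=0)
        x0 = [true_params.K, true_params.zeta, true_params.omega_n]
        f0 = evaluate_candidate(cal_stream, x0, cfg)
        for dx in ([0.08, 0, 0], [0, 0.3, 0], [0, 0, 2 * np.pi * 2]):
            f = evaluate_candidate(cal_stream, np.add(x0, dx), cfg)
            assert f > f0


class TestSearchSpace:
    def test_unit_cube_round_trip(self):
        sp = SearchSpace(k_max=2.0)
        x = np.array([0.7, 0.9, 2 * np.pi * 7.3])
        np.testing.assert_allclose(sp.from_unit(sp.to_unit(x)), x, rtol=1e-12)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(k_max=0.0)
        with pytest.raises(ValueError):
            SearchSpace(zeta_bounds=(1.0, 0.5))


class TestCalibrator:
    def test_short_run_is_deterministic_and_monotone(self, cal_stream):
        kwargs = dict(n_init=4, max_iters=3, polish=False, seed=11)
        cal1 = ArtifactCalibrator(**kwargs).fit(cal_stream)
        cal2 = ArtifactCalibrator(**kwargs).fit(cal_stream)
        assert cal1.params_ == cal2.params_
        # running minimum of observed objective values never increases
        run_min = np.minimum.accumulate(cal1.y_)
        assert np.all(np.diff(run_min) <= 0)

    def test_sklearn_params_round_trip(self):
        cal = ArtifactCalibrator(seed=3, max_iters=7)
        assert ArtifactCalibrator(**cal.get_params()).get_params() == cal.get_params()
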