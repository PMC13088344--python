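"""Artifact-parameter recognition by Bayesian optimization.

The gain, damping ratio and natural frequency (K, zeta, omega_n) of the
second-order artifact model are user- and wearing-dependent, so they are
recognized on a short calibration recording (two minutes of natural
running).  The objective exploits the quasi-periodicity of the pulse:
when the artifact model is right, subtracting the reconstructed artifact
leaves consecutive beats nearly identical, so the average normalized
Euclidean distance between beats

    D_ij = ||P_i - P_j||_2 / n
    f(x) = sum_{i in S} sum_{j=1..N} D_ij / (m * N)

(with S a random subsample of m = 20 beats for efficiency) is minimized
over x = [K, zeta, omega_n].  f is noisy and derivative-free, so it is
modelled with a zero-mean Gaussian process (ARD Matern 5/2 kernel,
Gaussian observation noise) and minimized by maximizing Expected
Improvement over the search space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .artifact import ArtifactParams, simulate_artifact
from .preprocess import BeatSet, bandpass_pulse, reference_acceleration, segment_beats
from .simulate import SensorStream

__all__ = [
    "InsufficientBeatsError",
    "CalibrationError",
    "SearchSpace",
    "SurrogateState",
    "CalibConfig",
    "normalized_distance",
    "objective",
    "evaluate_candidate",
    "matern52_ard",
    "gp_posterior",
    "fit_gp_hyperparams",
    "expected_improvement",
    "ArtifactCalibrator",
    "calibrate",
]


class InsufficientBeatsError(ValueError):
    """Fewer than two beats available to compare."""


class CalibrationError(RuntimeError):
    """Calibration could not evaluate the objective anywhere."""


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def normalized_distance(p_i: np.ndarray, p_j: np.ndarray, n: int) -> float:
    """Euclidean distance between two length-n beats, divided by n."""
    p_i = np.asarray(p_i, float)
    p_j = np.asarray(p_j, float)
    if p_i.shape != (n,) or p_j.shape != (n,):
        raise ValueError(f"both beats must have length {n}")
    return float(np.linalg.norm(p_i - p_j) / n)


def objective(beats: BeatSet, m: int = 20, seed: int = 0) -> float:
    """Average normalized distance from m sampled beats to all beats.

    ``m`` is capped at the beat count N (with N < 20 the sum runs over
    every beat and equals the full double-sum mean).  The subsample is a
    seeded uniform draw without replacement implemented by priority
    sampling (each beat gets a seeded uniform score; the m smallest
    scores win).  This is distributionally a plain uniform subsample,
    but it is stable under small changes of N — during calibration the
    beat count shifts by a beat or two between candidate filters, and a
    draw that reshuffled completely would make the objective needlessly
    discontinuous in the parameters.
    """
    if beats.N < 2:
        raise InsufficientBeatsError(
            f"need at least 2 beats to compare, got {beats.N}"
        )
    m_eff = min(m, beats.N)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random(beats.N))[:m_eff]
    d = cdist(beats.beats[idx], beats.beats) / beats.n
    return float(d.sum() / (m_eff * beats.N))


@dataclass(frozen=True)
class CalibConfig:
    """Settings of the candidate-evaluation pipeline and the BO loop."""

    band: tuple[float, float] = (0.5, 5.0)
    beat_length: int = 100
    m_subsample: int = 20
    n_init: int = 8
    max_iters: int = 40
    ei_tol: float = 1e-8
    seed: int = 0


def _candidate_pipeline(
    bp_hf: np.ndarray,
    a_ref: np.ndarray,
    x: np.ndarray,
    fs: float,
    cfg: CalibConfig,
) -> float:
    params = ArtifactParams(K=float(x[0]), zeta=float(x[1]), omega_n=float(x[2]), fs=fs)
    ma = simulate_artifact(a_ref, params)
    pw = bp_hf - bandpass_pulse(ma, fs, *cfg.band)
    beats = segment_beats(pw, fs, n=cfg.beat_length)
    return objective(beats, m=cfg.m_subsample, seed=cfg.seed)


def evaluate_candidate(
    stream: SensorStream, x: np.ndarray, cfg: CalibConfig | None = None
) -> float:
    """Objective value of one parameter vector x = [K, zeta, omega_n].

    Pipeline: reference acceleration -> artifact reconstruction with x ->
    subtraction from the band-passed hot film -> beat segmentation ->
    inter-beat distance objective.  Deterministic given (stream, x,
    cfg.seed).
    """
    if cfg is None:
        cfg = CalibConfig()
    bp_hf = bandpass_pulse(stream.hf, stream.fs, *cfg.band)
    a_ref = reference_acceleration(stream.acc)
    return _candidate_pipeline(bp_hf, a_ref, np.asarray(x, float), stream.fs, cfg)


# ---------------------------------------------------------------------------
# Gaussian-process surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Box bounds of the parameter search.

    Defaults: damping ratio in [0.05, 1.5]; natural frequency spanning
    1-30 Hz (in rad/s); the gain upper bound should be set from the data
    (see :meth:`ArtifactCalibrator`), defaulting to 5.

    The natural frequency is mapped to the surrogate's unit cube on a
    log scale: frequencies compare multiplicatively, and a linear map
    over a 30:1 range stretches the low-frequency region where skin
    resonances live into a sliver.
    """

    k_max: float = 5.0
    zeta_bounds: tuple[float, float] = (0.05, 1.5)
    omega_bounds: tuple[float, float] = (2 * np.pi * 1.0, 2 * np.pi * 30.0)

    def __post_init__(self) -> None:
        for lo, hi in ((0.0, self.k_max), self.zeta_bounds, self.omega_bounds):
            if not lo < hi:
                raise ValueError("lower bound must be below upper bound")
        if self.omega_bounds[0] <= 0:
            raise ValueError("omega bounds must be positive")

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 1
        x2 = np.atleast_2d(x)
        out = np.empty_like(x2)
        out[:, 0] = x2[:, 0] / self.k_max
        zl, zh = self.zeta_bounds
        out[:, 1] = (x2[:, 1] - zl) / (zh - zl)
        wl, wh = np.log(self.omega_bounds)
        out[:, 2] = (np.log(x2[:, 2]) - wl) / (wh - wl)
        return out[0] if single else out

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, float)
        single = u.ndim == 1
        u2 = np.atleast_2d(u)
        out = np.empty_like(u2)
        out[:, 0] = u2[:, 0] * self.k_max
        zl, zh = self.zeta_bounds
        out[:, 1] = zl + u2[:, 1] * (zh - zl)
        wl, wh = np.log(self.omega_bounds)
        out[:, 2] = np.exp(wl + u2[:, 2] * (wh - wl))
        return out[0] if single else out


@dataclass
class SurrogateState:
    """GP training set and hyperparameters.

    ``X`` holds the t evaluated parameter vectors (rows, already scaled
    to the unit cube); ``y`` the observed objective values.
    """

    X: np.ndarray
    y: np.ndarray
    length_scales: np.ndarray
    signal_var: float
    noise_var: float

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.y = np.asarray(self.y, float).ravel()
        self.length_scales = np.asarray(self.length_scales, float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows and y must agree")
        if self.signal_var <= 0 or self.noise_var <= 0:
            raise ValueError("variances must be > 0")
        if np.any(self.length_scales <= 0):
            raise ValueError("length scales must be > 0")


def matern52_ard(
    X1: np.ndarray, X2: np.ndarray, length_scales: np.ndarray, signal_var: float
) -> np.ndarray:
    """ARD Matern 5/2 kernel:
    k = sf2 * (1 + sqrt5*r + 5 r^2 / 3) * exp(-sqrt5*r),
    r^2 = sum_d (x_d - x'_d)^2 / l_d^2."""
    X1 = np.atleast_2d(X1) / length_scales
    X2 = np.atleast_2d(X2) / length_scales
    r = cdist(X1, X2)
    s5r = np.sqrt(5.0) * r
    return signal_var * (1.0 + s5r + s5r**2 / 3.0) * np.exp(-s5r)


_JITTER = 1e-8


def _chol_solve(state: SurrogateState):
    K = matern52_ard(state.X, state.X, state.length_scales, state.signal_var)
    base = K + state.noise_var * np.eye(len(state.y))
    # escalate jitter only when the clean system is numerically singular
    for jitter in (0.0, _JITTER, 1e-6, 1e-4):
        try:
            L = np.linalg.cholesky(base + jitter * np.eye(len(state.y)))
            break
        except np.linalg.LinAlgError:
            continue
    else:  # pragma: no cover - pathological
        raise np.linalg.LinAlgError("GP system singular beyond jitter tolerance")
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, state.y))
    return L, alpha


def gp_posterior(state: SurrogateState, x_star: np.ndarray):
    """Posterior mean and variance of f at query points.

    mu = k*^T (K + sn2 I)^-1 y ;  s2 = k(x*,x*) - k*^T (K + sn2 I)^-1 k*
    with zero prior mean.  Variance is clamped at 0 from below.
    Accepts a single point (1-D) or a batch (2-D, one row per point).
    """
    x_star = np.asarray(x_star, float)
    single = x_star.ndim == 1
    Xs = np.atleast_2d(x_star)
    L, alpha = _chol_solve(state)
    Ks = matern52_ard(state.X, Xs, state.length_scales, state.signal_var)
    mu = Ks.T @ alpha
    v = np.linalg.solve(L, Ks)
    var = state.signal_var - np.sum(v**2, axis=0)
    var = np.maximum(var, 0.0)
    if single:
        return float(mu[0]), float(var[0])
    return mu, var


def _log_marginal_likelihood(state: SurrogateState) -> float:
    L, alpha = _chol_solve(state)
    return float(
        -0.5 * state.y @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * len(state.y) * np.log(2 * np.pi)
    )


def fit_gp_hyperparams(
    X: np.ndarray, y: np.ndarray, seed: int = 0, n_starts: int = 3
) -> SurrogateState:
    """Fit (length_scales, signal_var, noise_var) by maximizing the log
    marginal likelihood with multi-start L-BFGS-B in log space.

    ``X`` must already be scaled to the unit cube.  ``y`` should be
    centered by the caller if a zero prior mean is assumed.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    d = X.shape[1]
    vy = max(float(np.var(y)), 1e-12)
    rng = np.random.default_rng(seed)

    def neg_lml(theta: np.ndarray) -> float:
        ls = np.exp(theta[:d])
        sf2 = np.exp(theta[d])
        sn2 = np.exp(theta[d + 1])
        try:
            state = SurrogateState(X, y, ls, sf2, sn2)
            return -_log_marginal_likelihood(state)
        except np.linalg.LinAlgError:
            return 1e10

    base = np.concatenate([np.log(np.full(d, 0.3)), [np.log(vy)], [np.log(1e-3 * vy)]])
    lo = np.concatenate([np.log(np.full(d, 0.02)), [np.log(1e-6 * vy)], [np.log(1e-9 * vy)]])
    hi = np.concatenate([np.log(np.full(d, 10.0)), [np.log(1e3 * vy)], [np.log(1e1 * vy)]])
    bounds = list(zip(lo, hi))

    best_theta, best_val = base, neg_lml(base)
    starts = [base] + [
        np.clip(base + rng.normal(0, 1.0, size=base.size), lo, hi)
        for _ in range(n_starts - 1)
    ]
    for th0 in starts:
        res = optimize.minimize(
            neg_lml, th0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 60},
        )
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    ls = np.exp(best_theta[:d])
    return SurrogateState(X, y, ls, float(np.exp(best_theta[d])),
                          float(np.exp(best_theta[d + 1])))


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def expected_improvement(mu, sigma, f_min) -> np.ndarray | float:
    """Closed-form EI for minimization:
    EI = (f_min - mu) * Phi(z) + sigma * phi(z),  z = (f_min - mu)/sigma,
    reducing to max(f_min - mu, 0) when sigma = 0."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    scalar = mu.ndim == 0
    mu, sigma = np.atleast_1d(mu), np.atleast_1d(sigma)
    ei = np.maximum(f_min - mu, 0.0)
    pos = sigma > 0
    if np.any(pos):
        z = (f_min - mu[pos]) / sigma[pos]
        ei_pos = (f_min - mu[pos]) * stats.norm.cdf(z) + sigma[pos] * stats.norm.pdf(z)
        ei = ei.copy()
        ei[pos] = np.maximum(ei_pos, 0.0)
    return float(ei[0]) if scalar else ei


def _maximize_ei(
    state: SurrogateState, f_min: float, rng: np.random.Generator,
    n_starts: int = 64, n_refine: int = 4,
) -> tuple[np.ndarray, float]:
    """Seeded random multi-start + local refinement of EI in the unit cube.

    Candidates mix global uniform draws with Gaussian perturbations of
    the incumbent (best posterior mean), since the EI surface is often
    sharply peaked near the current best and uniform draws alone descend
    flat valleys very slowly.
    """
    d = state.X.shape[1]
    mu_obs, _ = gp_posterior(state, state.X)
    incumbent = state.X[int(np.argmin(mu_obs))]
    local = np.clip(
        incumbent + 0.08 * rng.standard_normal((n_starts, d)), 0.0, 1.0
    )
    cand = np.vstack([rng.uniform(size=(n_starts, d)), local])
    mu, var = gp_posterior(state, cand)
    ei = expected_improvement(mu, np.sqrt(var), f_min)
    order = np.argsort(ei)[::-1]

    def neg_ei(u: np.ndarray) -> float:
        m, v = gp_posterior(state, u)
        return -expected_improvement(m, np.sqrt(v), f_min)

    best_u, best_ei = cand[order[0]], float(ei[order[0]])
    for i in order[:n_refine]:
        res = optimize.minimize(
            neg_ei, cand[i], method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d, options={"maxiter": 40},
        )
        if -res.fun > best_ei:
            best_ei, best_u = float(-res.fun), np.clip(res.x, 0.0, 1.0)
    return best_u, best_ei


# ---------------------------------------------------------------------------
# Calibrator
# ---------------------------------------------------------------------------

class ArtifactCalibrator(BaseEstimator):
    """Recognize (K, zeta, omega_n) on a calibration stream.

    scikit-learn-style estimator: :meth:`fit` takes a
    :class:`~pulseband.simulate.SensorStream` (two minutes of natural
    running is the intended condition) and exposes the recognized
    parameters as ``params_``.

    Parameters
    ----------
    space : SearchSpace, optional
        Box bounds; when omitted, the gain bound K_max is set to three
        times the ratio of hot-film RMS (mean removed) to
        reference-acceleration RMS, which keeps the degenerate
        over-subtraction regime out of reach.
    n_init : int
        Random initial evaluations before the GP loop (default 8).
    max_iters : int
        Maximum BO iterations after initialization (default 40).
    ei_tol : float
        Stop when the maximal Expected Improvement falls below this.
    polish : bool
        Run a bounded Nelder-Mead refinement of the objective from the
        BO incumbent after the loop (default True).  Bayesian
        optimization is sample-efficient globally but slow to sharpen a
        local optimum; the hybrid global+local strategy is standard.
    seed : int
        Controls initialization, the objective's beat subsample, GP
        fitting restarts and EI multi-starts.

    Attributes
    ----------
    params_ : ArtifactParams
        Recognized artifact model (argmin of GP posterior means over the
        evaluated points).
    X_, y_ : ndarray
        Evaluated parameter vectors (original units) and objective
        values.
    surrogate_ : SurrogateState
        Final fitted GP (unit-cube inputs, centered y).
    report_ : dict
        Iteration trace: evaluated points, values, chosen optimum.
    """

    def __init__(
        self,
        space: Optional[SearchSpace] = None,
        band: tuple[float, float] = (0.5, 5.0),
        beat_length: int = 100,
        m_subsample: int = 20,
        n_init: int = 8,
        max_iters: int = 40,
        ei_tol: float = 1e-8,
        polish: bool = True,
        seed: int = 0,
    ):
        self.space = space
        self.band = band
        self.beat_length = beat_length
        self.m_subsample = m_subsample
        self.n_init = n_init
        self.max_iters = max_iters
        self.ei_tol = ei_tol
        self.polish = polish
        self.seed = seed

    def _cfg(self) -> CalibConfig:
        return CalibConfig(
            band=self.band,
            beat_length=self.beat_length,
            m_subsample=self.m_subsample,
            n_init=self.n_init,
            max_iters=self.max_iters,
            ei_tol=self.ei_tol,
            seed=self.seed,
        )

    def _polish(self, u_best, f_best, fx, bp_hf, a_ref, fs, space, cfg):
        """Residual-power refinement of the BO incumbent.

        The similarity objective is slightly rugged in the parameters
        (beats enter and leave the segmentation as the candidate filter
        changes), which stalls purely local optimizers near the optimum.
        The polish therefore *proposes* candidates by minimizing a
        smooth, segmentation-free surrogate — the variance of the
        filtered waveform, the classic adaptive-noise-cancellation
        criterion: the pulse is uncorrelated with the reference
        acceleration, so any remaining reduction in output power can
        only come from cancelling artifact.  For fixed (zeta, omega_n)
        the optimal gain has the least-squares closed form, leaving a
        smooth 2-D problem.  A proposal is accepted only if it improves
        the full inter-beat objective, so the polish can never degrade
        the BO result and the similarity criterion keeps the final say.
        """

        def residual_power(zeta: float, omega_n: float):
            """Profiled least-squares gain and residual variance."""
            p1 = ArtifactParams(K=1.0, zeta=zeta, omega_n=omega_n, fs=fs)
            ma1 = bandpass_pulse(simulate_artifact(a_ref, p1), fs, *cfg.band)
            denom = float(ma1 @ ma1)
            if denom <= 0:
                return 0.0, float(bp_hf @ bp_hf)
            k_star = float(bp_hf @ ma1) / denom
            k_star = float(np.clip(k_star, 0.0, space.k_max))
            resid = bp_hf - k_star * ma1
            return k_star, float(resid @ resid)

        def g(v: np.ndarray) -> float:
            # v = (zeta, omega) in the unit square of the search space
            x = space.from_unit(np.array([0.0, v[0], v[1]]))
            return residual_power(x[1], x[2])[1]

        de = optimize.differential_evolution(
            g, bounds=[(0.0, 1.0), (0.0, 1.0)], seed=self.seed,
            maxiter=30, popsize=12, tol=1e-12, init="sobol", polish=False,
        )
        res = optimize.minimize(
            g, np.clip(de.x, 0, 1), method="Powell",
            bounds=[(0.0, 1.0)] * 2,
            options={"maxiter": 60, "xtol": 1e-6, "ftol": 1e-12},
        )
        v = np.clip(res.x, 0.0, 1.0)
        x_zw = space.from_unit(np.array([0.0, v[0], v[1]]))
        k_star, _ = residual_power(x_zw[1], x_zw[2])
        u_cand = space.to_unit(np.array([k_star, x_zw[1], x_zw[2]]))
        u_cand = np.clip(u_cand, 0.0, 1.0)
        f_cand = fx(u_cand)
        if not np.isnan(f_cand) and f_cand < f_best:
            u_best, f_best = u_cand, float(f_cand)
        return u_best, f_best

    def fit(self, stream: SensorStream, y=None) -> "ArtifactCalibrator":
        cfg = self._cfg()
        rng = np.random.default_rng(self.seed)
        fs = stream.fs
        bp_hf = bandpass_pulse(stream.hf, fs, *cfg.band)
        a_ref = reference_acceleration(stream.acc)

        space = self.space
        if space is None:
            a_rms = float(np.std(a_ref))
            hf_rms = float(np.std(stream.hf))
            k_max = 3.0 * hf_rms / max(a_rms, 1e-9)
            space = SearchSpace(k_max=k_max)
        self.space_ = space

        def fx(u: np.ndarray) -> float:
            x = space.from_unit(u)
            try:
                return _candidate_pipeline(bp_hf, a_ref, x, fs, cfg)
            except InsufficientBeatsError:
                return np.nan

        U = list(rng.uniform(size=(cfg.n_init, 3)))
        y_obs = [fx(u) for u in U]
        if np.all(np.isnan(y_obs)):
            raise CalibrationError("no candidate produced a usable beat set")

        for it in range(cfg.max_iters):
            mask = ~np.isnan(y_obs)
            Xu = np.asarray(U)[mask]
            yv = np.asarray(y_obs)[mask]
            shift = float(np.mean(yv))
            state = fit_gp_hyperparams(
                Xu, yv - shift, seed=self.seed + it, n_starts=3
            )
            mu_obs, _ = gp_posterior(state, Xu)
            f_min = float(np.min(mu_obs))
            u_next, ei = _maximize_ei(state, f_min, rng)
            if ei < cfg.ei_tol:
                break
            U.append(u_next)
            y_obs.append(fx(u_next))

        mask = ~np.isnan(y_obs)
        Xu = np.asarray(U)[mask]
        yv = np.asarray(y_obs)[mask]
        shift = float(np.mean(yv))
        state = fit_gp_hyperparams(Xu, yv - shift, seed=self.seed, n_starts=3)
        mu_obs, _ = gp_posterior(state, Xu)
        best = int(np.argmin(mu_obs))
        u_best, f_best = Xu[best], yv[best]

        if self.polish:
            u_best, f_best = self._polish(
                u_best, f_best, fx, bp_hf, a_ref, fs, space, cfg
            )
        x_best = space.from_unit(u_best)

        self.surrogate_ = state
        self.X_ = space.from_unit(Xu)
        self.y_ = yv
        self.params_ = ArtifactParams(
            K=float(x_best[0]), zeta=float(x_best[1]),
            omega_n=float(x_best[2]), fs=fs,
        )
        self.report_ = {
            "seed": self.seed,
            "evaluated_x": self.X_.tolist(),
            "evaluated_f": self.y_.tolist(),
            "posterior_mean_at_x": np.asarray(mu_obs + shift).tolist(),
            "chosen_x": x_best.tolist(),
            "n_evaluations": int(len(self.y_)),
        }
        return self


def calibrate(
    stream: SensorStream,
    space: Optional[SearchSpace] = None,
    cfg: Optional[CalibConfig] = None,
) -> ArtifactParams:
    """Functional wrapper over :class:`ArtifactCalibrator`."""
    cfg = cfg or CalibConfig()
    cal = ArtifactCalibrator(
        space=space, band=cfg.band, beat_length=cfg.beat_length,
        m_subsample=cfg.m_subsample, n_init=cfg.n_init,
        max_iters=cfg.max_iters, ei_tol=cfg.ei_tol, seed=cfg.seed,
    )
    cal.fit(stream)
    return cal.params_
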