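# Methods

This note documents the models, algorithms, default parameters and
design decisions behind `pulseband`, in the package's own words.

## Problem setting

A thermal-sensing headband measures three synchronized channels at
100 Hz: a self-heated **hot film** whose output follows skin thermal
conductance (carrying the arterial pulse waveform and a slow perfusion
baseline), an unheated **cold film** that is a linear skin-temperature
sensor, and a 3-axis head **accelerometer**. During exercise the pulse
channel is contaminated by motion artifact. The pipeline (i) models and
removes that artifact, (ii) extracts heart rate and forehead
temperature, and (iii) estimates total metabolic rate from
time-frequency representations of all three channels.

## Motion-artifact model

Skin deformation under the sensor responds to head acceleration like a
spring-damper system, so the acceleration-to-artifact mapping is a
second-order LTI transfer function

    MA(s) = K·ωn² / (s² + 2ζωn·s + ωn²) · A(s)

with gain `K` (dimensionless; the reference acceleration is fixed in
m/s², any unit change is absorbed into K), damping ratio `ζ` and
natural frequency `ωn` (rad/s). The reference `A` is the Euclidean norm
of the 3-axis acceleration minus standard gravity (9.80665 m/s²), which
makes it independent of wearing orientation; it is signed and
unclipped.

The filter is realized digitally by the bilinear (Tustin) transform
without pre-warping: at 100 Hz the artifact band lies far below
Nyquist, where frequency warping is negligible (verified: the
discretized magnitude at resonance agrees with the analytic continuous
response to ≤1.3 % for resonances up to 6 Hz, degrading to ≈2 % at 8 Hz
and ≈3.5 % at 10 Hz). Discretization happens at unit gain with the
numerator scaled by K afterwards, so K = 0 (no artifact) is
well-defined. Filtering is causal with zero initial state — the device
operates in real time; a zero-phase mode exists for offline analysis
only.

Artifact removal computes `PW = bandpass(hf − MA)`. Applying the same
band-pass to the reconstructed artifact (equivalently, filtering the
difference) is deliberate: it cancels the artifact's in-band energy
exactly, while out-of-band artifact is rejected by the filter anyway.
Subtracting the raw (unfiltered) artifact from the band-passed channel
would leave a residual equal to the artifact's out-of-band content
passed through neither path consistently.

## Signal conditioning

* **Band-pass**: Butterworth, 4 poles per skirt (scipy `butter(4, ...)`
  band-pass), 0.5–5 Hz — the physiological pulse band. Measured
  response: ≥26 dB attenuation at 0.25 Hz and 10 Hz (contract: ≥20 dB
  at half the low edge and twice the high edge), ≤1 dB passband
  ripple.
* **Beat segmentation**: systolic peaks via prominence-filtered peak
  picking (minimum inter-peak distance 60/220 s ≈ 0.27 s; adaptive
  threshold at 0.5× the median prominence), beat onset = local minimum
  between successive systolic peaks, each beat linearly resampled to
  n = 100 samples. n = 100 keeps ≥2 samples per original sample at
  180 BPM while keeping distance computations cheap. Fewer than two
  detectable beats yields a flagged empty set, not an error.

## Parameter recognition (calibration)

`(K, ζ, ωn)` depend on the user and the wearing condition, so they are
recognized on a two-minute natural-running recording. The objective
exploits pulse quasi-periodicity: with the correct model subtracted,
consecutive beats are nearly identical. For beats P_i (length n,
N total),

    D_ij = ‖P_i − P_j‖₂ / n
    f(x) = Σ_{i∈S} Σ_{j=1..N} D_ij / (m·N)

with S a seeded uniform subsample of m = 20 beats (m = N when fewer
beats exist, in which case f equals the full double-sum mean). The
subsample is drawn by priority sampling — each beat receives a seeded
uniform score and the m smallest win — which is distributionally a
plain uniform draw without replacement but changes by at most one
element when N shifts by one, keeping f close to continuous in the
parameters (the beat count changes slightly between candidate
filters).

The objective divides by n, not √n, so its scale depends on the beat
length; this is an internal consistency choice — all comparisons use
the same n.

f is noisy and derivative-free, so it is minimized by Bayesian
optimization:

* **Surrogate**: zero-mean GP with ARD Matérn 5/2 kernel
  k(x,x′) = σ_f²(1+√5r+5r²/3)e^(−√5r), r² = Σ_d (x_d−x′_d)²/ℓ_d²,
  plus Gaussian observation noise σ_n². Inputs are scaled to the unit
  cube over the search space; **ωn is mapped on a log scale**
  (frequencies compare multiplicatively; a linear map over the 1–30 Hz
  range compresses the low-frequency region where skin resonances live
  into a sliver). Observed objective values are centered before
  hyperparameter fitting.
* **Hyperparameters** (ℓ per dimension, σ_f², σ_n²) by maximizing the
  log marginal likelihood, multi-start L-BFGS-B in log space, three
  seeded starts per iteration. Jitter is added to the kernel diagonal
  only when the clean Cholesky factorization fails (escalating
  1e-8 → 1e-4), so the posterior matches the textbook dense-solve
  formulas exactly on well-conditioned systems.
* **Acquisition**: Expected Improvement,
  EI = (f_min − μ)Φ(z) + σφ(z), z = (f_min − μ)/σ, with the σ = 0 limit
  max(f_min − μ, 0); f_min is the minimum GP posterior mean over the
  evaluated points (not the raw noisy observations). EI is maximized by
  seeded multi-start — global uniform candidates mixed with Gaussian
  perturbations of the incumbent — plus L-BFGS-B refinement of the best
  starts.
* **Loop**: 8 seeded random initial evaluations, then up to 40
  iterations, stopping early if the best EI falls below `ei_tol`.
* **Search space**: ζ ∈ [0.05, 1.5]; ωn/2π ∈ [1, 30] Hz;
  K ∈ [0, K_max] with K_max defaulting to 3× the ratio of hot-film RMS
  to reference-acceleration RMS, which keeps the degenerate
  over-subtraction regime out of reach.
* **Polish**: the similarity objective is micro-rugged (beats enter and
  leave the segmentation as the candidate changes), which stalls purely
  local refinement near the optimum. After the BO loop, candidates are
  therefore *proposed* by minimizing a smooth, segmentation-free
  surrogate — the variance of the filtered waveform, the classic
  adaptive-noise-cancellation criterion (the pulse is uncorrelated with
  the reference acceleration, so output power can only drop by
  cancelling artifact). For fixed (ζ, ωn) the optimal gain has a
  least-squares closed form, leaving a smooth 2-D problem solved by
  seeded differential evolution plus Powell refinement. A proposal is
  **accepted only if it improves the full inter-beat objective**, so
  the similarity criterion keeps the final say and the polish can never
  degrade the BO result. The returned parameters are the accepted
  incumbent.

Identifiability note: recognizing ζ and ωn requires reference
excitation at more than one or two frequencies (persistent excitation,
as in any system identification). The bundled simulator's gait model
provides this through broadband heel-strike transients, cadence
jitter and a band-limited noise floor; on a hypothetical recording
whose reference acceleration were a pure line spectrum, (ζ, ωn) would
be determined only up to a response-matching family.

## Vitals extraction

* **Heart rate**: Hann-windowed FFT magnitude of a 10 s trailing window
  of the cleaned pulse, restricted to 0.5–5 Hz; the peak bin is refined
  by quadratic interpolation over its neighbours (raw resolution of a
  10 s window is 6 BPM; interpolation brings tone errors below
  0.5 BPM). A window with no peak at least 4× the median in-band
  magnitude is flagged invalid. Records are emitted at 1 Hz from
  overlapping windows; the first nine records are flagged `warmup`.
  When heart-rate estimates are scored against simulation ground truth,
  the reference is the true heart rate averaged over the same 10 s
  window — that is the quantity a windowed FFT measures.
* **Temperature**: temp = gain·cf + offset (two-point calibration
  supported), smoothed by a causal 1 s moving average. Out-of-range
  values ([25, 45] °C) are flagged rather than clipped.
* **Pulse amplitude**: mean peak-to-trough of the normalized beats in
  each window.

## Metabolic-rate estimation

Each 10 s window of (hot film, cold film, scalar reference
acceleration) is converted per channel to an STFT log-magnitude diagram:
2 s periodic-Hann windows hopped by 1 s → 9 frames × 101 one-sided bins
at 100 Hz; scaling is log(1+|X|). The scalar reference acceleration is
used (rather than three per-axis spectrograms) for consistency with the
artifact filter's reference signal.

The regressor is a compact CNN, implemented in numpy with full
backpropagation and Adam: each channel has its own trunk of two conv
blocks (3×3 kernels, 8 then 16 filters, ReLU, 2×2 max-pool), trunk
outputs are concatenated into one dense layer (64 units, ReLU) and a
scalar softplus output, which enforces non-negative predictions.
Inputs are z-normalized per channel with training-set statistics only;
the output bias is initialized to softplus⁻¹(mean target) and the
output weights to zero, so training starts from the constant predictor.
Trunk widths (8/16) are a CPU-scale default; the architecture is
configurable (`f1`, `f2`, `hidden`).

Evaluation follows Leave-One-Out cross-validation across sessions:
train on all but one, test on the held-out session; metrics are MAPE
(%) and AAE (W/kg), plus AAE per activity segment.

## Synthetic-data simulator

The simulator generates everything downstream stages consume, with
ground truth attached. Defaults (units in parentheses):

* **Protocol**: six segments — rest, walking at two speeds, jogging,
  running, final rest — with dimensionless intensity 0, 0.30, 0.45,
  0.60, 0.85, 0; the calibration condition is a single 2-minute
  segment at intensity 0.80.
* **Physiology**: heart rate, metabolic rate and core temperature relax
  toward intensity-dependent set points (HR: 62 + 110·intensity BPM,
  τ = 30 s; metabolic rate: 1.2 + 15·intensity W/kg, τ = 30 s;
  temperature: 36.6 + 1.8·intensity °C, τ = 300 s). The long thermal
  time constant means temperature barely tracks metabolic rate within
  short sessions — deliberately, so the hot-film baseline is the
  dominant metabolic cue, mirroring the dominant-input structure the
  estimator is meant to exploit.
* **Pulse**: sum of two Gaussian bumps on the unit beat interval
  (systolic 1.0 at phase 0.30, width 0.10; reflective 0.50 at 0.62,
  width 0.14), phase-warped by the integral of HR/60, amplitude
  modulated by a slow (0.04 Hz, 8 %) envelope. The bump widths were
  chosen so the diastolic trough is a well-defined minimum at resting
  heart rates; much narrower bumps leave a flat inter-beat region whose
  minimum is located by noise, and an isolated reflective bump gets
  double-detected as a beat.
* **Gait acceleration**: cadence 1.5 + 1.6·intensity Hz with 3 % slow
  frequency jitter; vertical harmonics at the cadence, twice the
  cadence, and half the cadence (left/right step asymmetry); one
  broadband half-sine heel-strike transient per step (40–80 ms,
  amplitude ±50 %, timing ±30 ms); slow (±15 %) amplitude modulation of
  every harmonic; band-limited (<10 Hz) noise with SD
  0.15 + 1.8·intensity m/s². The quasi-periodicity and broadband
  content matter: perfectly periodic gait would make an over-subtracted
  waveform look self-similar (a degenerate objective optimum), and a
  pure line spectrum would make (ζ, ωn) unidentifiable.
* **Channels**: hf = pulse + (0.5 + 0.15·metabolic rate) baseline +
  artifact + white noise (SD 0.08, visible beat distortion);
  cf = 0.05·temperature − 1.0 V + noise (SD 2 mV); the artifact channel
  is generated by the same `artifact` module used for removal (single
  source of truth).
* **Canonical artifact truth** for experiments: K = 0.12, ζ = 0.4,
  ωn = 2π·6 rad/s — in-band artifact RMS ≈ 1.3× the pulse RMS
  (distorted but visible beats). Parameter recovery was verified for
  in-band (3 Hz) and out-of-band (6 and 10 Hz) resonances.

What the simulator does **not** model: hemodynamic waveform physiology,
thermoregulation physics, sweat, sensor drift, and electronics noise
spectra. Passing tests therefore demonstrate the correctness and
conditioning of the algorithms under the stated signal model, not
clinical performance on human recordings.

## Problem sizes and numerical choices

Experiments run at desk scale: 2-minute calibration streams, 5- or
6-minute exercise sessions (60 s or 50 s per segment), three sessions
for Leave-One-Out, 30 training epochs, spectrogram windows hopped by
2 s for training sets. GP systems stay small (≤48 points). Degenerate
inputs: constant streams produce flagged empty beat sets; zero-variance
targets produce a warning and a constant predictor; all-failed
objective evaluations raise a calibration error. All randomness flows
from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

* ζ is the least identifiable parameter: its information lives in the
  resonance width, and recovery errors of ~10–15 % are typical where
  ωn recovers to ~1 %.
* The polish stage assumes pulse–acceleration uncorrelatedness over the
  calibration window; pathological phase locking of heart rate to
  cadence would bias the least-squares gain proposal (the Eq.-style
  similarity guard would reject grossly wrong proposals but keeps no
  guarantee of improvement in that regime).
* The CNN default is intentionally small; it saturates on complex
  multi-subject data and is meant to be scaled via its width
  parameters when used beyond the bundled simulator.
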