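# pulseband

Signal-processing and estimation stack for a head-worn thermal
biosensor: motion-artifact removal from a thermal pulse sensor using an
accelerometer reference, heart-rate and forehead-temperature readout,
and real-time total-metabolic-rate estimation — exercised end to end on
a bundled synthetic multimodal-sensor simulator with full ground truth.

## Who this is for

Researchers and engineers working on wearable physiological monitoring
who need a tested, reproducible reference implementation of the
adaptive-filtering + Bayesian-calibration + spectrogram-CNN pipeline —
or any of its pieces (second-order artifact models, beat segmentation,
GP/EI Bayesian optimization, numpy CNN regression) — without access to
device recordings.

## The method

A hot-film sensor on the forehead measures skin thermal conductance:
its output `HF` carries the arterial pulse waveform, a slow perfusion
baseline, and motion artifact. A cold film `CF` reads skin temperature
linearly, and a 3-axis accelerometer `Acc` tracks head motion.

**Artifact model.** Skin deformation responds to head acceleration like
a spring–damper, so artifact reconstruction uses the second-order
transfer function

```
MA(s) = K·ωₙ² / (s² + 2ζωₙ·s + ωₙ²) · A(s)
```

with `A = ‖Acc‖₂ − g` (orientation-free scalar reference). The clean
pulse is `PW = bandpass(HF − MA)`, band 0.5–5 Hz.

**Calibration.** `(K, ζ, ωₙ)` are user- and wearing-specific. They are
recognized on a 2-minute natural-running recording by minimizing the
average normalized Euclidean distance between time-normalized pulse
beats,

```
D_ij = ‖P_i − P_j‖₂ / n ,   f(x) = Σ_{i∈S} Σ_{j=1}^{N} D_ij / (m·N)
```

(m = 20 randomly sampled beats), via Bayesian optimization: a
Gaussian-process surrogate with ARD Matérn-5/2 kernel, Expected
Improvement acquisition, 8 random initial points, up to 40 iterations,
plus a residual-power local polish (accepted only when it improves f).

**Vitals.** Heart rate = 60 × the dominant in-band FFT frequency of a
10 s sliding window of `PW`, refined by quadratic peak interpolation;
forehead temperature = affine cold-film conversion with 1 s smoothing.

**Metabolic rate.** Each 10 s window of (HF, CF, A) becomes three
101-bin × 9-frame STFT log-magnitude diagrams (2 s Hann windows, 1 s
hop) feeding a compact CNN (per-channel conv trunks → dense → softplus)
trained with Adam on W/kg targets and evaluated by Leave-One-Out
cross-validation with MAPE and AAE.

All of this is validated on the bundled simulator
(`pulseband.simulate`), which generates protocol-driven heart-rate /
metabolic / temperature trajectories, a template-based pulse train,
realistic quasi-periodic gait acceleration, and the artifact channel
itself through the same second-order model — with every ground-truth
series attached to the stream.

## Worked example

```python
import numpy as np
from pulseband import (
    ArtifactParams, ArtifactCalibrator, NoiseConfig,
    calibration_protocol, synth_session,
)

truth = ArtifactParams(K=0.12, zeta=0.4, omega_n=2*np.pi*6, fs=100)
stream = synth_session(calibration_protocol(), truth, NoiseConfig(), seed=0)

cal = ArtifactCalibrator(seed=0).fit(stream)
p = cal.params_
print(f"K = {p.K:.3f}   zeta = {p.zeta:.3f}   fn = {p.omega_n/2/np.pi:.2f} Hz")
```

prints

```
K = 0.121   zeta = 0.413   fn = 6.01 Hz
```

i.e. the calibrator recovers the gain and natural frequency of the
simulated skin model (true values 0.12, 0.4, 6 Hz) to within a few
percent and the damping ratio to within a few percent to ~15 %, from
two minutes of noisy running data. Applying the recovered filter
reduces the in-band artifact RMS by 22–120× across seeds. Downstream, heart rate tracks the simulated
truth with a mean absolute error of ≈0.2 BPM outside exercise-intensity
transitions, and Leave-One-Out metabolic estimation over three
simulated sessions reaches ≈9 % MAPE (≈0.4 W/kg AAE).

A command-line surface wraps the same pipeline:

```bash
pulseband simulate --out session.csv --seed 1
pulseband calibrate --in calibration.csv --out params.json
pulseband vitals --in session.csv --params params.json --out vitals.csv
pulseband run --out-dir demo_run --seed 1    # full demo pipeline
```

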