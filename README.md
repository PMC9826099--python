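# triaxmeg

Simulation and analysis of wearable **triaxial OPM-MEG**: a 30-sensor
(90-channel) array of optically pumped magnetometers over sensorimotor
cortex, operated in a nulled background field, recording a handwriting
paradigm. The package provides the full computational chain as tested,
seeded components:

* **Background-field mapping and nulling** — the remnant static field in a
  shielded room is modelled by eight coefficients (uniform vector *b₀* and
  five independent linear gradients *g*, with *G* symmetric and trace-free).
  Because each OPM is field-zeroed at rest, only helmet motion identifies
  the model: mapping movements give motion-resolved channel data
  *yᵢ(t) = aᵢ(t)·(b₀ + G pᵢ(t)) + cᵢ*, fit by least squares from a 5-sensor
  subset; compensation currents are *I = −M⁻¹ĉ* for coil calibration *M*.
  A 60 Hz proportional–integral loop on 3 Hz-low-passed reference sensors
  stabilizes slow drift.
* **OPM response model** — SERF magnetometers have a Lorentzian zero-field
  resonance, so a quasi-static field step ΔB costs a fractional gain error
  ε = x/(1+x), x = (ΔB/Γ)². The linewidth Γ is calibrated from a single
  anchor (3 nT ↦ 3.8%), after which the model predicts the gain cost of any
  head rotation in any remnant field.
* **Synthetic recordings with planted truth** — beta-band (13–30 Hz)
  sources with event-related desynchronization during writing and a
  condition-dependent post-movement rebound (right hand 5.5–7.5 s, left
  hand 9–11 s after stimulus), a planted 78-region envelope connectome
  realized by a shared log-normal drive, motion-coupled background-field
  artifacts, a 16.6 Hz interference line, and white sensor noise.
* **LCMV beamforming** — Tikhonov-regularized covariance (μ = 5% of the
  largest eigenvalue), max-SNR source orientation from the 2×2 generalized
  eigenproblem (LᵀC⁻²L)η = λ(LᵀC⁻¹L)η, unit-gain weights
  w = C⁻¹Lη/(ηᵀLᵀC⁻¹Lη), and noise-normalized pseudo-T images
  T = (Pₐ − P꜀)/(2Pₙ) contrasting active and control windows, in triaxial or
  radial-only channel mode. The forward model is the closed-form current
  dipole in a homogeneous conducting sphere (volume currents included).
* **Connectomics and statistics** — pairwise-orthogonalized amplitude
  envelope correlation (78×78, Hilbert envelopes downsampled to 10 Hz),
  whole-brain and node-strength summaries, channel SNR and 16.6 Hz
  interference-ratio metrics, exact Wilcoxon rank-sum tests with Bonferroni
  correction, and permutation-based fingerprinting (56 within- vs 64
  between-participant run correlations, Monte-Carlo null).

## Worked example

```python
import numpy as np
from triaxmeg.fields import BackgroundField, CoilSystem
from triaxmeg.geometry import build_helmet_array
from triaxmeg.nulling import run_nulling
from triaxmeg.opm import NoiseModel, calibrate_linewidth, gain_error, rotation_field_step

# gain cost of a 90-degree head rotation, before and after nulling
gm = calibrate_linewidth(3.0, 0.038)        # Gamma ~ 15.09 nT
for field_nT in (3.0, 0.2):
    eps = gain_error(rotation_field_step(field_nT, 90.0), gm)
    print(f"{field_nT} nT remnant field -> {100 * eps:.4f} % gain error")

# one simulated nulling session: 3.0 nT / 3.4 nT/m background,
# 60 s mapping movement, 5-sensor fit, two iterations
array = build_helmet_array(30, scalp_radius=0.09)
env = BackgroundField([1.73, 1.73, 1.73], [1.52, -1.16, 1.34, 1.07, -0.89])
rep = run_nulling(env, CoilSystem.nominal(seed=1), array, gm,
                  NoiseModel(15.0, seed=2), iterations=2, seed=3)
print(f"uniform norm {rep.pre_uniform_norm:.2f} -> {rep.post_uniform_norm:.2e} nT")
```

Output:

```
3.0 nT remnant field -> 3.8000 % gain error
0.2 nT remnant field -> 0.0176 % gain error
uniform norm 2.99 -> 1.60e-05 nT
```

The 3.8% line is the calibration anchor; the 0.0176% line is the model's
prediction of how little a full head rotation costs once the field is
nulled to 0.2 nT. The nulling session drives a model-compliant 3 nT
background to microtesla-scale residuals; the 0.2 nT-scale residuals seen
on real hardware reflect tracking and calibration errors the simulator's
known-calibration setting does not include (see `docs/methods.md`).

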