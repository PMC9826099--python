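# Methods

This note documents the models behind `triaxmeg`, the parameters that
matter, and the choices made where the design was genuinely open. Units are
SI internally (tesla, meters, seconds); user-facing field coefficients are
in nT and nT/m, noise densities in fT/√Hz.

## Coordinate frame and geometry

Head coordinates are right-handed with the origin at the head-sphere
center: x anterior, y left, z superior. The head is an analytic sphere
(default radius 0.08 m); sensors sit on a Fibonacci lattice covering a
spherical cap about the vertex (default 60° angular radius), at scalp
radius 0.09 m plus a 6.5 mm standoff. These helmet dimensions are
configuration, not claims about any particular hardware. Each triaxial
sensor carries an orthonormal axis triad with the z axis radial by
construction; `tag_radial_channels` re-derives the tag for arbitrary
arrays as the axis with maximal |dot| with the outward radial, ties broken
in axis order x, y, z.

Sphere fitting is the algebraic least-squares form (solve
|p|² = 2c·p + k); it is exact on noiseless data and its error grows
linearly with point noise, which the tests verify at two noise levels.

## Forward models

Neural sources are current dipoles in a homogeneous conducting sphere,
evaluated with the closed-form solution including volume currents. Two
identities anchor correctness: a radial dipole moment produces no external
field, and the radial component of the external field equals the
free-space (Biot–Savart) radial component. Both are asserted against an
independent free-space oracle. (That oracle caught a sign/argument error
in the gradient term during development — the reason it exists.)

The choice of an analytic sphere over a realistic single-shell boundary
model is deliberate: it makes the forward model provable against closed
form, at the cost that source-space results validate against the
simulator's own ground truth rather than real anatomy.

The background field is B(p) = b₀ + G·p with G assembled from five
independent coefficients (Gxx, Gyy, Gxy, Gxz, Gyz); symmetry and zero
trace make it a valid magnetostatic gradient (div- and curl-free, verified
on a numerical stencil). The coil system maps eight currents to the eight
coefficients through an invertible calibration matrix; the default is
identity plus 5% seeded leakage so the inversion path is exercised
realistically. Interference is a narrowband line (default 16.6 Hz, 1 pT at
the helmet) from a far magnetic dipole 5 m away, giving a <15% field
variation across the helmet — nearly but not exactly uniform, which is
what makes it separable from neural sources by a triaxial beamformer.

## OPM response

SERF magnetometers are linear only near zero field. We model the gain
error of a quasi-static field step ΔB along a sensitive axis as
ε = x/(1+x) with x = (ΔB/Γ)², the magnitude response of a Lorentzian
zero-field resonance of half-width Γ. Γ is not a free parameter: it is
calibrated once from the anchor (3 nT, 3.8%), giving Γ ≈ 15.09 nT, and the
model then predicts 0.018% for a 90° rotation in a 0.2 nT field and
~0.0005% for a 10° rotation — the quantitative case for field nulling. An
alternative anchor (±3 nT at <5%) would give Γ ≈ 13.08 nT; the two are not
perfectly consistent, and we fix the 3.8% anchor as primary. The field
step under rotation is ΔB = B·sinθ (translation-through-gradient terms
excluded): the step seen by an axis that was zeroed at rest.

Sensor noise is white at a density of 9–15 fT/√Hz (per-sample
σ = density·√(fs/2)); no 1/f knee is modelled. In synthetic recordings the
two tangential axes carry 1.4× the radial density, reflecting the poorer
sensitivity of the light-shifted axes of real triaxial sensors; with equal
noise on all axes the array-level SNR summaries come out unrealistically
favourable to the tangential channels.

## Field mapping and nulling

Because OPMs are zeroed by on-sensor coils at rest, the absolute field is
unobservable; only motion-induced change identifies the background model.
The mapping fit therefore includes per-channel DC offsets cᵢ as nuisance
parameters — without them the fit is biased by the unknown zero levels.
Mapping movements are sums of three seeded sinusoids (0.05–0.4 Hz) per
degree of freedom, peaking at ±10° and ±5 cm; a 60 s movement at 120 Hz
makes the 8+15-column design matrix comfortably full-rank (condition
number ≲ 10³). Rank-deficient designs (e.g. no motion) are rejected with
the unidentifiable components named.

Nulling iterates mapping → fit → currents. One iteration suffices in the
noiseless, model-compliant case (residual < 1e-6 nT, tested); the second
iteration exists because gain errors in the un-nulled 3 nT field bias the
first fit by a few percent. The simulated two-iteration residual
(~1e-5 nT) is far below the 0.2 nT achieved on real hardware: the
simulator assumes an exactly known coil calibration and exact motion
tracking, so its residual is fit-noise-limited. The 0.2 nT scale on real
systems is attributed to tracking and calibration errors that are outside
this model; the simulated value should be read as "the algorithm is not
the bottleneck".

Dynamic stabilization is a discrete 60 Hz PI loop on reference estimates
of the six components the reference geometry can sense (three uniform
components and the z-varying gradients Gxz, Gyz, Gzz — the reference
sensors are separated only in z). References are low-passed at 3 Hz by a
first-order IIR; gains (Kp = 0.5, Ki = 10.6 s⁻¹) give a critically damped
closed loop at the cutoff: a constant offset is integrated away, a 0.1 Hz
drift is attenuated ≥10×, and a 10 Hz disturbance passes essentially
unmodified (the loop must be transparent in the signal band). Divergence
(unstable gains) raises, reporting the last stable iterate.

## Synthetic study

The paradigm is two blocks of 20 trials (5 s writing cue + 7 s rest) at
1200 Hz, one block per hand. Scaled-down versions (5 trials/block, 600 Hz)
are used in tests; the physics, filters, and window definitions are
unchanged, only the problem size shrinks, so passing tests demonstrate the
method chain at somewhat lower statistical power than the full study.

Each of 78 regions has a centroid on a 0.065 m source sphere (jittered
near-uniform lattice, seeded per participant), a tangential orientation,
and a band-limited (13–30 Hz) Gaussian carrier. Region envelopes are
log-normal, E = exp(σz − σ²/2) with σ = 0.6 and z a 0.3 Hz-bandwidth
latent Gaussian; envelope coupling is planted by correlating the latents.
The latent correlation needed to realize a desired measured envelope
correlation c is the closed-form log-normal inverse
ρ = ln(1 + c′(e^{σ²} − 1))/σ², with c′ = c/0.71: the 0.71 is a fixed
carrier-attenuation factor, measured once by simulating the source-level
envelope-correlation pipeline (Hilbert envelope, 10 Hz block average) —
the Rayleigh fluctuation of a narrowband carrier dilutes envelope
correlations by that roughly constant factor. Long-run recovery of a
planted coupling of 0.4 within ±0.05 at source level is a tested property.
The latent processes are synthesized at 4.8 Hz and interpolated up:
filtering white noise at the channel rate with a 0.3 Hz cutoff is
numerically fragile (normalized cutoff ~1e-4 produces spiky, heavy-tailed
output) and was rejected.

Task dynamics: motor-region envelopes are multiplied by a raised-cosine
profile — suppression (ERD, default depth 0.5) during writing, elevation
(rebound, default gain 0.3) in the condition's rebound window (right hand
5.5–7.5 s, left hand 9–11 s; the left hand writes more slowly). Right-hand
writing drives the left motor region at 5 nA·m against a 1 nA·m
distributed background (weights 2.5/1.2/0.5 × 2 nA·m baseline); left-hand
writing is bilateral (2.5/2.5) and elevates planted coupling globally
(×1.5) plus an extra bilateral motor edge (+0.25). The global elevation is
what makes the whole-brain (3003-pair) connectivity contrast detectable —
a single planted edge is statistically invisible in a sum of that size.
Source amplitudes and the amplitude structure are calibrated so channel
SNR summaries land in the range observed for this class of array (summed
triaxial/radial SNR ≈ 2).

Recordings compose, per the superposition design (each contributor
independently toggleable): neural projection through leadfields of the
moving helmet (piecewise-updated every 1 s at the segment-center pose — a
quasi-static approximation; the pose stream itself is 120 Hz), the
movement artifact aᵢ(t)ᵀB(pᵢ(t)) − aᵢ(0)ᵀB(pᵢ(0)) per channel, the
interference line, a per-channel static gain error from the maximal
quasi-static field step, and white noise. Word stimuli are not modelled
(only trigger timing matters) and 16-bit quantization is omitted (the
noise floor dominates the quantization step).

## Reconstruction

Preprocessing mean-corrects, applies a channel exclusion list (excluding
one triaxial sensor leaves 87 of 90 channels, the configuration the
analysis must tolerate), segments on stimulus triggers, and demeans each
epoch. Band-passing is zero-phase forward-backward Butterworth (order 4
each pass, effective order 8) — chosen over single-pass to avoid phase
distortion of envelopes. Covariance is estimated per condition from
concatenated filtered trials and regularized as C + μλmax·I, μ = 0.05.

LCMV orientation is the minimum-λ generalized eigenvector of
(LᵀC⁻²L)η = λ(LᵀC⁻¹L)η (maximum output SNR); its sign is pinned (largest
component positive) for determinism. Weights are unit-gain. A bordered-KKT
quadratic-programming oracle independently reproduces the weights to
1e-8 in tests.

Pseudo-T imaging defaults to the noise-normalized form
T = (Pₐ − P꜀)/(2Pₙ), where Pₙ is the sensor-noise power passed by the
voxel's filter (noise floor = smallest covariance eigenvalue). The
bounded symmetric ratio (Pₐ − P꜀)/(Pₐ + P꜀) is available as
`normalization="ratio"`, but it is not the default because the projected
sensor noise shrinks toward the sensors, which biases the ratio image's
extremum outward by 5–11 mm at study SNR; the noise-normalized form
cancels that profile and recovers the planted source at sub-voxel error.
Voxel-grid extrema break ties at the lowest linear index. Two window
presets exist: imaging (active 1.5–3.5 s vs the condition's rebound
window) and modulation/SNR (right 2–4 vs 5–7 s, left 4–6 vs 8–10 s).
Weights for time-course extraction can come from broadband or beta-limited
covariance; the TFS path uses broadband weights by default.

## Connectivity and statistics

AEC: per unordered pair, one region's beta time course is regressed out of
the other (exact for zero-lag linear leakage; Hilbert linearity lets the
orthogonalized analytic signal be formed from precomputed per-region
analytic signals), envelopes are block-averaged to 10 Hz (anti-alias
downsampling; envelopes are smooth, so decimation artifacts are
negligible), Pearson-correlated, and the two regression directions
averaged to keep the matrix symmetric. A residual that is numerically zero
(perfect leakage) contributes zero correlation — leakage fully removed.
Zero-variance regions get NaN edges and a log entry.

The interference ratio is (PSD(line) − PSD(neighbours))/PSD(neighbours)
with Welch bins of 0.1 Hz so 15.5, 16.6 and 17.7 Hz sit exactly on bins;
the line is a single bin, the neighbour level a ±0.3 Hz local mean
(lower-variance estimate of the smooth background). The single line bin
carries chi-square estimation noise of order 25% at 60 s record length —
null-level checks therefore average over records, while the
triaxial-vs-radial comparison is paired per run and robust to it.

Rank-sum tests use exact enumeration for tie-free groups up to n = 10 (the
study's n = 8 regime; fully separated 8-vs-8 groups give the exact
two-sided p = 2/12870) and a tie-corrected normal approximation otherwise;
identical groups return p = 1. Bonferroni correction is min(1, m·p).

Fingerprinting correlates run-level feature vectors (connectome upper
triangles, vectorized images, or TFS): 28 + 28 = 56 within-participant and
8×8 = 64 ordered between-participant pairs (the ordered convention matches
the 64 count). The statistic is mean(between) − mean(within), expected
negative; the null permutes the 120 correlations (n_perm = 100,000 by
default) and p = (1 + #{sham ≤ observed})/(n_perm + 1) — the +1 guarantees
p > 0, and the one-sided direction (within > between) is fixed a priori.
Under exchangeable inputs the p-value is uniform (tested by
Kolmogorov–Smirnov over 200 seeded repetitions at reduced n_perm).

## Known limitations

* The spherical conductor and synthetic parcellation mean source-space
  results validate against planted truth, not anatomy; absolute
  localization numbers do not transfer to real heads.
* The nulling simulator's residuals are fit-noise-limited because coil
  calibration and motion tracking are exactly known; real-hardware
  residuals are dominated by errors outside the model.
* Gain error is applied as a static per-channel factor from the maximal
  quasi-static field step; closed-loop sensor dynamics, cross-axis
  projection errors and inter-sensor crosstalk are not modelled.
* The carrier-attenuation constant (0.71) is tied to the default envelope
  spread (σ = 0.6) and bandwidth (0.3 Hz); changing those without
  re-measuring it will bias planted-coupling realization.
* Head motion during recordings is rigid and smooth; jerky motion,
  flexible helmet modes, and muscle/ocular artifacts are absent.
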