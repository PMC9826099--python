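"""Background-field mapping and nulling.

The remnant static field inside the shielded enclosure is modelled by eight
coefficients: three uniform components and five independent linear
gradients. Because each OPM is field-zeroed by its on-sensor coils at rest,
the absolute field is unobservable — only the *change* produced by moving
the helmet through the field identifies the model. The participant performs
mapping movements (rotations and translations about all three axes); the
motion-resolved channel data from a small sensor subset are fit by linear
least squares to

    y_i(t) = a_i(t)·(b0 + G p_i(t)) + c_i,

with a_i(t), p_i(t) the moved channel axis and sensor position and c_i a
per-channel nuisance offset absorbing the unknown zero level. Compensation
currents are then the negated calibration-inverse of the fitted
coefficients; mapping + compensation is iterated (twice in practice) because
sensor gain errors in the un-nulled field bias the first fit slightly.

Slow drift on top of the static field is handled by a discrete
proportional–integral loop fed by a reference sensor array: uniform
components and the z-varying gradients are controllable with reference
sensors split only along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import BackgroundField, CoilSystem, background_at
from .geometry import MotionTrace, RigidTransform, SensorArray, apply_motion
from .opm import GainModel, NoiseModel, gain_error

__all__ = [
    "FieldMapFit",
    "StabilizerState",
    "NullingReport",
    "generate_mapping_motion",
    "fit_field_map",
    "compensation_currents",
    "run_nulling",
    "dynamic_stabilization",
    "default_mapping_subset",
]

_COEFF_NAMES = ("Bx", "By", "Bz", "Gxx", "Gyy", "Gxy", "Gxz", "Gyz")


@dataclass(frozen=True)
class FieldMapFit:
    """Least-squares harmonic field-map fit: 8 coefficients + diagnostics."""

    coefficients: np.ndarray  # (8,): b0 (nT), g (nT/m)
    per_channel_offsets: np.ndarray  # (n_channels_used,), nT
    residual_rms: float  # nT
    condition_number: float

    @property
    def background(self) -> BackgroundField:
        return BackgroundField.from_coefficients(self.coefficients)


@dataclass
class StabilizerState:
    """Discrete PI controller configuration and accumulated state.

    Default gains give a critically damped closed loop at the 3 Hz reference
    low-pass cutoff (continuous-time design s² + a(1+Kp)s + a·Ki with
    a = 2π·f_c, discretized at the 60 Hz update rate).
    """

    kp: float = 0.5
    ki: float = 10.6
    lowpass_cutoff: float = 3.0
    update_rate: float = 60.0
    integral: np.ndarray = field(default_factory=lambda: np.zeros(6))
    filtered: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self):
        if not self.update_rate > 2.0 * self.lowpass_cutoff:
            raise ValueError("update rate must exceed twice the low-pass cutoff")


def generate_mapping_motion(
    duration: float = 60.0,
    amplitudes: tuple = (10.0, 0.05),
    seed: int = 0,
    fs: float = 120.0,
) -> MotionTrace:
    """Smooth pseudo-random head movements exercising all six degrees of freedom.

    Each DOF is a sum of three sinusoids at seeded incommensurate frequencies
    in 0.05–0.4 Hz, scaled to peak at ``amplitudes`` = (degrees, meters).
    """
    import warnings

    if not duration > 0:
        raise ValueError("duration must be positive")
    amp_deg, amp_m = amplitudes
    if amp_deg == 0 and amp_m == 0:
        warnings.warn("zero mapping amplitudes: the field-map fit will be degenerate")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    dof = np.zeros((6, n))
    for k in range(6):
        freqs = rng.uniform(0.05, 0.4, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        w = rng.uniform(0.5, 1.0, size=3)
        sig = np.sum(w[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0)
        peak = np.abs(sig).max()
        if peak > 0:
            sig = sig / peak
        dof[k] = sig
    from scipy.spatial.transform import Rotation

    mats = Rotation.from_euler("xyz", amp_deg * dof[:3].T, degrees=True).as_matrix()
    trans = amp_m * dof[3:].T
    poses = tuple(RigidTransform._trusted(R, tr) for R, tr in zip(mats, trans))
    return MotionTrace(t, poses, fs=fs)


def default_mapping_subset(array: SensorArray) -> np.ndarray:
    """Pick 5 well-spread sensors (front, back, left, right, top of the helmet)."""
    pos = array.positions
    picks = [
        int(np.argmax(pos[:, 0])),  # front (x anterior)
        int(np.argmin(pos[:, 0])),  # back
        int(np.argmax(pos[:, 1])),  # left
        int(np.argmin(pos[:, 1])),  # right
        int(np.argmax(pos[:, 2])),  # top
    ]
    # de-duplicate while keeping spread, padding from remaining sensors
    subset = list(dict.fromkeys(picks))
    for i in np.argsort(-pos[:, 2]):
        if len(subset) == 5:
            break
        if int(i) not in subset:
            subset.append(int(i))
    return np.array(subset[:5])


def _design_matrix(axes_t: np.ndarray, pos_t: np.ndarray) -> np.ndarray:
    """Harmonic-model regressors for moved channel axes (n,3) and positions (n,3).

    Columns follow _COEFF_NAMES; Gzz enters through the trace-free constraint.
    """
    ax, ay, az = axes_t[:, 0], axes_t[:, 1], axes_t[:, 2]
    px, py, pz = pos_t[:, 0], pos_t[:, 1], pos_t[:, 2]
    return np.column_stack(
        [
            ax,
            ay,
            az,
            ax * px - az * pz,  # Gxx (minus Gzz share)
            ay * py - az * pz,  # Gyy (minus Gzz share)
            ax * py + ay * px,  # Gxy
            ax * pz + az * px,  # Gxz
            ay * pz + az * py,  # Gyz
        ]
    )


def moved_channel_geometry(
    motion: MotionTrace, array: SensorArray, subset
) -> tuple[np.ndarray, np.ndarray]:
    """Moved channel axes and positions, each (n_samples, n_ch, 3), for the
    chosen sensor subset under the pose trajectory."""
    subset = np.asarray(subset, int)
    nt = len(motion)
    nch = 3 * len(subset)
    axes0 = array.axes[subset]  # (ns, 3, 3)
    pos0 = array.positions[subset]  # (ns, 3)
    R = np.stack([p.rotation for p in motion.poses])  # (nt, 3, 3)
    tr = np.stack([p.translation for p in motion.poses])  # (nt, 3)
    pos_t = np.einsum("tij,sj->tsi", R, pos0) + tr[:, None, :]  # (nt, ns, 3)
    axes_t = np.einsum("tij,sjk->tsik", R, axes0)  # (nt, ns, 3, 3)
    ch_axes = axes_t.transpose(0, 1, 3, 2).reshape(nt, nch, 3)
    ch_pos = np.repeat(pos_t, 3, axis=1)
    return ch_axes, ch_pos


def mapping_design(
    motion: MotionTrace, array: SensorArray, subset
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked design matrix for a mapped recording.

    Returns (A, axes_t, pos_t): A is (n_samples·n_ch, 8 + n_ch) including
    per-channel offset columns; axes_t/pos_t are (n_samples, n_ch, 3) moved
    channel axes and positions.
    """
    ch_axes, ch_pos = moved_channel_geometry(motion, array, subset)
    nt, nch, _ = ch_axes.shape
    A_phys = _design_matrix(ch_axes.reshape(-1, 3), ch_pos.reshape(-1, 3))
    offsets = np.tile(np.eye(nch), (nt, 1))
    return np.hstack([A_phys, offsets]), ch_axes, ch_pos


def fit_field_map(
    channels_nT: np.ndarray,
    motion: MotionTrace,
    array: SensorArray,
    subset,
    cond_limit: float = 1e8,
) -> FieldMapFit:
    """Fit the 8-coefficient harmonic field model (plus per-channel offsets)
    to motion-resolved channel data (n_channels_used x n_samples, nT)."""
    subset = np.asarray(subset, int)
    y = np.asarray(channels_nT, float)
    nch = 3 * len(subset)
    if y.shape != (nch, len(motion)):
        raise ValueError(
            f"channel data must be ({nch}, {len(motion)}) for this subset/motion"
        )
    A, _, _ = mapping_design(motion, array, subset)
    b = y.T.reshape(-1)
    sv = np.linalg.svd(A, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > cond_limit:
        # identify which physical columns are in the near-null space
        _, _, vt = np.linalg.svd(A)
        weak = np.abs(vt[-1][:8])
        bad = [
            name for name, w in zip(_COEFF_NAMES, weak) if w > 0.1
        ] or ["(offsets only)"]
        raise ValueError(
            "field-map design is rank-deficient (insufficient mapping motion); "
            f"unidentifiable components: {', '.join(bad)}"
        )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ sol
    return FieldMapFit(
        coefficients=sol[:8],
        per_channel_offsets=sol[8:],
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        condition_number=cond,
    )


def compensation_currents(fit: FieldMapFit, coils: CoilSystem) -> np.ndarray:
    """DC coil currents producing the equal-and-opposite field: I = −cal⁻¹·coeffs."""
    cal = coils.calibration
    if np.linalg.cond(cal) > 1e12:
        raise ValueError("coil calibration matrix is singular; cannot compute currents")
    return -np.linalg.solve(cal, fit.coefficients)


@dataclass(frozen=True)
class NullingReport:
    """Per-iteration nulling record and residual field norms."""

    pre_uniform_norm: float  # nT
    pre_gradient_norm: float  # nT/m
    post_uniform_norm: float  # nT
    post_gradient_norm: float  # nT/m
    iterations: tuple  # per-iteration dicts: coefficients, currents, residual norms
    final_fit: FieldMapFit


def _map_channels(
    env: BackgroundField,
    motion: MotionTrace,
    array: SensorArray,
    subset,
    gm: GainModel | None,
    nm: NoiseModel | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize the motion-resolved mapping data (nT) a zeroed OPM subset
    reads while the helmet moves through ``env``: the quasi-static field
    change along each moved axis, degraded by the instantaneous gain error
    and white noise."""
    _, ch_axes, ch_pos = mapping_design(motion, array, subset)
    nt, nch, _ = ch_axes.shape
    b = background_at(env, ch_pos.reshape(-1, 3)).reshape(nt, nch, 3)
    proj = np.einsum("tci,tci->tc", ch_axes, b)  # nT along each moved axis
    y = (proj - proj[0]).T  # zeroed at the rest pose -> (nch, nt)
    if gm is not None:
        eps = gain_error(np.abs(y), gm)
        y = (1.0 - eps) * y
    if nm is not None and nm.density_fT_per_rtHz > 0:
        y = y + rng.normal(0.0, nm.sigma_T(motion.fs) / 1e-9, size=y.shape)
    return y


def run_nulling(
    env: BackgroundField,
    coils: CoilSystem,
    array: SensorArray,
    gm: GainModel | None,
    nm: NoiseModel | None,
    iterations: int = 2,
    seed: int = 0,
    mapping_duration: float = 60.0,
    mapping_amplitudes: tuple = (10.0, 0.05),
    subset=None,
) -> NullingReport:
    """Simulate the full static-field nulling procedure.

    Each iteration: generate a fresh mapping movement, synthesize the subset
    channels in the current residual field, fit the harmonic model, and apply
    compensation currents. A final mapping captures the achieved residual.
    """
    if iterations < 1:
        raise ValueError("at least one nulling iteration is required")
    if subset is None:
        subset = default_mapping_subset(array)
    rng = np.random.default_rng(seed)
    current_env = env
    total_currents = np.zeros(8)
    records = []
    pre_fit = None
    for it in range(iterations):
        motion = generate_mapping_motion(
            mapping_duration, mapping_amplitudes, seed=int(rng.integers(2**31))
        )
        y = _map_channels(current_env, motion, array, subset, gm, nm, rng)
        fit = fit_field_map(y, motion, array, subset)
        if it == 0:
            pre_fit = fit
        currents = compensation_currents(fit, coils)
        total_currents = total_currents + currents
        current_env = current_env + coils.field_from_currents(currents)
        records.append(
            {
                "fitted_coefficients": fit.coefficients.tolist(),
                "currents": currents.tolist(),
                "residual_uniform_norm_nT": current_env.uniform_norm(),
                "residual_gradient_norm_nT_per_m": current_env.gradient_norm(),
            }
        )
    # final mapping run: measure what is left
    motion = generate_mapping_motion(
        mapping_duration, mapping_amplitudes, seed=int(rng.integers(2**31))
    )
    y = _map_channels(current_env, motion, array, subset, gm, nm, rng)
    final_fit = fit_field_map(y, motion, array, subset)
    final_bg = final_fit.background
    return NullingReport(
        pre_uniform_norm=pre_fit.background.uniform_norm(),
        pre_gradient_norm=pre_fit.background.gradient_norm(),
        post_uniform_norm=final_bg.uniform_norm(),
        post_gradient_norm=final_bg.gradient_norm(),
        iterations=tuple(records),
        final_fit=final_fit,
    )


# ---------------------------------------------------------------------------
# dynamic stabilization


def default_reference_array() -> tuple[np.ndarray, np.ndarray]:
    """Reference array behind the participant: 4 dual-axis sensors in two
    z-separated pairs (~0.4 m apart). Returns (positions (8,3), axes (8,3)) —
    one row per reference channel."""
    positions = []
    axes = []
    sensor_pos = [
        (-0.35, 0.15, 0.20),
        (-0.35, -0.15, 0.20),
        (-0.35, 0.15, -0.20),
        (-0.35, -0.15, -0.20),
    ]
    sensor_axes = [
        ((1, 0, 0), (0, 0, 1)),
        ((0, 1, 0), (0, 0, 1)),
        ((1, 0, 0), (0, 1, 0)),
        ((0, 1, 0), (0, 0, 1)),
    ]
    for p, (a1, a2) in zip(sensor_pos, sensor_axes):
        for a in (a1, a2):
            positions.append(p)
            axes.append(a)
    return np.asarray(positions, float), np.asarray(axes, float)


def _zvarying_design(positions: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """(n_channels, 6) map from (Bx,By,Bz,Gxz,Gyz,Gzz) to reference readings."""
    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    ax, ay, az = axes[:, 0], axes[:, 1], axes[:, 2]
    return np.column_stack(
        [
            ax,
            ay,
            az,
            ax * z + az * x,  # Gxz
            ay * z + az * y,  # Gyz
            az * z,  # Gzz (the z-varying part the loop can see/drive)
        ]
    )


def dynamic_stabilization(
    drift,
    duration: float,
    state: StabilizerState | None = None,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
    noise_nT: float = 0.0,
    seed: int = 0,
):
    """Closed-loop compensation of slow field drift.

    ``drift`` maps time (s) to the 6 drifting components
    (Bx, By, Bz, Gxz, Gyz, Gzz) in nT / nT/m — the uniform field plus the
    z-varying gradients the reference pair geometry can sense. Each 60 Hz
    step: read the reference channels in (drift + compensation), solve for
    the 6 components, low-pass at 3 Hz, and update the PI terms driving the
    coils. Returns (times, residual (n,6)) — the field left at the helmet.

    Raises on controller divergence, attaching the last stable residual.
    """
    if state is None:
        state = StabilizerState()
    if reference is None:
        reference = default_reference_array()
    positions, axes = reference
    M = _zvarying_design(positions, axes)
    if np.linalg.matrix_rank(M) < 6:
        raise ValueError("reference geometry cannot identify the 6 stabilized components")
    Minv = np.linalg.pinv(M)
    dt = 1.0 / state.update_rate
    alpha = dt * 2 * np.pi * state.lowpass_cutoff
    alpha = alpha / (1.0 + alpha)  # first-order IIR coefficient
    n = int(round(duration * state.update_rate))
    rng = np.random.default_rng(seed)
    comp = np.zeros(6)
    times = np.arange(n) * dt
    residual = np.empty((n, 6))
    scale = max(1.0, float(np.max(np.abs(drift(0.0)))))
    for k in range(n):
        true = np.asarray(drift(times[k]), float) + comp
        residual[k] = true
        readings = M @ true
        if noise_nT > 0:
            readings = readings + rng.normal(0.0, noise_nT, size=readings.shape)
        est = Minv @ readings
        state.filtered = state.filtered + alpha * (est - state.filtered)
        state.integral = state.integral + state.ki * state.filtered * dt
        if np.any(np.abs(state.integral) > 1e6 * scale):
            raise RuntimeError(
                f"stabilizer diverged at t={times[k]:.3f}s; last stable residual "
                f"{residual[max(k - 1, 0)]}"
            )
        comp = -(state.kp * state.filtered + state.integral)
    return times, residual
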