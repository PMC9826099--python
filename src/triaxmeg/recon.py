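"""Preprocessing and LCMV beamformer source reconstruction.

The beamformer is a linearly constrained minimum-variance spatial filter:
for a location with tangential leadfield L (channels x 2) and regularized
data covariance C, the source orientation eta is chosen to maximize output
SNR (the minimum-eigenvalue solution of the generalized problem
(L'C^-2 L) eta = lambda (L'C^-1 L) eta), and the unit-gain weights are

    w = C^-1 L eta / (eta' L' C^-1 L eta).

Pseudo-T images contrast beamformer-projected beta power between an active
(writing/ERD) and a control (rebound) window per voxel. Two normalizations
are provided:

* ``"noise"`` (default): T = (P_active - P_control) / (2 P_noise), with
  P_noise the sensor-noise power passed by the voxel's filter (noise floor
  estimated from the smallest covariance eigenvalue). This is the classic
  synthetic-aperture-magnetometry form; dividing by the filter's noise gain
  cancels the depth-dependent projected-noise profile that otherwise biases
  power-ratio images toward the sensors.
* ``"ratio"``: T = (P_active - P_control) / (P_active + P_control), a
  bounded ([-1, 1]), unit-free modulation index.

Radial-only mode restricts every stage (covariance, leadfields, weights) to
the radially tagged channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import linalg, signal

from .fields import leadfield
from .geometry import HeadModel, SensorArray
from .synthpara import Recording

__all__ = [
    "Epochs",
    "CovarianceModel",
    "BeamformerSolution",
    "SourceImage",
    "preprocess",
    "bandpass",
    "estimate_covariance",
    "lcmv",
    "pseudo_t_image",
    "peak_and_repeatability",
    "virtual_electrode",
    "cubic_grid",
    "IMAGING_WINDOWS",
    "MODULATION_WINDOWS",
]

#: Imaging windows (s, relative to stimulus onset): active ERD window and the
#: condition-dependent control window centred on the rebound.
IMAGING_WINDOWS = {
    "left": {"active": (1.5, 3.5), "control": (9.0, 11.0)},
    "right": {"active": (1.5, 3.5), "control": (5.5, 7.5)},
}
#: Modulation-metric windows (used for beta-modulation amplitude and SNR).
MODULATION_WINDOWS = {
    "left": {"active": (4.0, 6.0), "control": (8.0, 10.0)},
    "right": {"active": (2.0, 4.0), "control": (5.0, 7.0)},
}


@dataclass(frozen=True)
class Epochs:
    """Segmented single-condition trials: (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    fs: float
    condition: str
    channel_indices: np.ndarray  # indices into the recording's channel axis
    labels: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, float))
        object.__setattr__(
            self, "channel_indices", np.asarray(self.channel_indices, int)
        )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def window_slice(self, window) -> slice:
        a = int(round(window[0] * self.fs))
        b = int(round(window[1] * self.fs))
        return slice(a, b)


@dataclass(frozen=True)
class CovarianceModel:
    """Channel covariance with Tikhonov regularization mu (fraction of the
    maximum eigenvalue; 0.05 by default)."""

    matrix: np.ndarray
    mu: float = 0.05
    band: tuple = (13.0, 30.0)

    def __post_init__(self):
        C = np.asarray(self.matrix, float)
        if not np.allclose(C, C.T, atol=1e-12 * max(1.0, np.abs(C).max())):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "matrix", (C + C.T) / 2.0)

    @property
    def regularized(self) -> np.ndarray:
        lam = float(np.linalg.eigvalsh(self.matrix)[-1])
        return self.matrix + self.mu * lam * np.eye(len(self.matrix))


@dataclass(frozen=True)
class BeamformerSolution:
    """Unit-gain LCMV weights and the chosen source orientation."""

    weights: np.ndarray  # (n_channels,)
    orientation: np.ndarray  # (2,) in the source-tangential basis
    unit_gain: bool = True


@dataclass(frozen=True)
class SourceImage:
    """Voxelized pseudo-T image on a regular axis-aligned grid."""

    grid: np.ndarray  # (n_vox, 3) m
    values: np.ndarray  # (n_vox,)
    spacing: float  # m
    windows: dict = field(default_factory=dict)
    mode: str = "triaxial"


def preprocess(
    rec: Recording,
    exclude_sensors=(),
    exclude_channels=(),
    trial_s: float | None = None,
) -> dict:
    """Mean-correct, apply the channel exclusion list, and segment on stimulus
    triggers into left- and right-handed condition epochs."""
    stim = [(s, lbl) for s, lbl in rec.triggers if lbl == "stimulus"]
    blocks = [(s, lbl) for s, lbl in rec.triggers if lbl.startswith("block_")]
    if not stim or not blocks:
        raise ValueError("recording has no stimulus/block triggers; cannot segment")
    if trial_s is None:
        para = rec.provenance.get("paradigm", {})
        trial_s = para.get("stimulus_s", 5.0) + para.get("rest_s", 7.0)
    n_trial = int(round(trial_s * rec.fs))

    keep = np.ones(rec.n_channels, dtype=bool)
    for s in exclude_sensors:
        keep[3 * s : 3 * s + 3] = False
    for c in exclude_channels:
        keep[c] = False
    idx = np.flatnonzero(keep)

    data = rec.data[idx]
    data = data - data.mean(axis=1, keepdims=True)

    out = {}
    for sample, lbl in blocks:
        cond = lbl.removeprefix("block_")
        trials = []
        for s, _ in stim:
            # stimulus belongs to the latest block starting at or before it
            starts = [bs for bs, _ in blocks if bs <= s]
            if starts and starts[-1] == sample and s + n_trial <= data.shape[1]:
                seg = data[:, s : s + n_trial]
                trials.append(seg - seg.mean(axis=1, keepdims=True))
        if trials:
            out[cond] = Epochs(
                np.stack(trials),
                rec.fs,
                cond,
                idx,
                labels=tuple(rec.array.labels[i] for i in idx),
            )
    return out


def bandpass(x: np.ndarray, lo: float = 13.0, hi: float = 30.0, fs: float = 1200.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    if hi >= fs / 2.0:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


def estimate_covariance(trials: np.ndarray, mu: float = 0.05,
                        band=(13.0, 30.0)) -> CovarianceModel:
    """Covariance of concatenated (already band-filtered) trials
    (n_trials, n_channels, n_samples)."""
    x = np.asarray(trials, float)
    if x.ndim == 2:
        x = x[None]
    nch = x.shape[1]
    cat = x.transpose(1, 0, 2).reshape(nch, -1)
    if cat.shape[1] < 2 * nch:
        raise ValueError("need at least 2x channels of samples for covariance")
    cat = cat - cat.mean(axis=1, keepdims=True)
    C = cat @ cat.T / (cat.shape[1] - 1)
    if np.linalg.matrix_rank(C) < nch and mu == 0:
        warnings.warn("rank-deficient covariance with no regularization")
    return CovarianceModel(C, mu=mu, band=tuple(band))


def lcmv(cov: CovarianceModel, L: np.ndarray) -> BeamformerSolution:
    """LCMV weights with the max-SNR source orientation for leadfield L
    (n_channels x 2)."""
    L = np.asarray(L, float)
    Creg = cov.regularized
    cho = linalg.cho_factor(Creg)
    CiL = linalg.cho_solve(cho, L)  # C^-1 L
    B = L.T @ CiL  # L' C^-1 L
    A = CiL.T @ CiL  # L' C^-2 L
    if np.linalg.cond(B) > 1e12:
        raise ValueError("orientation-ambiguous source: L'C^-1L is singular")
    # minimum-eigenvalue generalized eigenvector maximizes output SNR
    vals, vecs = linalg.eigh(A, B)
    eta = vecs[:, 0]
    eta = eta / np.linalg.norm(eta)
    if eta[np.argmax(np.abs(eta))] < 0:  # eigenvector sign is arbitrary; pin it
        eta = -eta
    denom = eta @ B @ eta
    w = CiL @ eta / denom
    return BeamformerSolution(weights=w, orientation=eta)


def _power_per_second(w: np.ndarray, stacked: np.ndarray, fs: float) -> float:
    """Mean squared beamformer output per second over stacked window samples."""
    s = w @ stacked
    return float(np.sum(s**2) * fs / s.size) if s.size else 0.0


def pseudo_t_image(
    epochs: Epochs,
    array: SensorArray,
    head: HeadModel,
    grid: np.ndarray,
    windows: dict | None = None,
    mode: str = "triaxial",
    mu: float = 0.05,
    spacing: float = 0.004,
    normalization: str = "noise",
) -> SourceImage:
    """Pseudo-T image over a voxel grid for one (band-filtered) condition.

    ``windows`` holds "active" and "control" (s relative to stimulus onset);
    defaults to the imaging preset for the epochs' condition. ``mode`` =
    "radial" restricts all stages to the radially tagged channels;
    ``normalization`` selects the noise-normalized ("noise") or bounded
    power-ratio ("ratio") pseudo-T form.
    """
    if windows is None:
        windows = IMAGING_WINDOWS[epochs.condition]
    act = epochs.window_slice(windows["active"])
    ctl = epochs.window_slice(windows["control"])
    if act.stop <= act.start or ctl.stop <= ctl.start:
        raise ValueError("active/control windows are empty")
    if mode == "radial":
        chan_sel = np.flatnonzero(array.radial_tags[epochs.channel_indices])
    elif mode == "triaxial":
        chan_sel = np.arange(epochs.n_channels)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if normalization not in ("noise", "ratio"):
        raise ValueError(f"unknown normalization {normalization!r}")
    x = epochs.data[:, chan_sel, :]
    cov = estimate_covariance(x, mu=mu)
    # sensor-noise floor: the flat bottom of the covariance spectrum
    noise_var = float(np.linalg.eigvalsh(cov.matrix)[0])
    Xa = x[:, :, act].transpose(1, 0, 2).reshape(len(chan_sel), -1)
    Xc = x[:, :, ctl].transpose(1, 0, 2).reshape(len(chan_sel), -1)
    full_rows = epochs.channel_indices[chan_sel]
    grid = np.asarray(grid, float).reshape(-1, 3)
    values = np.zeros(len(grid))
    for v, pos in enumerate(grid):
        L = leadfield(array, pos, head)[full_rows]
        sol = lcmv(cov, L)
        pa = _power_per_second(sol.weights, Xa, epochs.fs)
        pc = _power_per_second(sol.weights, Xc, epochs.fs)
        if normalization == "noise":
            pn = noise_var * float(sol.weights @ sol.weights) * epochs.fs
            values[v] = (pa - pc) / (2.0 * pn) if pn > 0 else 0.0
        else:
            tot = pa + pc
            values[v] = (pa - pc) / tot if tot > 0 else 0.0
    return SourceImage(grid=grid, values=values, spacing=spacing,
                       windows=dict(windows), mode=mode)


def cubic_grid(center, half_extent: float, spacing: float) -> np.ndarray:
    """Axis-aligned cubic voxel grid (n,3) around ``center`` (m)."""
    c = np.asarray(center, float)
    ax = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return c + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def peak_and_repeatability(images: list, mask=None):
    """Per-run extremum voxel of |T| and the scatter about the mean location.

    Returns (peaks (n_runs, 3) m, distances_mm (n_runs,), mean_distance_mm).
    ``mask`` is a boolean voxel selector (e.g. one hemisphere); ties break to
    the lowest voxel index.
    """
    if len(images) < 2:
        raise ValueError("repeatability needs at least 2 runs")
    peaks = []
    for img in images:
        vals = np.abs(img.values)
        if mask is not None:
            m = np.asarray(mask, bool)
            if not m.any():
                raise ValueError("empty hemisphere mask")
            vals = np.where(m, vals, -np.inf)
        peaks.append(img.grid[int(np.argmax(vals))])
    peaks = np.asarray(peaks)
    center = peaks.mean(axis=0)
    dist_mm = np.linalg.norm(peaks - center, axis=1) * 1000.0
    return peaks, dist_mm, float(dist_mm.mean())


def virtual_electrode(sol: BeamformerSolution, data: np.ndarray) -> np.ndarray:
    """Source time course s(t) = w'x(t); data is (..., n_channels, n_samples)."""
    x = np.asarray(data, float)
    return np.einsum("c,...ct->...t", sol.weights, x)
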