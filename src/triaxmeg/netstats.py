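"""Envelope, connectivity, and repeatability statistics.

Amplitude-envelope correlation (AEC) with pairwise leakage orthogonalization:
for each unordered region pair the beta-band time course of one region is
regressed out of the other (exact for zero-lag linear leakage), Hilbert
envelopes are computed, downsampled to 10 Hz by anti-alias block averaging,
and Pearson-correlated; averaging the two regression directions keeps the
78 x 78 connectome symmetric.

Fingerprinting: with 8 runs per participant, run-level feature vectors give
28 + 28 = 56 within-participant and 8 x 8 = 64 between-participant Pearson
correlations; the observed statistic is mean(between) - mean(within)
(expected negative when individuals are distinguishable) and its
significance comes from a Monte-Carlo permutation of the 120 values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .recon import bandpass

__all__ = [
    "EnvelopeTrace",
    "Connectome",
    "FingerprintResult",
    "hilbert_envelope",
    "tfs",
    "aec_connectome",
    "connectivity_summaries",
    "beta_modulation",
    "channel_snr",
    "interference_ratio",
    "ranksum_bonferroni",
    "fingerprint_test",
    "interference_bands",
    "default_tfs_bands",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnvelopeTrace:
    """Non-negative amplitude envelope with its sampling rate and band."""

    env: np.ndarray
    fs: float
    band: tuple = (13.0, 30.0)

    def __post_init__(self):
        e = np.asarray(self.env, float)
        if np.any(e < 0):
            raise ValueError("envelope must be non-negative")
        object.__setattr__(self, "env", e)


@dataclass(frozen=True)
class Connectome:
    """Symmetric region x region envelope-correlation matrix."""

    matrix: np.ndarray
    labels: tuple = ()
    condition: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("connectome must be square")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite], atol=1e-10):
            raise ValueError("connectome must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n_regions(self) -> int:
        return len(self.matrix)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.matrix[iu]


@dataclass(frozen=True)
class FingerprintResult:
    """Within/between run-correlation contrast and its permutation p-value."""

    within: np.ndarray  # (56,)
    between: np.ndarray  # (64,)
    observed: float  # mean(between) - mean(within)
    p_value: float
    n_perm: int


def hilbert_envelope(x: np.ndarray, fs: float, trim_s: float = 0.0) -> EnvelopeTrace:
    """Magnitude of the analytic signal along the last axis; ``trim_s`` seconds
    are dropped from each end to discard edge transients."""
    x = np.asarray(x, float)
    env = np.abs(signal.hilbert(x, axis=-1))
    pad = int(round(trim_s * fs))
    if pad > 0:
        env = env[..., pad:-pad]
    return EnvelopeTrace(env, fs)


def default_tfs_bands(lo: float = 1.0, hi: float = 48.0, width: float = 2.0,
                      step: float = 1.0) -> list:
    """Overlapping 2 Hz bands stepping 1 Hz across 1-48 Hz (broadband TFS)."""
    bands = []
    f = lo
    while f + width <= hi + 1e-9:
        bands.append((f, f + width))
        f += step
    return bands


def interference_bands() -> list:
    """1.5 Hz-wide overlapping bands across 13-30 Hz (interference TFS preset)."""
    bands = []
    f = 13.0
    while f + 1.5 <= 30.0 + 1e-9:
        bands.append((f, f + 1.5))
        f += 0.75
    return bands


def tfs(trials: np.ndarray, fs: float, bands=None) -> tuple[np.ndarray, list]:
    """Trial-averaged time-frequency spectrum of a source time course.

    ``trials`` is (n_trials, n_samples) (a 1-D input is one trial). Per band:
    zero-phase band-pass, Hilbert envelope, average across trials; rows are
    stacked low-to-high frequency. Returns (n_bands x n_samples, bands).
    """
    x = np.atleast_2d(np.asarray(trials, float))
    if bands is None:
        bands = default_tfs_bands()
    nyq = fs / 2.0
    rows = []
    for lo, hi in bands:
        if hi >= nyq:
            raise ValueError(f"band ({lo}, {hi}) Hz exceeds Nyquist {nyq} Hz")
        filt = bandpass(x, lo, hi, fs=fs)
        rows.append(np.abs(signal.hilbert(filt, axis=-1)).mean(axis=0))
    return np.vstack(rows), list(bands)


def _block_average(x: np.ndarray, fs: float, target_fs: float = 10.0) -> np.ndarray:
    """Anti-alias downsampling by non-overlapping block means."""
    step = int(round(fs / target_fs))
    n = (x.shape[-1] // step) * step
    return x[..., :n].reshape(*x.shape[:-1], -1, step).mean(axis=-1)


def aec_connectome(region_tcs: np.ndarray, fs: float, labels=(),
                   condition: str = "", env_fs: float = 10.0) -> Connectome:
    """Orthogonalized amplitude-envelope-correlation connectome.

    ``region_tcs`` is (n_regions, n_samples) of beta-band time courses.
    Hilbert transforms are linear, so the analytic signal of the
    leakage-orthogonalized residual B - (A.B/A.A) A is formed from
    precomputed per-region analytic signals. Regions with zero variance get
    NaN edges (flagged and logged).
    """
    x = np.asarray(region_tcs, float)
    n = x.shape[0]
    var = x.var(axis=1)
    dead = var < 1e-30
    if dead.any():
        logger.warning("zero-variance regions %s: edges set to NaN",
                       np.flatnonzero(dead).tolist())
    analytic = signal.hilbert(x, axis=-1)
    own_env = _block_average(np.abs(analytic), fs, env_fs)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    dots = x @ x.T  # zero-lag inner products for the regressions
    for i, j in itertools.combinations(range(n), 2):
        if dead[i] or dead[j]:
            continue
        # regress i out of j, and j out of i
        rs = []
        for a, b in ((i, j), (j, i)):
            c = dots[a, b] / dots[a, a]
            resid = analytic[b] - c * analytic[a]
            # fully explained by leakage: nothing left to correlate
            if np.mean(np.abs(resid) ** 2) < 1e-12 * np.mean(np.abs(analytic[b]) ** 2):
                rs.append(0.0)
                continue
            resid_env = _block_average(np.abs(resid), fs, env_fs)
            if resid_env.std() < 1e-30 or own_env[a].std() < 1e-30:
                rs.append(np.nan)
            else:
                rs.append(np.corrcoef(own_env[a], resid_env)[0, 1])
        mat[i, j] = mat[j, i] = np.nanmean(rs)
    return Connectome(mat, labels=tuple(labels), condition=condition)


def connectivity_summaries(c: Connectome, node: int | None = None):
    """Whole-brain connectivity (sum over the n(n-1)/2 unique pairs) and,
    if ``node`` is given, that region's strength (sum of its n-1 edges)."""
    total = float(np.nansum(c.upper_triangle()))
    if node is None:
        return total, None
    if not 0 <= node < c.n_regions:
        raise ValueError(f"node {node} out of range for {c.n_regions} regions")
    row = np.delete(c.matrix[node], node)
    return total, float(np.nansum(row))


def beta_modulation(env: EnvelopeTrace, active, control) -> float:
    """Task beta-modulation amplitude: mean envelope in the control (rebound)
    window minus the active (ERD) window — positive for the canonical
    suppression-then-rebound response."""
    e = env.env
    a = slice(int(round(active[0] * env.fs)), int(round(active[1] * env.fs)))
    c = slice(int(round(control[0] * env.fs)), int(round(control[1] * env.fs)))
    if a.stop <= a.start or c.stop <= c.start:
        raise ValueError("empty modulation window")
    return float(e[..., c].mean() - e[..., a].mean())


def channel_snr(env: np.ndarray, fs: float, active, control) -> np.ndarray:
    """Per-channel SNR: |active-control mean envelope difference| divided by
    the envelope standard deviation in the active window.

    ``env`` is (n_channels, n_samples) of trial-averaged envelopes.
    """
    e = np.atleast_2d(np.asarray(env, float))
    a = slice(int(round(active[0] * fs)), int(round(active[1] * fs)))
    c = slice(int(round(control[0] * fs)), int(round(control[1] * fs)))
    sd = e[:, a].std(axis=1)
    if np.any(sd < 1e-300):
        raise ValueError("zero envelope variance in the active window")
    return np.abs(e[:, a].mean(axis=1) - e[:, c].mean(axis=1)) / sd


def interference_ratio(x: np.ndarray, fs: float, line: float = 16.6,
                       neighbors=(15.5, 17.7), df: float = 0.1) -> float:
    """Excess PSD at the interference line over its neighbours:
    (PSD(line) - mean PSD(neighbors)) / mean PSD(neighbors).

    Welch estimate with bin spacing ``df`` chosen so all three frequencies
    sit exactly on bins (75% segment overlap for variance). The line PSD is
    the single bin at ``line``; the neighbour level is the local mean over
    +-0.3 Hz around each neighbour frequency, a lower-variance estimate of
    the smooth background at those frequencies.
    """
    x = np.asarray(x, float)
    nperseg = int(round(fs / df))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"record too short to resolve {df} Hz bins: need {nperseg} samples"
        )
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg,
                              noverlap=3 * nperseg // 4)
    line_psd = psd[..., int(np.argmin(np.abs(freqs - line)))]
    neigh_vals = []
    for f in neighbors:
        band = np.abs(freqs - f) <= 0.3 + 1e-9
        neigh_vals.append(psd[..., band].mean())
    neigh = np.mean(neigh_vals)
    return float((line_psd - neigh) / neigh)


def ranksum_bonferroni(group_a, group_b, m_tests: int = 1):
    """Two-sided Wilcoxon rank-sum test with Bonferroni correction.

    Exact enumeration for small tie-free samples (n <= 10 per group, the
    study's regime), tie-corrected normal approximation otherwise. Returns
    (rank-sum statistic of group A, p, corrected p).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("missing values are not allowed")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        ranks = stats.rankdata(pooled)
        return float(ranks[: len(a)].sum()), 1.0, 1.0
    method = "exact" if (not has_ties and max(len(a), len(b)) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    w = u + len(a) * (len(a) + 1) / 2.0  # convert U to the rank-sum of A
    p = float(res.pvalue)
    return w, p, min(1.0, m_tests * p)


def fingerprint_test(items: np.ndarray, n_perm: int = 100_000,
                     seed: int = 0) -> FingerprintResult:
    """Permutation test of participant identifiability from run-level vectors.

    ``items`` is (16, n_features): rows 0-7 are participant 1's runs, rows
    8-15 participant 2's. Pearson correlations give 56 within- and 64
    between-participant values; p = (1 + #{sham <= observed}) / (n_perm + 1)
    for the one-sided hypothesis within > between.
    """
    x = np.asarray(items, float)
    if x.shape[0] != 16:
        raise ValueError("expected 16 run vectors (8 per participant)")
    corr = np.corrcoef(x)
    within = np.array(
        [corr[i, j] for g in (range(8), range(8, 16))
         for i, j in itertools.combinations(g, 2)]
    )
    between = corr[:8, 8:].ravel()
    observed = float(between.mean() - within.mean())
    values = np.concatenate([between, within])  # 120 values
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    sham = perms[:, :64].mean(axis=1) - perms[:, 64:].mean(axis=1)
    p = (1.0 + np.count_nonzero(sham <= observed)) / (n_perm + 1.0)
    return FingerprintResult(within=within, between=between, observed=observed,
                             p_value=float(p), n_perm=n_perm)
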