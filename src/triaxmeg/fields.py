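"""Forward models for every magnetic-field contributor.

Neural sources are current dipoles in a homogeneous conducting sphere
(Sarvas closed form, volume currents included); the environmental remnant
field is a uniform vector plus a symmetric trace-free linear gradient; the
compensation coil system maps eight currents to the eight field/gradient
coefficients; environmental interference is a narrowband line source.

Units: tesla and meters internally; BackgroundField coefficients are in
nT and nT/m, the units the coil hardware is specified in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import HeadModel, SensorArray

__all__ = [
    "Dipole",
    "BackgroundField",
    "CoilSystem",
    "InterferenceSource",
    "dipole_field",
    "leadfield",
    "background_at",
    "interference_at",
    "source_tangential_basis",
]

logger = logging.getLogger(__name__)

MU0_OVER_4PI = 1e-7  # T·m/A
NT = 1e-9  # tesla per nanotesla

#: Order of the 5 independent gradient coefficients (nT/m); Gzz = -Gxx-Gyy.
GRADIENT_COMPONENTS = ("Gxx", "Gyy", "Gxy", "Gxz", "Gyz")


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m, inside the head sphere), moment (A·m)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float).reshape(3))
        object.__setattr__(self, "moment", np.asarray(self.moment, float).reshape(3))


@dataclass(frozen=True)
class BackgroundField:
    """Quasi-static remnant field: uniform b0 (nT) and 5 gradient coefficients g (nT/m)."""

    b0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    g: np.ndarray = field(default_factory=lambda: np.zeros(5))

    def __post_init__(self):
        object.__setattr__(self, "b0", np.asarray(self.b0, float).reshape(3))
        object.__setattr__(self, "g", np.asarray(self.g, float).reshape(5))

    def gradient_tensor(self) -> np.ndarray:
        """Assemble the symmetric trace-free 3x3 gradient tensor (nT/m)."""
        gxx, gyy, gxy, gxz, gyz = self.g
        return np.array(
            [
                [gxx, gxy, gxz],
                [gxy, gyy, gyz],
                [gxz, gyz, -gxx - gyy],
            ]
        )

    @property
    def coefficients(self) -> np.ndarray:
        """The 8-vector (b0 in nT, g in nT/m) the coil system works in."""
        return np.concatenate([self.b0, self.g])

    @classmethod
    def from_coefficients(cls, coeffs) -> "BackgroundField":
        c = np.asarray(coeffs, float).reshape(8)
        return cls(c[:3], c[3:])

    def uniform_norm(self) -> float:
        """Euclidean norm of the three uniform components (nT)."""
        return float(np.linalg.norm(self.b0))

    def gradient_norm(self) -> float:
        """Euclidean norm of the five gradient coefficients (nT/m)."""
        return float(np.linalg.norm(self.g))

    def __add__(self, other: "BackgroundField") -> "BackgroundField":
        return BackgroundField(self.b0 + other.b0, self.g + other.g)

    def to_config(self) -> dict:
        return {"b0_nT": self.b0.tolist(), "g_nT_per_m": self.g.tolist()}

    @classmethod
    def from_config(cls, cfg: dict) -> "BackgroundField":
        return cls(np.asarray(cfg["b0_nT"], float), np.asarray(cfg["g_nT_per_m"], float))


@dataclass(frozen=True)
class CoilSystem:
    """Biplanar coil set: calibration maps 8 coil currents to the 8 produced
    (b0, g) coefficients, nT (or nT/m) per unit current."""

    calibration: np.ndarray

    def __post_init__(self):
        cal = np.asarray(self.calibration, float).reshape(8, 8)
        object.__setattr__(self, "calibration", cal)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.calibration))

    def field_from_currents(self, currents) -> BackgroundField:
        return BackgroundField.from_coefficients(self.calibration @ np.asarray(currents, float))

    @classmethod
    def nominal(cls, leakage: float = 0.05, seed: int = 0) -> "CoilSystem":
        """Identity-like calibration with seeded off-diagonal leakage, emulating
        imperfect coil orthogonality while staying well-conditioned."""
        rng = np.random.default_rng(seed)
        cal = np.eye(8) + leakage * rng.standard_normal((8, 8))
        return cls(cal)

    def to_config(self) -> dict:
        return {"calibration": self.calibration.tolist()}

    @classmethod
    def from_config(cls, cfg: dict) -> "CoilSystem":
        return cls(np.asarray(cfg["calibration"], float))


@dataclass(frozen=True)
class InterferenceSource:
    """Narrowband environmental interference (e.g. a 16.6 Hz machine line).

    ``position`` places a far magnetic dipole whose pattern is evaluated at the
    sensors; ``amplitude`` is the field magnitude (tesla) it produces at the
    origin. With ``position=None`` the pattern is a spatially uniform field
    along ``direction``.
    """

    frequency: float = 16.6
    amplitude: float = 1e-12
    position: np.ndarray | None = field(default_factory=lambda: np.array([5.0, 0.0, 0.0]))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    phase: float = 0.0

    def __post_init__(self):
        if not self.frequency > 0:
            raise ValueError("interference frequency must be positive")
        if self.position is not None:
            object.__setattr__(self, "position", np.asarray(self.position, float).reshape(3))
        d = np.asarray(self.direction, float).reshape(3)
        object.__setattr__(self, "direction", d / np.linalg.norm(d))

    def pattern(self, points: np.ndarray) -> np.ndarray:
        """(n,3) field pattern (tesla, unit sine amplitude) at the given points."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.position is None:
            return np.broadcast_to(self.amplitude * self.direction, pts.shape).copy()
        # free-space magnetic dipole at self.position, moment along direction
        r = pts - self.position
        rn = np.linalg.norm(r, axis=1, keepdims=True)
        rhat = r / rn
        m = self.direction
        b = (3.0 * rhat * (rhat @ m)[:, None] - m) / rn**3
        # scale so |B| at the origin equals amplitude
        r0 = -self.position
        r0n = np.linalg.norm(r0)
        b0 = (3.0 * (r0 / r0n) * ((r0 / r0n) @ m) - m) / r0n**3
        return self.amplitude * b / np.linalg.norm(b0)


def dipole_field(d: Dipole, at: np.ndarray, head: HeadModel) -> np.ndarray:
    """Magnetic field (tesla) of a current dipole in a homogeneous conducting
    sphere, evaluated outside the sphere (Sarvas closed form).

    Includes the volume-current contribution; linear in the dipole moment.
    Raises if the observation point is inside the sphere or the dipole outside.
    """
    at = np.asarray(at, float).reshape(3)
    r0 = d.position - head.center
    r = at - head.center
    if np.linalg.norm(r0) >= head.radius:
        raise ValueError("dipole must lie strictly inside the head sphere")
    if np.linalg.norm(r) <= head.radius:
        raise ValueError("observation point must lie strictly outside the head sphere")
    return _sarvas(d.moment, r0, r[None, :])[0]


def _sarvas(q: np.ndarray, r0: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Sarvas formula: field of dipole (moment q at r0, sphere center at origin)
    at points r (n,3). Vectorized over observation points."""
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    f = a * (rn * a + rn**2 - r0_dot_r)
    a_dot_r = np.einsum("ni,ni->n", a_vec, r)
    grad_f = (
        (a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0
    )
    q_x_r0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * q_x_r0 - (r @ q_x_r0)[:, None] * grad_f
    )
    return b


def source_tangential_basis(source_pos: np.ndarray, head: HeadModel):
    """Two unit vectors tangential to the head sphere at the source location
    (the polar/azimuthal dipole orientations MEG can see).

    For a source on the vertical axis through the center the azimuth is
    undefined; a deterministic fallback aligned with +x is used and logged.
    """
    u = np.asarray(source_pos, float).reshape(3) - head.center
    un = np.linalg.norm(u)
    if un < 1e-12:
        logger.info("source at sphere center: using canonical tangential basis")
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    u = u / un
    zhat = np.array([0.0, 0.0, 1.0])
    e_phi = np.cross(zhat, u)
    n = np.linalg.norm(e_phi)
    if n < 1e-9:
        logger.info("source on the z-axis: falling back to x-aligned tangential basis")
        e_phi = np.array([0.0, 1.0, 0.0])
        e_theta = np.cross(e_phi, u)
    else:
        e_phi = e_phi / n
        e_theta = np.cross(e_phi, u)
    return e_theta, e_phi


def leadfield(array: SensorArray, source_pos: np.ndarray, head: HeadModel) -> np.ndarray:
    """Leadfield matrix (n_channels x 2), tesla per A·m: channel responses to
    unit dipoles along the two source-tangential orientations."""
    source_pos = np.asarray(source_pos, float).reshape(3)
    if np.linalg.norm(source_pos - head.center) >= head.radius:
        raise ValueError("source must lie strictly inside the head sphere")
    r = array.positions - head.center
    if np.any(np.linalg.norm(r, axis=1) <= head.radius):
        raise ValueError("all sensors must lie strictly outside the head sphere")
    e_theta, e_phi = source_tangential_basis(source_pos, head)
    r0 = source_pos - head.center
    orient = array.channel_orientations()  # (3n, 3)
    L = np.empty((array.n_channels, 2))
    for k, q in enumerate((e_theta, e_phi)):
        b = _sarvas(q, r0, r)  # (n_sensors, 3)
        b_ch = np.repeat(b, 3, axis=0)
        L[:, k] = np.einsum("ci,ci->c", b_ch, orient)
    return L


def oriented_leadfields(
    array: SensorArray, positions: np.ndarray, orientations: np.ndarray, head: HeadModel
) -> np.ndarray:
    """(n_channels, n_sources) responses to unit dipoles with fixed orientations.

    Batched Sarvas evaluation over sources; radial moment components produce
    no external field in a spherical conductor, so passing tangential
    orientations is equivalent to projecting the 2-column leadfield.
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    q = np.asarray(orientations, float).reshape(-1, 3)
    r = array.positions - head.center  # (n, 3)
    r0 = pos - head.center  # (m, 3)
    if np.any(np.linalg.norm(r0, axis=1) >= head.radius):
        raise ValueError("all sources must lie strictly inside the head sphere")
    a_vec = r[None, :, :] - r0[:, None, :]  # (m, n, 3)
    a = np.linalg.norm(a_vec, axis=2)
    rn = np.linalg.norm(r, axis=1)  # (n,)
    r0_dot_r = r0 @ r.T  # (m, n)
    f = a * (rn * a + rn**2 - r0_dot_r)
    adotr = np.einsum("mni,ni->mn", a_vec, r)
    c1 = a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + adotr / a
    grad_f = c1[..., None] * r[None, :, :] - c2[..., None] * r0[:, None, :]
    q_x_r0 = np.cross(q, r0)  # (m, 3)
    rdot = np.einsum("nj,mj->mn", r, q_x_r0)
    b = (MU0_OVER_4PI / f[..., None] ** 2) * (
        f[..., None] * q_x_r0[:, None, :] - rdot[..., None] * grad_f
    )  # (m, n, 3)
    proj = np.einsum("mni,nik->mnk", b, array.axes)  # (m, n, 3 axes)
    return proj.reshape(len(pos), -1).T  # (n_channels, m)


def background_at(bg: BackgroundField, at: np.ndarray) -> np.ndarray:
    """Background field B(p) = b0 + G p (nT) at point(s) p (m)."""
    at = np.asarray(at, float)
    return bg.b0 + at @ bg.gradient_tensor().T


def interference_at(src: InterferenceSource, array: SensorArray, t) -> np.ndarray:
    """Per-channel interference (tesla) at time(s) t (s).

    Returns (n_channels,) for scalar t, else (n_channels, n_times).
    """
    pattern = src.pattern(array.positions)  # (n_sensors, 3)
    pattern_ch = np.repeat(pattern, 3, axis=0)
    orient = array.channel_orientations()
    proj = np.einsum("ci,ci->c", pattern_ch, orient)
    t = np.asarray(t, float)
    carrier = np.sin(2.0 * np.pi * src.frequency * t + src.phase)
    if carrier.ndim == 0:
        return proj * float(carrier)
    return proj[:, None] * carrier[None, :]
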