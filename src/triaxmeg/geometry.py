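"""Sensor-array geometry, rigid-body motion, and sphere fitting.

Head coordinate convention: right-handed, origin at the head-sphere center,
x anterior, y left, z superior; all lengths in meters.

A triaxial sensor carries an orthonormal axis triad; by construction the
third axis (tag ``z``) points radially outward from the head-sphere center
and the other two are tangential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensorArray",
    "RigidTransform",
    "MotionTrace",
    "HeadModel",
    "build_helmet_array",
    "apply_motion",
    "fit_sphere",
    "radial_tangential_basis",
]

_ORTHO_TOL = 1e-10
_AXIS_TAGS = ("x", "y", "z")

#: Minimum center-to-center sensor spacing a helmet can realise (m).
MIN_SENSOR_SPACING = 0.025


@dataclass(frozen=True)
class HeadModel:
    """Best-fit sphere standing in for the head: center (m) and radius (m)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", center)
        if not self.radius > 0:
            raise ValueError(f"head radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform p -> R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not orthogonal (R^T R != I)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is improper (det R = -1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def _trusted(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        """Skip validation for matrices known proper by construction
        (batch-generated trajectories); not part of the public surface."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "rotation", rotation)
        object.__setattr__(obj, "translation", translation)
        return obj

    @classmethod
    def from_euler(cls, angles_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotation (degrees) plus translation (m)."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", np.asarray(angles_deg, float), degrees=True)
        return cls(R.as_matrix(), np.asarray(translation, float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-helmet pose trajectory sampled at a fixed rate (default 120 Hz)."""

    timestamps: np.ndarray
    poses: tuple
    fs: float = 120.0

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1 or len(ts) != len(self.poses):
            raise ValueError("timestamps and poses must have equal length")
        if len(ts) > 1:
            dt = np.diff(ts)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs, atol=1e-9):
                raise ValueError(f"timestamps must be uniform at {self.fs} Hz")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "poses", tuple(self.poses))

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SensorArray:
    """Triaxial sensor array: positions (n,3) m, axis triads (n,3,3), channel labels.

    ``axes[i]`` has the sensor's sensitive axes as *columns* (x, y, z order);
    channel ``3*i + k`` measures the field projection onto ``axes[i][:, k]``.
    ``radial_tags`` marks, per channel, whether its axis is the radial one.
    """

    positions: np.ndarray
    axes: np.ndarray
    labels: tuple = ()
    radial_tags: np.ndarray = field(default=None)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        axes = np.asarray(self.axes, dtype=float).reshape(-1, 3, 3)
        if len(pos) != len(axes):
            raise ValueError("positions and axes must match in sensor count")
        gram = np.einsum("nij,nik->njk", axes, axes)
        if not np.allclose(gram, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("sensor axis triads must be orthonormal")
        labels = tuple(self.labels) if self.labels else tuple(
            f"S{i:02d}-{tag}" for i in range(len(pos)) for tag in _AXIS_TAGS
        )
        if len(labels) != 3 * len(pos):
            raise ValueError("need one label per channel (3 per sensor)")
        tags = self.radial_tags
        if tags is None:
            tags = np.zeros(3 * len(pos), dtype=bool)
        tags = np.asarray(tags, dtype=bool).reshape(3 * len(pos))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "radial_tags", tags)

    @property
    def n_sensors(self) -> int:
        return len(self.positions)

    @property
    def n_channels(self) -> int:
        return 3 * len(self.positions)

    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3) sensor position repeated per axis."""
        return np.repeat(self.positions, 3, axis=0)

    def channel_orientations(self) -> np.ndarray:
        """(n_channels, 3) unit vector of each channel's sensitive axis."""
        return self.axes.transpose(0, 2, 1).reshape(-1, 3)

    def radial_channel_indices(self) -> np.ndarray:
        return np.flatnonzero(self.radial_tags)

    def channel_table(self) -> list:
        """JSON-serializable channel table (one row per channel)."""
        orient = self.channel_orientations()
        pos = self.channel_positions()
        return [
            {
                "label": self.labels[c],
                "sensor": c // 3,
                "axis": _AXIS_TAGS[c % 3],
                "radial": bool(self.radial_tags[c]),
                "position_m": pos[c].tolist(),
                "orientation": orient[c].tolist(),
            }
            for c in range(self.n_channels)
        ]


def _cap_directions(n: int, theta_max_rad: float) -> np.ndarray:
    """Near-uniform unit vectors on the polar cap theta <= theta_max (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    # equal-area in cos(theta) over the cap
    cos_t = 1.0 - (k / n) * (1.0 - np.cos(theta_max_rad))
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def build_helmet_array(
    n_sensors: int,
    scalp_radius: float = 0.09,
    coverage_deg: float = 60.0,
    standoff: float = 0.0065,
    center=(0.0, 0.0, 0.0),
) -> SensorArray:
    """Place triaxial sensors quasi-uniformly on a spherical cap about +z.

    The cap (angular radius ``coverage_deg`` about the vertex) covers the
    left and right sensorimotor strips. Sensors sit ``standoff`` m above the
    scalp sphere of radius ``scalp_radius``; the triad z-axis points radially
    outward and is tagged as the radial channel.
    """
    if n_sensors < 1:
        raise ValueError("n_sensors must be >= 1")
    r = scalp_radius + standoff
    theta = np.deg2rad(coverage_deg)
    cap_area = 2.0 * np.pi * r**2 * (1.0 - np.cos(theta))
    max_sites = max(1, int(cap_area / MIN_SENSOR_SPACING**2))
    if n_sensors > max_sites:
        raise ValueError(
            f"cannot place {n_sensors} sensors on a {coverage_deg} deg cap of radius "
            f"{r:.3f} m with {MIN_SENSOR_SPACING*100:.1f} cm spacing "
            f"(limit {max_sites} sites)"
        )
    center = np.asarray(center, float).reshape(3)
    u = _cap_directions(n_sensors, theta)  # radial unit vectors
    positions = center + r * u
    axes = np.empty((n_sensors, 3, 3))
    zhat = np.array([0.0, 0.0, 1.0])
    for i, ur in enumerate(u):
        t1 = np.cross(zhat, ur)
        if np.linalg.norm(t1) < 1e-12:  # sensor at the pole
            t1 = np.array([1.0, 0.0, 0.0])
        else:
            t1 = t1 / np.linalg.norm(t1)
        t2 = np.cross(ur, t1)
        axes[i] = np.column_stack([t1, t2, ur])
    tags = np.zeros(3 * n_sensors, dtype=bool)
    tags[2::3] = True  # triad z-axis is radial by construction
    return SensorArray(positions, axes, radial_tags=tags)


def apply_motion(array: SensorArray, pose: RigidTransform) -> SensorArray:
    """Return a moved copy of the array: p -> R p + t, triads -> R triad."""
    return SensorArray(
        pose.apply_points(array.positions),
        np.einsum("ij,njk->nik", pose.rotation, array.axes),
        labels=array.labels,
        radial_tags=array.radial_tags,
    )


def fit_sphere(points: np.ndarray) -> HeadModel:
    """Algebraic least-squares sphere through a point cloud.

    Solves ``|p|^2 = 2 c.p + k`` for center c and k = r^2 - |c|^2; requires
    at least 4 points in general (non-coplanar) position.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 4:
        raise ValueError("degenerate point set (coplanar or coincident); sphere undetermined")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("sphere fit produced non-positive radius")
    return HeadModel(center, float(np.sqrt(r2)))


def radial_tangential_basis(array: SensorArray, head: HeadModel):
    """Per-sensor orthonormal (radial, t1, t2) basis relative to the head sphere.

    Returns (radial, t1, t2), each (n_sensors, 3), with radial pointing
    outward from the sphere center.
    """
    d = array.positions - head.center
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("sensor coincides with the sphere center; basis undefined")
    radial = d / norms[:, None]
    zhat = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(zhat, radial)
    t1n = np.linalg.norm(t1, axis=1)
    degenerate = t1n < 1e-12
    t1[degenerate] = [1.0, 0.0, 0.0]
    t1[~degenerate] /= t1n[~degenerate, None]
    t2 = np.cross(radial, t1)
    return radial, t1, t2


def tag_radial_channels(array: SensorArray, head: HeadModel) -> SensorArray:
    """Re-tag each sensor's radial channel as the axis with max |dot| with the
    outward radial direction; ties broken in axis order x, y, z."""
    radial, _, _ = radial_tangential_basis(array, head)
    dots = np.abs(np.einsum("ni,nik->nk", radial, array.axes))
    best = np.argmax(dots, axis=1)  # argmax keeps the first (x before y before z)
    tags = np.zeros(array.n_channels, dtype=bool)
    tags[3 * np.arange(array.n_sensors) + best] = True
    return SensorArray(array.positions, array.axes, labels=array.labels, radial_tags=tags)
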