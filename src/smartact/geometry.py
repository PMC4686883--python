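"""Coordinate conventions and pipette-axis geometry.

All positions are expressed in microns in a single right-handed stack frame:
``x`` is anterior (the horizontal component of pipette advance), ``y`` is the
orthogonal in-plane axis and ``z`` increases with depth below the top of the
stack.  Voxel indices are 0-based and convert to microns as
``index * voxel_size`` (voxel centers sit on that lattice).

The pipette advances along a unit *axis* pointing forward and downward; the
approach angle is measured below the horizontal (31 degrees in the reference
configuration), so the axis z-component equals ``sin(approach_angle)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "Point3D",
    "PipetteGeometry",
    "SeparationMetrics",
    "axis_from_angles",
    "decompose_separation",
    "voxel_to_micron",
    "micron_to_voxel",
    "rotation_aligning",
    "DEFAULT_VOXEL_SIZE",
    "DEFAULT_APPROACH_ANGLE",
]

#: Reference two-photon configuration: 256 x 256 frames, ~150 planes,
#: (1.23, 1.23, 2) micron voxels, pipette 31 degrees below horizontal.
DEFAULT_VOXEL_SIZE = (1.23, 1.23, 2.0)
DEFAULT_APPROACH_ANGLE = 31.0

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and voxel pitch of a 3D stack; shape is (nx, ny, nz)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size in microns spanned by the voxel centers."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.voxel_size))


@dataclass(frozen=True)
class Point3D:
    """A position in microns in the stack frame."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError(f"coordinates must be finite, got {self}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "Point3D":
        a = np.asarray(arr, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def __add__(self, other) -> "Point3D":
        return Point3D.from_array(self.to_array() + np.asarray(other, dtype=float))

    def __sub__(self, other) -> np.ndarray:
        if isinstance(other, Point3D):
            return self.to_array() - other.to_array()
        return self.to_array() - np.asarray(other, dtype=float)


def axis_from_angles(approach_angle: float, azimuth: float = 0.0) -> np.ndarray:
    """Unit advance vector from an approach angle (degrees below horizontal)
    and an azimuth (degrees in the x-y plane, 0 = +x).

    The returned vector points forward and *down* (positive z = deeper), with
    vertical component ``sin(approach_angle)``.
    """
    if not -90.0 < approach_angle < 90.0:
        raise ValueError(
            f"approach angle must lie in (-90, 90) degrees, got {approach_angle}"
        )
    theta = math.radians(approach_angle)
    phi = math.radians(azimuth)
    return np.array(
        [math.cos(theta) * math.cos(phi), math.cos(theta) * math.sin(phi), math.sin(theta)]
    )


@dataclass(frozen=True)
class PipetteGeometry:
    """Tip position plus the advance axis derived from approach angle/azimuth."""

    tip: Point3D
    approach_angle: float = DEFAULT_APPROACH_ANGLE
    azimuth: float = 0.0
    axis: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", axis_from_angles(self.approach_angle, self.azimuth))


@dataclass(frozen=True)
class SeparationMetrics:
    """Decomposition of a tip-to-target displacement about the pipette axis.

    ``r_lateral`` is the closest distance from the target to the pipette axis
    line; ``r_axial`` is the signed along-axis component (positive when the
    target lies ahead of the tip); ``r_total`` the Euclidean separation.
    """

    r_lateral: float
    r_axial: float
    r_total: float


def _check_unit(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,) or abs(np.linalg.norm(axis) - 1.0) > _UNIT_TOL:
        raise ValueError(f"axis must be a 3D unit vector (tolerance {_UNIT_TOL}), got {axis}")
    return axis


def decompose_separation(tip: Point3D, target: Point3D, axis) -> SeparationMetrics:
    """Split the tip->target displacement into axial and lateral components.

    Satisfies ``r_total**2 == r_lateral**2 + r_axial**2`` and is invariant
    under joint translation of both points and joint rotation of points and
    axis.
    """
    axis = _check_unit(axis)
    d = target - tip
    r_axial = float(d @ axis)
    r_lateral = float(np.linalg.norm(d - r_axial * axis))
    r_total = float(np.linalg.norm(d))
    return SeparationMetrics(r_lateral=r_lateral, r_axial=r_axial, r_total=r_total)


def voxel_to_micron(index, grid: VoxelGrid) -> Point3D:
    """Convert a 0-based voxel index triple to microns (index * voxel_size)."""
    idx = np.asarray(index, dtype=float)
    return Point3D.from_array(idx * np.asarray(grid.voxel_size))


def micron_to_voxel(point: Point3D, grid: VoxelGrid) -> tuple[tuple[int, int, int], bool]:
    """Nearest voxel index for a micron-space point, plus an in-bounds flag.

    Out-of-bounds points are flagged (``False``), not rejected; the returned
    index is clipped to the grid.  Round-trips micron -> voxel -> micron agree
    within half a voxel per axis.
    """
    raw = point.to_array() / np.asarray(grid.voxel_size)
    idx = np.rint(raw).astype(int)
    hi = np.asarray(grid.shape) - 1
    in_bounds = bool(np.all(idx >= 0) and np.all(idx <= hi))
    idx = np.clip(idx, 0, hi)
    return (int(idx[0]), int(idx[1]), int(idx[2])), in_bounds


def rotation_aligning(axis, reference=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Rotation matrix mapping ``axis`` onto ``reference`` (both unit vectors).

    Used to pose point clouds in a target-centered frame with the pipette
    direction as a fixed reference direction.  Distances to the axis line are
    preserved, so lateral/axial decompositions survive the rotation.
    """
    a = _check_unit(axis)
    b = _check_unit(np.asarray(reference, dtype=float))
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        p = p - (p @ a) * a
        p /= np.linalg.norm(p)
        return 2.0 * np.outer(p, p) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
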