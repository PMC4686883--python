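"""Automatic localization of the pipette tip and the target soma.

Operates on freshly acquired two-channel substacks.  The pipette channel
(a fluorescent dye in the pipette internal solution) is processed by
percentile normalization, 3x3x1 boxcar smoothing, maximum-intensity
projection along each axis, per-projection thresholding/segmentation and a
tip-pixel fusion rule.  The cytosolic-label channel is processed by a 3D
Gaussian bandpass (difference of Gaussians) tuned to soma-sized blobs,
thresholding, small-object removal and a nearest-to-nominal center-of-mass
rule.

Arrays are indexed ``[x, y, z]`` to match the ``VoxelGrid`` shape convention;
an ``ImageStack`` carries its grid, channel role and the micron-space origin
of voxel ``(0, 0, 0)`` so region-of-interest substacks keep absolute
coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import (DEFAULT_APPROACH_ANGLE, Point3D, VoxelGrid, axis_from_angles,
                       voxel_to_micron)

__all__ = [
    "ImageStack",
    "RoiSpec",
    "TipLocParams",
    "TargetLocParams",
    "TipEstimate",
    "TargetEstimate",
    "TipNotFoundError",
    "TargetNotFoundError",
    "extract_roi",
    "normalize_substack",
    "smooth_boxcar",
    "max_projections",
    "segment_largest",
    "locate_tip",
    "bandpass_3d",
    "locate_target",
    "load_stack",
    "save_stack",
    "write_report_line",
]

# 2D MIPs use 8-connectivity, 3D volumes 26-connectivity: robust to single
# diagonal gaps from anisotropic voxels.
_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


class TipNotFoundError(RuntimeError):
    """No qualifying pipette object in one of the projections."""

    def __init__(self, projection: str):
        self.projection = projection
        super().__init__(f"no qualifying pipette object in the {projection} projection")


class TargetNotFoundError(RuntimeError):
    """No segmented component survives size filtering."""


@dataclass
class ImageStack:
    """A 3D intensity volume over a voxel grid.

    ``origin`` is the micron-space position of voxel (0, 0, 0), so substacks
    cut from a parent stack report estimates in the parent frame.
    """

    data: np.ndarray
    grid: VoxelGrid
    channel_role: str = "pipette_dye"  # or "cytosolic_label"
    origin: Point3D = field(default_factory=lambda: Point3D(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return ImageStack(data, self.grid, self.channel_role, self.origin)

    def index_to_micron(self, index) -> Point3D:
        return self.origin + voxel_to_micron(index, self.grid).to_array()


@dataclass(frozen=True)
class RoiSpec:
    """A box around an expected tip or cell location, in microns."""

    center: Point3D
    half_extent: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.half_extent):
            raise ValueError("ROI half extents must be positive")


@dataclass(frozen=True)
class TipLocParams:
    upper_percentile: float = 98.0
    threshold_fraction: float = 0.90
    min_object_pixels: int = 10
    n_tip_pixels: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must be in (0, 1]")
        if not 5.0 < self.upper_percentile <= 100.0:
            raise ValueError("upper_percentile must be in (5, 100]")


@dataclass(frozen=True)
class TargetLocParams:
    band_low: float = 2.0
    band_high: float = 20.0
    threshold_fraction: float = 0.90
    min_object_voxels: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if not 0.0 < self.threshold_fraction <= 1.0:
            raise ValueError("threshold_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TipEstimate:
    point: Point3D
    #: redundant x estimate averaged from the x-y projection, kept as a
    #: quality metric together with its disagreement with the adopted x
    quality: dict


@dataclass(frozen=True)
class TargetEstimate:
    point: Point3D
    n_candidates: int
    quality: dict


def extract_roi(stack: ImageStack, roi: RoiSpec) -> ImageStack:
    """Cut a region of interest (clipped to the stack bounds) as a substack."""
    vs = np.asarray(stack.grid.voxel_size)
    center = (roi.center - stack.origin) / vs
    half = np.asarray(roi.half_extent) / vs
    lo = np.maximum(np.floor(center - half).astype(int), 0)
    hi = np.minimum(np.ceil(center + half).astype(int) + 1, np.asarray(stack.grid.shape))
    if np.any(hi <= lo):
        raise ValueError("ROI does not intersect the stack")
    sub = stack.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    origin = stack.origin + lo * vs
    return ImageStack(sub.copy(), VoxelGrid(tuple(sub.shape), stack.grid.voxel_size),
                      stack.channel_role, origin)


# ---------------------------------------------------------------------------
# pipette-tip pipeline
# ---------------------------------------------------------------------------

def normalize_substack(stack: ImageStack, p: float = 98.0) -> ImageStack:
    """Subtract the minimum and rescale so the 5th percentile maps to 0 and
    the p-th percentile maps to 1, clipping to [0, 1].

    A degenerate stack whose 5th and p-th percentiles coincide maps to all
    zeros with a warning rather than an exception.
    """
    data = stack.data - stack.data.min()
    lo, hi = np.percentile(data, [5.0, p])
    if hi <= lo:
        warnings.warn("degenerate substack: 5th and upper percentile coincide; "
                      "returning all zeros", RuntimeWarning, stacklevel=2)
        return stack.with_data(np.zeros_like(data))
    return stack.with_data(np.clip((data - lo) / (hi - lo), 0.0, 1.0))


def smooth_boxcar(stack: ImageStack) -> ImageStack:
    """3x3x1 boxcar: in-plane 3x3 mean per z-plane, edges replicated."""
    return stack.with_data(ndimage.uniform_filter(stack.data, size=(3, 3, 1), mode="nearest"))


def max_projections(stack: ImageStack) -> dict[str, np.ndarray]:
    """Maximum intensity projections along each axis.

    Returns ``{"xy": A[x, y], "xz": A[x, z], "yz": A[y, z]}``.
    """
    d = stack.data
    return {"xy": d.max(axis=2), "xz": d.max(axis=1), "yz": d.max(axis=0)}


def segment_largest(image2d: np.ndarray, threshold_fraction: float = 0.90,
                    min_pixels: int = 10) -> np.ndarray:
    """Largest 8-connected component of ``image >= fraction * max`` with more
    than ``min_pixels`` pixels; empty mask if none qualifies."""
    image2d = np.asarray(image2d, dtype=float)
    peak = image2d.max()
    empty = np.zeros(image2d.shape, dtype=bool)
    if peak <= 0:
        return empty
    labels, n = ndimage.label(image2d >= threshold_fraction * peak, structure=_STRUCT_2D)
    if n == 0:
        return empty
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] <= min_pixels:
        return empty
    return labels == best


def _tip_pixels(mask: np.ndarray, pitch: tuple[float, float], direction: np.ndarray,
                n: int) -> np.ndarray:
    """The ``n`` mask pixels most advanced along an in-plane direction.

    ``pitch`` converts indices to microns so anisotropic voxels project
    correctly; ties are broken toward the second (depth-like) axis then by
    index for determinism.  Returns an (m, 2) index array, m <= n.
    """
    idx = np.argwhere(mask)
    pos = idx * np.asarray(pitch)
    score = pos @ direction
    order = np.lexsort((idx[:, 0], idx[:, 1], score))  # ascending; take the tail
    return idx[order[-n:]]


def locate_tip(substack: ImageStack, params: TipLocParams = TipLocParams(),
               advance_axis=None) -> TipEstimate:
    """Locate the pipette tip in a pipette-dye substack.

    Pipeline: percentile normalization, 3x3x1 boxcar, per-axis MIPs,
    per-MIP thresholding at ``threshold_fraction`` of the MIP max keeping the
    largest object above ``min_object_pixels``, then selection of the
    ``n_tip_pixels`` pixels most advanced along the (projected) advance
    direction in each MIP.  Fusion: z is the deepest tip pixel seen in the
    projections containing z; x is the most anterior tip-pixel x of the x-z
    MIP; y is the mean tip-pixel y of the x-y MIP.  The x-y projection also
    yields a redundant x estimate, logged in ``quality`` with its
    disagreement from the adopted x.
    """
    if advance_axis is None:
        advance_axis = axis_from_angles(DEFAULT_APPROACH_ANGLE, 0.0)
    axis = np.asarray(advance_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    norm = normalize_substack(substack, params.upper_percentile)
    smooth = smooth_boxcar(norm)
    mips = max_projections(smooth)
    dx, dy, dz = substack.grid.voxel_size

    plane_axes = {"xy": (0, 1, (dx, dy)), "xz": (0, 2, (dx, dz)), "yz": (1, 2, (dy, dz))}
    tips: dict[str, np.ndarray] = {}
    for name, (a, b, pitch) in plane_axes.items():
        mask = segment_largest(mips[name], params.threshold_fraction, params.min_object_pixels)
        if not mask.any():
            raise TipNotFoundError(name)
        direction = np.array([axis[a], axis[b]])
        n = np.linalg.norm(direction)
        direction = direction / n if n > 0 else np.array([0.0, 1.0])
        tips[name] = _tip_pixels(mask, pitch, direction, params.n_tip_pixels)

    x_vox = float(tips["xz"][:, 0].max())                      # most anterior (x-z MIP)
    z_vox = float(max(tips["xz"][:, 1].max(), tips["yz"][:, 1].max()))  # deepest
    y_vox = float(tips["xy"][:, 1].mean())                     # averaged (x-y MIP)
    x_redundant = float(tips["xy"][:, 0].mean())

    point = substack.index_to_micron((x_vox, y_vox, z_vox))
    quality = {
        "x_redundant_um": substack.origin.x + x_redundant * dx,
        "x_disagreement_um": abs(x_vox - x_redundant) * dx,
        "n_tip_pixels": {k: int(v.shape[0]) for k, v in tips.items()},
    }
    return TipEstimate(point=point, quality=quality)


# ---------------------------------------------------------------------------
# target-soma pipeline
# ---------------------------------------------------------------------------

def bandpass_3d(stack: ImageStack, band_low: float = 2.0, band_high: float = 20.0) -> ImageStack:
    """3D Gaussian bandpass (difference of Gaussians) highlighting round
    features between the two characteristic sizes, given in lateral pixels.

    Each characteristic size maps to sigma = size / 2; the z sigma is divided
    by the axial/lateral pitch ratio so filtering is isotropic in microns.
    The result may be negative before thresholding.
    """
    if not band_low < band_high:
        raise ValueError("require band_low < band_high")
    dx, _, dz = stack.grid.voxel_size
    aniso = dz / dx

    def blur(size: float) -> np.ndarray:
        s = size / 2.0
        return ndimage.gaussian_filter(stack.data, sigma=(s, s, s / aniso), mode="nearest")

    return stack.with_data(blur(band_low) - blur(band_high))


def locate_target(substack: ImageStack, nominal: Point3D,
                  params: TargetLocParams = TargetLocParams()) -> TargetEstimate:
    """Locate the target soma nearest a nominal (user-supplied) position.

    The cytosolic-label substack is bandpassed, thresholded at
    ``threshold_fraction`` of the filtered max, 26-connected components below
    ``min_object_voxels`` are eliminated, and the surviving component whose
    center of mass is closest (microns) to ``nominal`` is returned.  The
    center of mass is intensity-weighted on the nonnegative-clipped filtered
    image, giving subvoxel accuracy; exact distance ties resolve to the lower
    component label.
    """
    filtered = bandpass_3d(substack, params.band_low, params.band_high)
    peak = filtered.data.max()
    if peak <= 0:
        raise TargetNotFoundError("no positive bandpass response in substack")
    labels, n = ndimage.label(filtered.data >= params.threshold_fraction * peak,
                              structure=_STRUCT_3D)
    if n == 0:
        raise TargetNotFoundError("no suprathreshold component")
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts >= params.min_object_voxels) + 1
    if keep.size == 0:
        raise TargetNotFoundError(
            f"all {n} components smaller than {params.min_object_voxels} voxels")

    weights = np.clip(filtered.data, 0.0, None)
    coms = ndimage.center_of_mass(weights, labels, keep)
    vs = np.asarray(substack.grid.voxel_size)
    points = substack.origin.to_array() + np.asarray(coms) * vs
    dists = np.linalg.norm(points - nominal.to_array(), axis=1)
    best = int(np.argmin(dists))  # argmin returns the first (lowest label) on ties
    return TargetEstimate(
        point=Point3D.from_array(points[best]),
        n_candidates=int(keep.size),
        quality={"distance_to_nominal_um": float(dists[best]),
                 "component_voxels": int(counts[keep[best] - 1]),
                 "threshold_reference": "bandpassed_max"},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_stack(path, channel: int | None = None, channel_role: str = "pipette_dye",
               voxel_size: tuple[float, float, float] | None = None) -> ImageStack:
    """Read a (multi-channel) TIFF z-stack.

    TIFF pages are assumed z-major with in-page axes (y, x); multi-channel
    stacks may be (z, c, y, x) or (c, z, y, x) — ``channel`` selects one.
    Voxel size comes from the TIFF resolution tags and ImageJ ``spacing``
    metadata when present, else from ``voxel_size``, else the reference
    configuration.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        if voxel_size is None:
            voxel_size = _voxel_size_from_tiff(tf)
    if arr.ndim == 4:
        if channel is None:
            raise ValueError("multi-channel stack: a channel index is required")
        # heuristics: the channel axis is the smaller of the two leading axes
        c_axis = 0 if arr.shape[0] <= arr.shape[1] else 1
        arr = np.take(arr, channel, axis=c_axis)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {arr.shape}")
    data = np.transpose(arr, (2, 1, 0))  # (z, y, x) -> (x, y, z)
    grid = VoxelGrid(data.shape, voxel_size or (1.23, 1.23, 2.0))
    return ImageStack(data.astype(float), grid, channel_role)


def _voxel_size_from_tiff(tf) -> tuple[float, float, float] | None:
    try:
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
        dz = None
        if tf.imagej_metadata:
            dz = tf.imagej_metadata.get("spacing")
        if dz:
            return (float(dx), float(dy), float(dz))
    except (KeyError, IndexError, ZeroDivisionError, TypeError):
        pass
    return None


def save_stack(path, stacks: "ImageStack | list[ImageStack]") -> None:
    """Write one or more same-grid channels as a z-major TIFF with voxel-size
    metadata (ImageJ convention)."""
    import tifffile

    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    grid = stacks[0].grid
    arr = np.stack([np.transpose(s.data, (2, 1, 0)) for s in stacks], axis=1)
    if arr.shape[1] == 1:
        arr = arr[:, 0]
    dx, dy, dz = grid.voxel_size
    tifffile.imwrite(
        str(path), arr.astype(np.float32), imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZCYX" if arr.ndim == 4 else "ZYX"},
    )


def write_report_line(path, kind: str, estimate, params) -> None:
    """Append a JSON-lines localization report (timestamp, params, estimate,
    quality metrics)."""
    import datetime

    rec = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "kind": kind,
        "params": asdict(params),
        "estimate_um": [estimate.point.x, estimate.point.y, estimate.point.z],
        "quality": estimate.quality,
    }
    with Path(path).open("a") as fh:
        fh.write(json.dumps(rec) + "\n")
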