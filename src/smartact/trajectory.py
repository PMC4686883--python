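"""Approach-trajectory planning, adaptive correction and execution.

The planned trajectory has three phases: a *retract* step up and away from
the brain surface along the (reversed) pipette axis, a *translate* step in a
horizontal clearance plane onto the approach line — the line parallel to the
pipette axis that intersects the target — and discrete axial *approach*
steps ending at the buffer distance R from the target.

Mid-approach, freshly localized tip and target positions yield an
``AdaptiveCorrection``: the lateral component of the tip offset is
compensated (the axial component is reported but not compensated), and the
remaining path is translated by the measured target displacement.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .geometry import PipetteGeometry, Point3D, decompose_separation

__all__ = [
    "ApproachParams",
    "ApproachPlan",
    "AdaptiveCorrection",
    "NoIntersectionError",
    "AdaptationError",
    "plan_trajectory",
    "compute_correction",
    "adapt_trajectory",
    "Manipulator",
    "ExecutionLog",
    "execute_plan",
]

_AXIS_Z_TOL = 1e-9


class NoIntersectionError(ValueError):
    """The pipette axis is parallel to the pia plane."""


class AdaptationError(RuntimeError):
    """The corrected termination would sit above the pia."""


@dataclass(frozen=True)
class ApproachParams:
    """Buffer distance R (microns), axial step size, retraction clearance.

    The reference protocol uses 2-4 micron steps and a 10-12 micron buffer
    distance; retraction clearance is the height above the pia reached before
    lateral translation.
    """

    buffer_distance: float = 12.0
    step_size: float = 3.0
    retraction_clearance: float = 50.0

    def __post_init__(self) -> None:
        if self.buffer_distance <= 0:
            raise ValueError("buffer_distance must be positive")
        if not 0 < self.step_size <= self.buffer_distance:
            raise ValueError("require 0 < step_size <= buffer_distance")
        if self.retraction_clearance < 0:
            raise ValueError("retraction_clearance must be nonnegative")


@dataclass
class ApproachPlan:
    """Ordered manipulator waypoints with per-waypoint phase labels."""

    waypoints: list[Point3D]
    phases: list[str]  # one of "retract" | "translate" | "adapt" | "approach"
    entry_point: Point3D
    termination: Point3D
    target: Point3D
    axis: np.ndarray
    pia_z: float
    params: ApproachParams

    def approach_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.phases) if p == "approach"]

    def to_dict(self) -> dict:
        return {
            "waypoints_um": [[w.x, w.y, w.z] for w in self.waypoints],
            "phases": list(self.phases),
            "entry_point_um": [self.entry_point.x, self.entry_point.y, self.entry_point.z],
            "termination_um": [self.termination.x, self.termination.y, self.termination.z],
            "target_um": [self.target.x, self.target.y, self.target.z],
            "axis": list(map(float, self.axis)),
            "pia_z_um": self.pia_z,
            "params": {"buffer_distance": self.params.buffer_distance,
                       "step_size": self.params.step_size,
                       "retraction_clearance": self.params.retraction_clearance},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ApproachPlan":
        p = d["params"]
        return cls(
            waypoints=[Point3D(*w) for w in d["waypoints_um"]],
            phases=list(d["phases"]),
            entry_point=Point3D(*d["entry_point_um"]),
            termination=Point3D(*d["termination_um"]),
            target=Point3D(*d["target_um"]),
            axis=np.asarray(d["axis"], dtype=float),
            pia_z=float(d["pia_z_um"]),
            params=ApproachParams(**p),
        )

    @classmethod
    def load(cls, path) -> "ApproachPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _line_point_at_z(target: np.ndarray, axis: np.ndarray, z: float) -> np.ndarray:
    """Point on the approach line {target - t*axis} at the given depth z."""
    t = (target[2] - z) / axis[2]
    return target - t * axis


def _axial_steps(start: np.ndarray, end: np.ndarray, step_size: float) -> list[np.ndarray]:
    """Equal sub-steps of at most ``step_size`` from start to end (end exact)."""
    dist = float(np.linalg.norm(end - start))
    if dist <= 1e-12:
        return []
    n = max(1, math.ceil(dist / step_size - 1e-9))
    return [start + (end - start) * (k / n) for k in range(1, n + 1)]


def plan_trajectory(tip: Point3D, target: Point3D, pia_z: float,
                    geom: PipetteGeometry, params: ApproachParams) -> ApproachPlan:
    """Plan the naive approach from the current tip position to the buffer
    point ``target - R * axis``.

    The tip must start above the pia (z < pia_z) and the target below it.
    All motion below the pia is purely axial.  If the buffer point would sit
    above the pia (target shallower than R), the termination is clamped to
    the entry point with a warning.
    """
    axis = np.asarray(geom.axis, dtype=float)
    if abs(axis[2]) < _AXIS_Z_TOL:
        raise NoIntersectionError("pipette axis is parallel to the pia plane")
    if not tip.z < pia_z:
        raise ValueError(f"tip (z={tip.z}) must start above the pia (z={pia_z})")
    if not target.z > pia_z:
        raise ValueError(f"target (z={target.z}) must lie below the pia (z={pia_z})")

    tgt = target.to_array()
    entry = _line_point_at_z(tgt, axis, pia_z)
    termination = tgt - params.buffer_distance * axis
    if termination[2] < pia_z:
        warnings.warn("target is shallower than the buffer distance below the pia; "
                      "clamping termination to the entry point", RuntimeWarning,
                      stacklevel=2)
        termination = entry.copy()

    clearance_z = pia_z - params.retraction_clearance
    waypoints: list[Point3D] = []
    phases: list[str] = []

    # retract up/back along -axis to the clearance plane (skip if already above)
    pos = tip.to_array()
    if pos[2] > clearance_z:
        s = (pos[2] - clearance_z) / axis[2]
        pos = pos - s * axis
        waypoints.append(Point3D.from_array(pos))
        phases.append("retract")

    # translate horizontally onto the approach line
    start = _line_point_at_z(tgt, axis, pos[2])
    if np.linalg.norm(start - pos) > 1e-12:
        waypoints.append(Point3D.from_array(start))
        phases.append("translate")

    for w in _axial_steps(start, termination, params.step_size):
        waypoints.append(Point3D.from_array(w))
        phases.append("approach")

    return ApproachPlan(
        waypoints=waypoints, phases=phases,
        entry_point=Point3D.from_array(entry),
        termination=Point3D.from_array(termination),
        target=target, axis=axis, pia_z=float(pia_z), params=params,
    )


@dataclass(frozen=True)
class AdaptiveCorrection:
    """Measured tip offset (lateral part to be compensated) and target
    displacement (applied as a whole-path translation)."""

    tip_offset: np.ndarray
    tip_lateral_offset: np.ndarray
    tip_axial_offset: float
    target_displacement: np.ndarray


def compute_correction(expected_tip: Point3D, measured_tip: Point3D,
                       original_target: Point3D, measured_target: Point3D,
                       axis) -> AdaptiveCorrection:
    """Decompose the tip offset about the axis and measure target motion.

    Only the lateral tip component is compensated downstream; the axial
    component is reported for audit (the termination criterion remains
    distance-R-from-target along the axis).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    tip_offset = measured_tip - expected_tip
    axial = float(tip_offset @ axis)
    lateral = tip_offset - axial * axis
    return AdaptiveCorrection(
        tip_offset=tip_offset,
        tip_lateral_offset=lateral,
        tip_axial_offset=axial,
        target_displacement=measured_target - original_target,
    )


def adapt_trajectory(plan: ApproachPlan, corr: AdaptiveCorrection,
                     params: ApproachParams | None = None,
                     resume_index: int = 0) -> ApproachPlan:
    """Correct the remaining path for pipette deflection and target motion.

    Waypoints before ``resume_index`` (already executed) are kept.  The
    physical tip is re-centered on the planned line by commanding the
    negative of the measured lateral tip offset, then the remaining path —
    including the termination — is translated by the target displacement and
    re-discretized into axial steps of at most ``step_size``.

    An exactly-zero correction returns the plan unchanged.  A corrected
    termination above the pia raises :class:`AdaptationError`.
    """
    params = params or plan.params
    shift = -corr.tip_lateral_offset + corr.target_displacement
    if not np.any(shift):
        return plan

    new_target = plan.target + corr.target_displacement
    new_term = plan.termination + shift
    if new_term.z < plan.pia_z:
        raise AdaptationError(
            f"corrected termination z={new_term.z:.2f} um lies above the pia "
            f"(z={plan.pia_z:.2f} um); refusing to adapt")

    kept_w = plan.waypoints[:resume_index]
    kept_p = plan.phases[:resume_index]
    if resume_index == 0:
        raise ValueError("resume_index must point past the waypoint where the "
                         "adaptive substack was acquired")
    current = plan.waypoints[resume_index - 1].to_array()

    corrected = current + shift
    waypoints = kept_w + [Point3D.from_array(corrected)]
    phases = kept_p + ["adapt"]
    for w in _axial_steps(corrected, new_term.to_array(), params.step_size):
        waypoints.append(Point3D.from_array(w))
        phases.append("approach")

    return ApproachPlan(
        waypoints=waypoints, phases=phases,
        entry_point=plan.entry_point + corr.target_displacement,
        termination=new_term, target=new_target,
        axis=plan.axis, pia_z=plan.pia_z, params=params,
    )


class Manipulator(Protocol):
    """Command sink for absolute 3-axis micron moves.

    ``move_to`` returns the acknowledged (physical) position; raising aborts
    execution with a partial log.  A hardware adapter would implement this
    protocol; the phantom module ships a simulated one with deflection.
    """

    def move_to(self, point: Point3D) -> Point3D: ...


@dataclass
class ExecutionLog:
    commanded: list[Point3D] = field(default_factory=list)
    acknowledged: list[Point3D] = field(default_factory=list)
    phases: list[str] = field(default_factory=list)
    aborted: bool = False
    error: str | None = None


def execute_plan(plan: ApproachPlan, manipulator: Manipulator,
                 start_index: int = 0, stop_index: int | None = None) -> ExecutionLog:
    """Issue one absolute move per waypoint, in order, recording commanded
    vs acknowledged positions; a manipulator rejection aborts with the
    partial log."""
    log = ExecutionLog()
    stop = len(plan.waypoints) if stop_index is None else stop_index
    for w, phase in zip(plan.waypoints[start_index:stop], plan.phases[start_index:stop]):
        try:
            ack = manipulator.move_to(w)
        except Exception as exc:  # noqa: BLE001 - surface hardware rejections
            log.aborted = True
            log.error = str(exc)
            return log
        log.commanded.append(w)
        log.acknowledged.append(ack)
        log.phases.append(phase)
    return log


def waypoint_lateral_errors(plan: ApproachPlan) -> list[float]:
    """r_lateral of every approach-phase waypoint to the target line (a
    planning invariant: all should be ~0)."""
    return [decompose_separation(plan.waypoints[i], plan.target, plan.axis).r_lateral
            for i in plan.approach_indices()]
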