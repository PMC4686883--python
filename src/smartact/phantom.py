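"""Synthetic two-channel 3D stacks with ground truth, and a closed-loop
approach simulator.

The phantom emulates the in vivo two-photon scene: a bright tapered pipette
(dye-filled lumen, rendered saturated the way a dye-loaded pipette images)
in one channel, and spherical somata (radius about 5 microns) over diffuse
background in a cytosolic-label channel, with optional Poisson shot noise
and Gaussian read noise.  Ground truth (tip, cell centers, applied
deflection/displacement) accompanies every rendered stack.

``simulate_approach`` closes the loop: physics (deflection/drift at the
current insertion depth) -> imaging (render) -> analysis (localize) ->
control (plan/adapt/step), recording the final tip-target separation for
naive and adaptive strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (DEFAULT_APPROACH_ANGLE, DEFAULT_VOXEL_SIZE, PipetteGeometry,
                       Point3D, SeparationMetrics, VoxelGrid, axis_from_angles,
                       decompose_separation)
from .localization import (ImageStack, RoiSpec, TargetLocParams, TargetNotFoundError,
                           TipLocParams, TipNotFoundError, extract_roi, locate_target,
                           locate_tip)
from .trajectory import (AdaptationError, ApproachParams, adapt_trajectory,
                         compute_correction, plan_trajectory)

__all__ = [
    "CellSpec",
    "PhantomSpec",
    "PhantomTruth",
    "DeflectionModel",
    "SimulatedManipulator",
    "render_stack",
    "simulate_approach",
    "run_batch",
    "default_scenario",
    "dense_cells",
    "sample_deflection_model",
    "photons_for_snr",
    "ApproachRecord",
]


@dataclass(frozen=True)
class CellSpec:
    """A fluorescent soma: center (microns), radius and peak intensity above
    background."""

    center: Point3D
    radius: float = 5.0
    peak: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cell radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description for a rendered two-channel stack.

    Defaults follow the reference imaging configuration: 256 x 256 x 150
    stacks at (1.23, 1.23, 2) micron voxels, pipette 31 degrees below
    horizontal.  ``saturation_gain`` models detector saturation of the
    bright dye-filled pipette: a voxel covering >= 1/gain of the cone cross
    section renders at full intensity, which is what gives real pipette
    images their crisp apparent tip.
    """

    grid: VoxelGrid = VoxelGrid((256, 256, 150), DEFAULT_VOXEL_SIZE)
    tip_truth: Point3D = Point3D(47.0, 157.0, 8.0)
    approach_angle: float = DEFAULT_APPROACH_ANGLE
    azimuth: float = 0.0
    cone_half_angle: float = 3.0
    tip_radius: float = 3.0
    cone_length: float = 150.0
    pipette_peak: float = 1.0
    saturation_gain: float = 6.0
    hollow: bool = False
    wall_thickness: float = 1.0
    cells: tuple[CellSpec, ...] = (CellSpec(Point3D(250.0, 157.0, 130.0)),)
    background: float = 0.25
    cell_edge_sigma: float = 0.4
    texture_amplitude: float = 0.0
    noise_model: str = "none"  # none | poisson | gaussian | poisson_gaussian
    photons: float = 200.0  # photon count at unit intensity (Poisson scale)
    read_noise: float = 0.0  # additive Gaussian sigma, intensity units
    pia_z: float = 20.0
    seed: int = 0

    @property
    def axis(self) -> np.ndarray:
        return axis_from_angles(self.approach_angle, self.azimuth)

    def snr(self) -> float:
        """Peak signal above background over the background noise sigma."""
        var = 0.0
        if self.noise_model in ("poisson", "poisson_gaussian"):
            var += self.background / self.photons
        if self.noise_model in ("gaussian", "poisson_gaussian"):
            var += self.read_noise ** 2
        if var == 0.0:
            return math.inf
        peak = max(self.pipette_peak, max((c.peak for c in self.cells), default=0.0))
        return peak / math.sqrt(var)


def photons_for_snr(snr: float, background: float = 0.25, peak: float = 1.0) -> float:
    """Poisson photon scale giving the requested peak-over-background-sigma
    SNR (pure shot noise)."""
    return snr ** 2 * background / peak ** 2


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for a rendered stack (testing oracle)."""

    tip: Point3D
    cells: tuple[Point3D, ...]
    tip_shift: tuple[float, float, float]
    cell_shift: tuple[float, float, float]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _voxel_centers(grid: VoxelGrid, lo: np.ndarray, hi: np.ndarray):
    """Open micron-coordinate meshgrid for voxel index box [lo, hi)."""
    vs = grid.voxel_size
    coords = [np.arange(lo[a], hi[a]) * vs[a] for a in range(3)]
    return np.meshgrid(*coords, indexing="ij", sparse=True)


def _bounding_box(grid: VoxelGrid, lo_um: np.ndarray, hi_um: np.ndarray, pad: float):
    vs = np.asarray(grid.voxel_size)
    lo = np.floor((lo_um - pad) / vs).astype(int)
    hi = np.ceil((hi_um + pad) / vs).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(grid.shape))
    return lo, hi


def _render_cone(data: np.ndarray, spec: PhantomSpec, tip: np.ndarray) -> None:
    """Add the pipette cone (apex at ``tip``, opening backwards along -axis)
    with 2x supersampled coverage and saturation."""
    axis = spec.axis
    tail = tip - spec.cone_length * axis
    r_max = spec.tip_radius + spec.cone_length * math.tan(math.radians(spec.cone_half_angle))
    lo_um = np.minimum(tip, tail) - r_max
    hi_um = np.maximum(tip, tail) + r_max
    lo, hi = _bounding_box(spec.grid, lo_um, hi_um, pad=2.0)
    if np.any(hi <= lo):
        return
    xs, ys, zs = _voxel_centers(spec.grid, lo, hi)

    vs = np.asarray(spec.grid.voxel_size)
    tan_a = math.tan(math.radians(spec.cone_half_angle))
    cover = np.zeros(tuple(h - l for l, h in zip(lo, hi)))
    offsets = (-0.25, 0.25)  # 2x2x2 supersampling within each voxel
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                ux = xs + ox * vs[0] - tip[0]
                uy = ys + oy * vs[1] - tip[1]
                uz = zs + oz * vs[2] - tip[2]
                s = -(ux * axis[0] + uy * axis[1] + uz * axis[2])
                rho2 = (ux + s * axis[0]) ** 2 + (uy + s * axis[1]) ** 2 \
                    + (uz + s * axis[2]) ** 2
                r_s = spec.tip_radius + s * tan_a
                inside = (s >= 0) & (s <= spec.cone_length) & (rho2 <= r_s ** 2)
                if spec.hollow:
                    inner = np.maximum(r_s - spec.wall_thickness, 0.0)
                    inside &= rho2 >= inner ** 2
                cover += inside
    cover /= len(offsets) ** 3
    intensity = spec.pipette_peak * np.clip(spec.saturation_gain * cover, 0.0, 1.0)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += intensity


def _render_cell(data: np.ndarray, spec: PhantomSpec, cell: CellSpec,
                 center: np.ndarray) -> None:
    from scipy.special import erfc

    pad = cell.radius + 4 * spec.cell_edge_sigma
    lo, hi = _bounding_box(spec.grid, center - pad, center + pad, pad=0.0)
    if np.any(hi <= lo):
        return
    xs, ys, zs = _voxel_centers(spec.grid, lo, hi)
    rho = np.sqrt((xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2)
    profile = 0.5 * erfc((rho - cell.radius) / (math.sqrt(2.0) * spec.cell_edge_sigma))
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += cell.peak * profile


def _apply_noise(data: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return data
    out = data
    if spec.noise_model in ("poisson", "poisson_gaussian"):
        out = rng.poisson(np.clip(out, 0.0, None) * spec.photons) / spec.photons
    if spec.noise_model in ("gaussian", "poisson_gaussian"):
        out = out + rng.normal(0.0, spec.read_noise, size=out.shape)
    return out


def render_stack(spec: PhantomSpec, tip_shift=(0.0, 0.0, 0.0),
                 cell_shift=(0.0, 0.0, 0.0),
                 rng: np.random.Generator | None = None,
                 ) -> tuple[ImageStack, ImageStack, PhantomTruth]:
    """Render the pipette-dye and cytosolic-label channels plus ground truth.

    ``tip_shift`` displaces the rendered tip from ``spec.tip_truth`` (pipette
    deflection); ``cell_shift`` displaces every soma (tissue displacement).
    A fixed ``spec.seed`` (with no explicit ``rng``) gives bit-identical
    stacks.  Cells whose sphere leaves the grid are clipped with a warning.
    """
    import warnings

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    shape = tuple(spec.grid.shape)
    extent = np.asarray(spec.grid.shape) * np.asarray(spec.grid.voxel_size)

    pip = np.full(shape, spec.background, dtype=float)
    tip = spec.tip_truth.to_array() + np.asarray(tip_shift, dtype=float)
    _render_cone(pip, spec, tip)

    cells = np.full(shape, spec.background, dtype=float)
    if spec.texture_amplitude > 0:
        from scipy import ndimage

        field_ = rng.normal(size=shape)
        field_ = ndimage.gaussian_filter(field_, sigma=(2.0, 2.0, 1.2), mode="nearest")
        field_ /= max(field_.std(), 1e-12)
        cells += spec.texture_amplitude * np.abs(field_)
    true_cells = []
    for cell in spec.cells:
        c = cell.center.to_array() + np.asarray(cell_shift, dtype=float)
        if np.any(c - cell.radius < 0) or np.any(c + cell.radius > extent):
            warnings.warn(f"cell at {c} extends outside the grid; clipping",
                          RuntimeWarning, stacklevel=2)
        _render_cell(cells, spec, cell, c)
        true_cells.append(Point3D.from_array(c))

    pip = _apply_noise(pip, spec, rng)
    cells = _apply_noise(cells, spec, rng)
    truth = PhantomTruth(tip=Point3D.from_array(tip), cells=tuple(true_cells),
                         tip_shift=tuple(map(float, tip_shift)),
                         cell_shift=tuple(map(float, cell_shift)))
    return (ImageStack(pip, spec.grid, "pipette_dye"),
            ImageStack(cells, spec.grid, "cytosolic_label"),
            truth)


# ---------------------------------------------------------------------------
# deflection / displacement physics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeflectionModel:
    """Pipette deflection and target drift as a function of insertion depth.

    ``profile="constant"`` applies the full vectors as a rigid offset as soon
    as the pipette is inside the cortex; ``profile="linear"`` ramps them
    linearly up to ``reference_depth``.  Zero insertion always means zero
    deflection and zero drift.
    """

    lateral_deflection: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    profile: str = "constant"
    reference_depth: float = 100.0

    def _scale(self, depth: float) -> float:
        if depth <= 0:
            return 0.0
        if self.profile == "constant":
            return 1.0
        if self.profile == "linear":
            return min(depth / self.reference_depth, 1.0)
        raise ValueError(f"unknown deflection profile {self.profile!r}")

    def deflection_at(self, depth: float) -> np.ndarray:
        return self._scale(depth) * np.asarray(self.lateral_deflection, dtype=float)

    def drift_at(self, depth: float) -> np.ndarray:
        return self._scale(depth) * np.asarray(self.target_drift, dtype=float)


def sample_deflection_model(rng: np.random.Generator, axis,
                            deflection_sd: float = 5.0, drift_sd: float = 4.0,
                            profile: str = "constant") -> DeflectionModel:
    """Draw a random deflection model: the tip deflection is strictly lateral
    (two perpendicular components ~ N(0, deflection_sd)); the target drift is
    an isotropic 3D normal vector."""
    axis = np.asarray(axis, dtype=float)
    e1 = np.cross(axis, [0.0, 0.0, 1.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    lateral = rng.normal(0.0, deflection_sd) * e1 + rng.normal(0.0, deflection_sd) * e2
    drift = rng.normal(0.0, drift_sd, size=3)
    return DeflectionModel(lateral_deflection=tuple(lateral),
                           target_drift=tuple(drift), profile=profile)


class SimulatedManipulator:
    """Manipulator command sink whose acknowledged positions include the
    deflection model evaluated at the commanded insertion depth."""

    def __init__(self, model: DeflectionModel, pia_z: float):
        self.model = model
        self.pia_z = pia_z

    def move_to(self, point: Point3D) -> Point3D:
        depth = max(0.0, point.z - self.pia_z)
        return point + self.model.deflection_at(depth)


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

@dataclass
class ApproachRecord:
    """Outcome of one simulated approach."""

    strategy: str
    success: bool
    metrics: SeparationMetrics | None
    surface_distance: float | None  # r_total minus the target soma radius
    adaptive_step_r_lateral: float | None
    snr: float
    n_commands: int
    seed: int
    failure: str | None = None
    final_tip: Point3D | None = None
    final_target: Point3D | None = None
    commanded: list[Point3D] = field(default_factory=list)
    physical: list[Point3D] = field(default_factory=list)
    localization: dict = field(default_factory=dict)


def _localize_pair(pip: ImageStack, cells: ImageStack, tip_nominal: Point3D,
                   target_nominal: Point3D, axis, tip_roi_half, target_roi_half,
                   tip_params: TipLocParams, target_params: TargetLocParams):
    tip_roi = extract_roi(pip, RoiSpec(tip_nominal, tip_roi_half))
    tip_est = locate_tip(tip_roi, tip_params, advance_axis=axis)
    target_roi = extract_roi(cells, RoiSpec(target_nominal, target_roi_half))
    target_est = locate_target(target_roi, target_nominal, target_params)
    return tip_est.point, target_est.point


def simulate_approach(spec: PhantomSpec, deflection: DeflectionModel,
                      strategy: str = "adaptive",
                      params: ApproachParams = ApproachParams(),
                      seed: int = 0,
                      localization: str = "image",
                      adaptive_fraction: float = 0.5,
                      tip_roi_half=(15.0, 15.0, 15.0),
                      target_roi_half=(14.0, 14.0, 16.0),
                      nominal_jitter: float = 1.0,
                      tip_params: TipLocParams = TipLocParams(),
                      target_params: TargetLocParams = TargetLocParams(),
                      ) -> ApproachRecord:
    """Run one naive or adaptive approach against the deflection model.

    The loop alternates physics (deflection and drift at the commanded
    insertion depth), imaging (render), analysis (tip and target
    localization inside ROIs around the expected positions) and control
    (plan, then one mid-course adaptation at ``adaptive_fraction`` of the
    intracortical depth for the adaptive strategy).  ``localization="truth"``
    bypasses image analysis and feeds ground truth to the controller.

    Localization failures are surfaced in the record (``success=False``,
    ``failure`` set); the approach then continues uncorrected so a final
    position is still reported.
    """
    if strategy not in ("naive", "adaptive"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    axis_true = spec.axis
    target_cell = spec.cells[0]
    record = ApproachRecord(strategy=strategy, success=True, metrics=None,
                            surface_distance=None, adaptive_step_r_lateral=None,
                            snr=spec.snr(), n_commands=0, seed=seed)

    # --- initial imaging + localization --------------------------------
    pip, cells, truth = render_stack(spec, rng=rng)
    tip_nominal = truth.tip + rng.normal(0.0, nominal_jitter, size=3)
    target_nominal = truth.cells[0] + rng.normal(0.0, nominal_jitter, size=3)
    if localization == "truth":
        tip_est, target_est = truth.tip, truth.cells[0]
    else:
        try:
            tip_est, target_est = _localize_pair(
                pip, cells, tip_nominal, target_nominal, axis_true,
                tip_roi_half, target_roi_half, tip_params, target_params)
        except (TipNotFoundError, TargetNotFoundError) as exc:
            record.success = False
            record.failure = f"initial localization failed: {exc}"
            return record
    record.localization["initial_tip_error_um"] = float(
        np.linalg.norm(tip_est - truth.tip))
    record.localization["initial_target_error_um"] = float(
        np.linalg.norm(target_est - truth.cells[0]))

    geom = PipetteGeometry(tip_est, spec.approach_angle, spec.azimuth)
    plan = plan_trajectory(tip_est, target_est, spec.pia_z, geom, params)
    final_depth = plan.termination.z - spec.pia_z

    # --- execution -----------------------------------------------------
    adapted = strategy == "naive"
    i = 0
    while i < len(plan.waypoints):
        w = plan.waypoints[i]
        depth = max(0.0, w.z - spec.pia_z)
        physical = w + deflection.deflection_at(depth)
        record.commanded.append(w)
        record.physical.append(physical)
        record.n_commands += 1

        if (not adapted and plan.phases[i] == "approach"
                and depth >= adaptive_fraction * final_depth):
            adapted = True
            drift_now = deflection.drift_at(depth)
            true_target_now = truth.cells[0] + drift_now
            if localization == "truth":
                tip_meas, target_meas = physical, true_target_now
            else:
                mid_pip, mid_cells, _ = render_stack(
                    spec, tip_shift=physical - spec.tip_truth,
                    cell_shift=drift_now, rng=rng)
                try:
                    tip_meas, target_meas = _localize_pair(
                        mid_pip, mid_cells, w, target_est, axis_true,
                        tip_roi_half, target_roi_half, tip_params, target_params)
                except (TipNotFoundError, TargetNotFoundError) as exc:
                    record.success = False
                    record.failure = f"adaptive-step localization failed: {exc}"
                    i += 1
                    continue
            record.adaptive_step_r_lateral = decompose_separation(
                tip_meas, target_meas, axis_true).r_lateral
            record.localization["adaptive_tip_error_um"] = float(
                np.linalg.norm(tip_meas - physical))
            record.localization["adaptive_target_error_um"] = float(
                np.linalg.norm(target_meas - true_target_now))
            corr = compute_correction(w, tip_meas, target_est, target_meas, axis_true)
            try:
                plan = adapt_trajectory(plan, corr, params, resume_index=i + 1)
            except AdaptationError as exc:
                record.success = False
                record.failure = str(exc)
        i += 1

    # --- final physical separation --------------------------------------
    final_cmd = plan.waypoints[-1] if plan.waypoints else tip_est
    depth_f = max(0.0, final_cmd.z - spec.pia_z)
    final_tip = final_cmd + deflection.deflection_at(depth_f)
    final_target = truth.cells[0] + deflection.drift_at(depth_f)
    record.final_tip = final_tip
    record.final_target = final_target
    record.metrics = decompose_separation(final_tip, final_target, axis_true)
    record.surface_distance = record.metrics.r_total - target_cell.radius
    return record


def default_scenario(seed: int = 0, noise_snr: float | None = None,
                     n_distractors: int = 4, dense: bool = False) -> PhantomSpec:
    """The reference simulated scene: full 256 x 256 x 150 stack, pia at
    z = 20 um, target soma 110 um below the pia, pipette starting above the
    surface on (near) the approach line.

    ``noise_snr`` switches on Poisson noise at the requested
    peak-over-background-sigma SNR.  ``dense`` emulates densely labeled
    cortex (many distractor somata plus neurite-like texture).
    """
    rng = np.random.default_rng(seed)
    grid = VoxelGrid((256, 256, 150), DEFAULT_VOXEL_SIZE)
    target = Point3D(250.0, 157.0, 130.0)
    cells = [CellSpec(target, radius=5.0, peak=1.0)]
    if dense:
        cells += dense_cells(rng, grid, n=max(n_distractors, 20), exclude=target,
                             min_separation=16.0)
    else:
        offsets = [(-30.0, 18.0, -12.0), (-45.0, -25.0, 10.0),
                   (25.0, 30.0, 25.0), (-20.0, -40.0, -30.0)]
        for off in offsets[:n_distractors]:
            cells.append(CellSpec(target + np.asarray(off),
                                  radius=float(rng.uniform(4.0, 6.0)),
                                  peak=float(rng.uniform(0.85, 1.0))))
    kwargs = {}
    if noise_snr is not None:
        kwargs = {"noise_model": "poisson",
                  "photons": photons_for_snr(noise_snr)}
    if dense:
        kwargs["texture_amplitude"] = 0.05
    axis = axis_from_angles(DEFAULT_APPROACH_ANGLE, 0.0)
    t = (target.z - 8.0) / axis[2]
    tip = Point3D.from_array(target.to_array() - t * axis + np.array([0.0, 4.0, 0.0]))
    return PhantomSpec(grid=grid, tip_truth=tip, cells=tuple(cells),
                       pia_z=20.0, seed=seed, **kwargs)


def dense_cells(rng: np.random.Generator, grid: VoxelGrid, n: int,
                exclude: Point3D, min_separation: float = 16.0,
                radius_range=(4.0, 6.0), peak_range=(0.9, 1.0)) -> list[CellSpec]:
    """Distractor somata with a minimum mutual (and target) separation,
    emulating densely labeled layer-2/3 cortex."""
    extent = np.asarray(grid.shape) * np.asarray(grid.voxel_size)
    placed = [exclude.to_array()]
    out: list[CellSpec] = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        c = rng.uniform([10.0, 10.0, 40.0], extent - 10.0)
        if min(np.linalg.norm(c - p) for p in placed) < min_separation:
            continue
        placed.append(c)
        out.append(CellSpec(Point3D.from_array(c),
                            radius=float(rng.uniform(*radius_range)),
                            peak=float(rng.uniform(*peak_range))))
    return out


def run_batch(n: int, strategy: str, seed: int,
              scenario=default_scenario, noise_snr: float | None = None,
              deflection_sd: float = 5.0, drift_sd: float = 4.0,
              params: ApproachParams = ApproachParams(),
              localization: str = "image",
              **sim_kwargs) -> list[ApproachRecord]:
    """Seeded batch of approaches: one scenario, deflection model and
    approach seed per repetition, all derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    records = []
    for k, child in enumerate(ss.spawn(n)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = scenario(seed=sub_seed, noise_snr=noise_snr)
        rng = np.random.default_rng(sub_seed + 1)
        model = sample_deflection_model(rng, spec.axis, deflection_sd, drift_sd)
        records.append(simulate_approach(spec, model, strategy=strategy,
                                         params=params, seed=sub_seed,
                                         localization=localization, **sim_kwargs))
    return records
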