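# Methods

## Problem and model

Targeted single-cell experiments in vivo (whole-cell recording, cell-attached
recording, single-cell electroporation) require bringing a glass micropipette
tip within a few microns of a chosen neuron, hundreds of microns deep in
cortex, under two-photon (2-P) guidance. Advancing the pipette blindly along
its nominal axis fails at the cell-body scale for two reasons: the pipette
bends laterally as it penetrates tissue, and the tissue (with the target
soma) is displaced by the advancing pipette. This package implements the
image-guided strategy that fixes both: localize the tip and the target in a
freshly acquired 3-D stack, plan a straight approach along the pipette axis,
pause mid-course to re-image and re-localize, and correct the remaining
trajectory for the measured lateral tip offset and target displacement.

All computation happens in one right-handed micron-space frame: `x`
anterior (the horizontal direction of pipette advance), `z` depth, 0-based
voxel indices mapping to microns as `index * voxel_size`. The reference
imaging configuration is 256 × 256 × ~150 stacks at (1.23, 1.23, 2) µm
voxels with the pipette 31° below horizontal. The pipette axis is the unit
vector `a = (cos θ cos φ, cos θ sin φ, sin θ)` for approach angle θ and
azimuth φ. A tip-to-target displacement `d` decomposes as

    r_axial   = d · a                    (signed; reporting uses |r_axial|)
    r_lateral = ‖d − r_axial a‖          (closest distance target-to-axis)
    r_total   = ‖d‖,  r_total² = r_lateral² + r_axial²

`r_axial` is the distance to the target's perpendicular foot point on the
axis line: the natural decomposition "measured from the line parallel to the
pipette axis". Sign convention: positive when the target lies ahead of the
tip.

## Tip localization

Inside a region of interest around the expected tip (pipette-dye channel):

1. subtract the minimum, then rescale so the 5th percentile maps to 0 and
   the p-th (default 98th) to 1, clipping to [0, 1]. The high anchor rides
   on the bright pipette, so background noise stays small after
   normalization. A degenerate ROI (5th and p-th percentile equal — e.g. no
   pipette present) maps to zeros with a warning and ends in a
   tip-not-found error rather than a fabricated estimate;
2. smooth with a 3 × 3 × 1 boxcar (in-plane mean, edges replicated);
3. maximum-intensity projections along each axis (x-y, x-z, y-z);
4. per projection: threshold at 90 % of that projection's max, keep the
   largest 8-connected object with more than 10 pixels;
5. per projection: select the 10 object pixels most advanced along the
   in-plane projection of the advance axis (anisotropy-corrected, ties
   broken toward depth then by index for determinism);
6. fuse: `z` = deepest tip pixel of the projections containing z, `x` =
   most anterior tip-pixel x of the x-z projection, `y` = mean tip-pixel y
   of the x-y projection. The x-y projection's redundant x estimate and its
   disagreement with the adopted x are logged as a quality metric.

## Target localization

Inside an ROI around the nominal (user-supplied) soma position
(cytosolic-label channel): a 3-D Gaussian bandpass — difference of
Gaussians with characteristic sizes 2 and 20 pixels, σ = size/2 per lateral
axis and the z-σ divided by the axial/lateral pitch ratio so filtering is
isotropic in microns — highlights soma-sized blobs; threshold at 90 % of
the *filtered* max (choice logged in the output metadata); drop
26-connected components under 10 voxels; among survivors return the
intensity-weighted center of mass (on the nonnegative-clipped filtered
image) of the component nearest the nominal point, exact ties to the lower
label.

Because the band limits are pixel-denominated, detectable soma size is tied
to the sampling: at the reference pitch the 90 %-core of a 3 µm-radius soma
holds only 3–4 voxels and is (correctly) removed by the 10-voxel cull — the
pipeline raises a target-not-found error. Resolving radii down to 3 µm
requires sampling matched to the structure (≈0.8 µm pixels), which the test
suite exercises explicitly.

## Trajectory planning and adaptation

Planning inputs: measured tip, measured target, entry plane depth `pia_z`,
axis geometry, and approach parameters — buffer distance R (default 12 µm,
protocol range 10–12), axial step size (default 3 µm, range 2–4) and
retraction clearance (default 50 µm above the pia). The plan is retract
(along −axis to the clearance plane, avoiding dragging the tip through
tissue), translate (horizontally onto the approach line — the line parallel
to the axis through the target), then equal axial steps (each ≤ step size)
ending exactly at `target − R·axis`. Planning refuses a horizontal axis (no
entry intersection) and clamps the termination to the entry point, with a
warning, when the target is shallower than R.

At the adaptive pause (default: the first approach waypoint at ≥ 50 % of
the intracortical depth; the expected tip is the commanded waypoint, which
is always available), a fresh stack gives measured tip and target. The
correction compensates only the *lateral* component of the tip offset — the
axial component is reported but not compensated, since termination is
defined by distance R along the axis — then translates the remaining path,
including the termination, by the measured target displacement, and
re-discretizes into ≤ step-size axial steps. An exactly-zero correction
returns the plan unchanged (re-grouping residual sub-steps would otherwise
alter waypoints without changing geometry). A corrected termination above
the pia is refused.

Execution issues one absolute micron-space move per waypoint to a command
sink (`move_to(point) -> acknowledged point`); a hardware adapter would
implement this protocol, and the shipped simulated manipulator acknowledges
commands displaced by the deflection model.

## The phantom: what it emulates, and what it does not

The synthetic scene renders the two channels of the in vivo configuration:

- **Pipette channel** — a dye-filled truncated cone along the axis: tip
  aperture radius 3 µm, half-angle 3°, length 150 µm, supersampled (2× per
  axis) coverage passed through a saturation gain of 6 and clipped. The
  saturation models how a bright dye-filled pipette images: even
  partial-volume voxels at the rim reach full intensity, producing the
  crisp apparent tip real pipettes show. A hollow-wall variant is
  available.
- **Cell channel** — spheres with an erf edge profile (edge σ 0.4 µm,
  sharp enough to keep integrated intensity ∝ radius³ within 5 %), default
  radius 5 µm (a typical mouse pyramidal soma), over a diffuse background
  at 0.25 of the soma peak representing neuropil fluorescence. The dense
  mode adds ≥ 20 distractor somata (minimum separation 16 µm, similar
  sizes and intensities, as in densely labeled layer-2/3 cortex) and a
  smoothed-noise texture standing in for labeled dendritic arborizations.
- **Noise** — Poisson shot noise on photon counts (scale set by
  `photons`, the count at unit intensity) plus optional Gaussian read
  noise. SNR is defined as peak-above-background over background σ;
  `photons_for_snr` inverts that definition for pure shot noise.

Deflection physics: the deflection model applies a strictly lateral tip
offset and a 3-D target drift, either as a rigid offset once the pipette is
inside the cortex (default — consistent with correction removing a
measured, stable offset) or ramped linearly with insertion depth
(configurable; the depth dependence of real deflection is not
characterized, so it is exposed rather than asserted). Batch sampling draws
the two lateral deflection components from N(0, 5 µm) and drift components
from N(0, 4 µm), magnitudes chosen to match reported naive-approach error
contributions (≈10 µm deflection, ≈6 µm displacement at full depth).

What the phantom does *not* model: the optical point-spread function,
depth-dependent scattering and attenuation, brain pulsation, pipette
pressure effects, or tissue mechanics coupling deflection to drift.
Passing tests therefore demonstrate the correctness of the analysis and
control chain under controlled geometry and noise — not in vivo
performance, whose reported values depend on real tissue.

## Closed-loop simulation

`simulate_approach` alternates physics (deflection/drift at the commanded
insertion depth), imaging (full-stack render), analysis (tip and target
localization in ROIs of half-extent 15 µm tip / 14–16 µm target around
expected positions; nominal click positions are truth plus 1 µm Gaussian
jitter, the scale of single-click precision), and control (plan, one
adaptation, steps). The naive strategy skips the adaptation. Localization
failures mark the record unsuccessful and the approach continues
uncorrected — a final position still exists physically and exclusion is a
reporting decision (the distance-based outlier filter, default 40 µm,
flags rather than deletes rows).

With deflections sampled as above and noiseless imaging, 100 seeded runs
per strategy give mean final r_lateral ≈ 7–8 µm (naive) versus ≈ 1.4 µm
(adaptive), a ratio ≈ 0.17–0.19 — the adaptive end-state is far below half
the error measured at the adaptive step, the qualitative signature the
method is built for. Fed ground truth instead of images, adaptation cancels
a rigid deflection exactly (r_lateral ≤ 1e-6 µm).

## Numerical and reporting choices

- Unit-axis checks at 1e-6; geometric identities tested at 1e-9.
- Filters use edge replication; connectivity is 8-connected in 2-D,
  26-connected in 3-D (robust to anisotropic voxels).
- Summaries report mean ± SD (ddof = 1, not SEM; SD is undefined and
  reported as unavailable for N = 1); repeated-localization spread uses the
  MSD about the centroid. Axial distances are reported unsigned.
- Point clouds are exported in a target-centered frame rotated so the
  pipette axis is a fixed reference direction; the rotation preserves every
  point's lateral/axial decomposition, and the 5 µm soma reference sphere
  accompanies the export.
- Determinism: all stochastic components (noise, scenario sampling, batch
  seeds) derive from explicit integer seeds; identical inputs give
  bit-identical outputs.
- Problem sizes in the test suite: localization sweeps run on 96 × 96 × 60
  grids at reference pitch (the ROI scale at which the pipelines operate),
  batches at 100 approaches per strategy on the full 256 × 256 × 150
  scene, noise robustness at 50 trials, dense-labeling selection at 60
  trials — sizes chosen to estimate each property stably.
- Timing instrumentation of simulated phases is available in execution
  logs but is never a test criterion (workflow time is hardware-bound).
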