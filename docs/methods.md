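# Methods

This note documents the models, estimators and numerical choices behind
`bbflow`: a synthetic end-to-end reimplementation of an in vitro analysis in
which spin-echo black-blood (BB) MRI signal is used as a proxy for the
velocity reduction that flow-modulating devices (FMDs) produce inside
intracranial-aneurysm phantoms.

## The scientific question

In BB MRI, fast-flowing spins are suppressed and appear dark; slow or static
fluid keeps its signal.  If an implanted device (a flow-diverter stent in the
parent vessel, or an intrasaccular flow disruptor in the sac) reduces
intra-aneurysmal velocity, BB suppression *fails* inside the sac and the
signal rises.  The analysis quantifies this: normalized BB signal and
phase-contrast (PC) velocity are measured in geometrically registered
volumes of interest (VOIs), per-device treatment effects

    delta = (value_with_device - value_without) / value_without

are formed, and their association is tested nonparametrically.  An
effective device yields `delta_velocity < 0` and `delta_BB > 0`, and across
devices the two are inversely correlated.

Note the sign convention: the relative change is taken *treated minus
untreated over untreated*.  This reproduces the reported directions
(velocity drops give negative effects, BB gains positive ones).

## Phantom generator

The generator emulates 3D-printed vessel models submerged in agarose gel and
perfused by a pulsatile pump:

* **Geometry.**  Straight tubes (inner diameter 4 or 6 mm, wall 3 mm) and
  saccular aneurysm models: a sidewall sac with the patient-derived
  dimensions 14.1 x 7.7 x 13.4 mm (height x neck x dome), and four
  bifurcation sacs from 3.5 x 2.7 x 3.2 to 16.4 x 9.2 x 10.2 mm on a
  3.2 mm parent tube (a typical basilar calibre; the source geometry is
  patient-specific and does not print its parent diameter).  Sacs are
  ellipsoids placed so the cross-section at the attachment plane matches the
  neck width.  CAD lumen/wall surfaces are extracted by marching cubes on an
  analytic inside-positive field at 0.35 mm pitch, which makes them
  watertight and sub-voxel accurate (tube volume error < 1%).
* **VOIs.**  A cylindrical vessel VOI (80% of the lumen radius, 10 mm long)
  in the parent segment, an ellipsoidal aneurysm VOI (75% of the sac
  semi-axes), and two agarose reference cuboids of 19.5 x 16.3 x 23.4 mm
  placed laterally, clear of the sac wall.
* **Flow.**  Parent vessels carry a Poiseuille profile scaled by a unit-mean
  raised-cosine cardiac waveform (peak at 0.2 s of an 0.8 s cycle for
  straight/ICA conditions, 1.26 s period for the bifurcation models; peak
  flow about 2.5x the mean).  The sac carries a solid-body-like
  recirculation capped at the parent mean speed and scaled by the treatment
  factor `k` (1 = untreated, 0 = arrest).  Only the ordering and scaling of
  median speeds matter downstream; no turbulence, elasticity or strut
  geometry is modelled — a device *is* its `k`.
* **Device set.**  Fifteen devices: five flow diverters on the ICA model and
  ten intrasaccular devices across the bifurcation models.  The `k` values
  are fixed study conditions derived from the published per-device
  reductions where printed (strongest FD 0.6/12.2 -> k = 0.05; weakest
  11.2/12.2 -> k = 0.92; smallest/largest bifurcation models 11.8 -> 0.6
  and 14.3 -> 3.2 cm/s) and interpolated for the rest.
* **Image formation.**  TOF: bright lumen (200), mid-gray wall (60), dark
  gel (20).  BB: gel at the agarose level (100), wall brighter (140), fluid
  `S = S_agar * (beta + (1 - beta) exp(-|v| / v0))` with floor
  `beta = 0.05` — monotone non-increasing in the time-averaged speed.  The
  exponential-with-floor form is a calibration stand-in (only monotonicity
  and the gradual/sharp regimes are constrained by observation):
  `v0 = 20 cm/s` for the perpendicular-readout variant (gradual, near-linear
  decay over the physiological range) and `2 cm/s` for the MSDE-prepared and
  parallel-readout variants (sharp decline around ~5 cm/s).  PC: magnitude
  plus per-component phase `pi * v / VENC` wrapped to (-pi, pi], with
  `VENC = 1.1 x` the maximum true speed.  Each modality is rendered under
  its own small rigid misalignment (<= 4 degrees, <= 2.5 mm by default; all
  BB variants share one frame, PC stays in the scene frame, emulating
  marker-based plane planning).  Rician noise (two Gaussian channels) is
  added last; `sigma = 2` on the 100-level gel, consistent with the high
  SNR of long-TR spin-echo and averaged PC protocols in vitro.  Metal
  artifacts are modelled as spherical signal voids with a returned mask.
* **Grid.**  0.6 mm isotropic by default (between the 0.55–0.75 mm
  acquisitions emulated); the field of view is padded so misaligned renders
  still contain the whole model.
* **Truth registry.**  Every scene records the applied misalignments,
  noiseless per-VOI median speeds and noiseless BB medians, enabling
  registration-recovery and suppression-monotonicity tests.

What the generator does *not* emulate — partial-volume averaging inside a
voxel, eddy-current phase errors beyond a linear term, strut-level flow,
ghosting — bounds what green tests show: they validate the measurement
chain and the statistics under the stated signal model, not scanner
physics.

## Measurement chain

1. **Segmentation** — threshold window + connected component from a seed
   (6-neighbourhood by default; thresholds and connectivity are config, as
   the emulated workflow chose them interactively), then marching cubes at
   the 0.5 iso-level.  The binary lattice is anti-aliased with a 0.6-voxel
   Gaussian first; otherwise stair-stepping inflates surface area by ~10%
   and biases ICP.  Structures too small to survive the blur fall back to a
   supersampled binary extraction.
2. **Registration** — ICP with evenly strided subsampling (<= 20 000
   points), tolerance 1e-6 mm on the error change, 200 iterations max.
   The TOF lumen is aligned to the CAD lumen (`T_lumen`), the TOF wall to
   the BB wall (`T_wall`); CAD VOIs map into BB space via
   `T_wall @ T_lumen^-1` (column-vector convention).  The pipeline uses the
   point-to-plane metric: for near-cylindrical vessels the axial
   translation is observable only through end caps (~2% of points), which
   point-to-point correspondence cannot exploit; a small ridge keeps the
   genuinely unobservable azimuthal freedom at its initial value.
   Initialization is the identity (scanner frames are coarsely aligned);
   a principal-axes initialization is available for arbitrary poses of
   asymmetric surfaces.  Reported alignment error is the mean
   nearest-vertex distance on dense marching-cubes surfaces.
3. **VOI voxelization** — each slice plane cuts the closed VOI surface into
   planar contours (in voxel-index space, where pixel cells are unit
   squares); a pixel joins the mask iff the contour covers strictly more
   than 50% of its cell, with coverage computed by exact polygon–rectangle
   clipping, so the rule is deterministic.  "Voxel volume" for this 2D step
   is in-plane pixel area; slice thickness is not re-weighted.
4. **BB normalization** — voxel intensities divided by the pooled
   voxel-weighted mean over both agarose cuboids; voxels pooled across
   slices; median with first/third quartiles.  Artifact-masked voxels are
   excluded and counted.  Normalization cancels any global gain.
5. **PC velocimetry** — `v = VENC * phi / pi` per component; single-wrap
   aliasing correction where a voxel's sign disagrees with its
   6-neighbourhood majority in the fluid mask (iterated to a fixed point,
   hence idempotent); a linear phase offset `a + bx + cy + dz` fitted over
   static gel and subtracted.  Velocity summaries use five equidistant
   planes perpendicular to the vessel (spacing 1.5–2 mm) or sac axis
   (0.5–1.5 mm depending on sac size): per cardiac phase, speed magnitude
   is spatially averaged in-plane, planes are averaged with equal weight,
   and the temporal *median* is reported because pulsatile speed
   distributions are skewed.  Two numerical refinements keep the spatial
   mean faithful at vessel-sized regions (see below).

### Plane-averaging accuracy

A hard in/out pixel decision quantizes the ROI area and moves the spatial
mean of a parabolic profile by several percent at 0.5–0.7 mm pixels on a
2 mm-radius vessel.  The plane summary therefore (a) samples on the voxel
lattice with *partial-volume coverage weights* (4x4 supersampling of the
analytic region, or trilinear mask interpolation when only a mask exists),
and (b) uses mask-normalized interpolation of the speed field so that
out-of-fluid zeros do not dilute boundary samples.  With both, the steady
full-lumen summary reproduces `Q / (pi r^2)` to ~1% at 0.5–0.6 mm voxels.
Speed magnitudes acquire a positive noise floor at low SNR; when a noise
estimate from static gel is available the summary subtracts it in
quadrature (`sqrt(max(|v|^2 - 3 sigma^2, 0))`) before averaging.

## Statistics

Spearman rho on mid-ranks (exact permutation p for n <= 9, t-approximation
beyond); tie-corrected Kruskal–Wallis H with chi-square p (identical data
returns H = 0, p = 1 by convention); Dunn pairwise z with tie-corrected
pooled variance and Benjamini–Hochberg step-up adjustment (requires >= 3
groups); two-sided Wilcoxon signed-rank with zeros dropped, exact sign
enumeration (computed by convolution) for n <= 20 without tied magnitudes
and a tie-corrected normal approximation otherwise; OLS with R^2 (constant
response gives R^2 = 0 by the SS_tot = SS_res convention).  These thin
implementations exist so small-sample p-values are exact and reproducible;
the test suite cross-checks each against independent enumeration oracles
and library routines.  The statistical unit for BB distribution comparisons
is the voxel — group p-values are voxel-scale and carry the usual
pseudo-replication caveat, which the pipeline notes in its report metadata.

## Reproducibility and problem sizes

Every run is driven by one config and one seed, expanded deterministically
into per-scene substreams; identical configs produce byte-identical CSV
outputs.  The shipped analyses use 0.6–0.7 mm grids and 8–10 cardiac
phases, which keep a full 20-scene device experiment within minutes on one
CPU while holding the quantification errors documented above; the grid,
phase count, noise and misalignment magnitudes are all config-exposed.

## Known limitations

* The BB signal model is parametric; absolute `delta_BB` magnitudes depend
  on `v0`/`beta` and are not comparable to scanner-measured values —
  directions, orderings and correlations are.
* Rotationally symmetric straight-tube scenes leave an azimuthal degree of
  freedom unobservable to any surface registration; the ridge-regularized
  point-to-plane step pins it at the initialization, and on-axis VOIs are
  insensitive to it.
* Velocity summaries assume the evaluation-plane axis is known from the
  scene geometry (the marker-based planning of the emulated workflow);
  plane placement error is not simulated.
* The single-wrap unwrapping corrects isolated aliased voxels only,
  consistent with the VENC rule making wraps rare; coherently aliased
  regions would need spatial unwrapping, which is out of scope.
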