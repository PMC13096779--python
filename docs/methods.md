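# Methods

## The problem

Long-term light-sheet imaging of a growing tissue — here a posteriorly
elongating tailbud with all nuclei fluorescently labelled — fails once the
tissue outgrows the detector's field of view (FOV). `tailtrack` models the
standard remedy: during acquisition, estimate the tissue's drift from the
images themselves and feed it back to the microscope stage so the object is
re-centred; after acquisition, resample the saved series to isotropic
voxels and register all timepoints into one global frame, removing the
stage jumps the tracking introduced.

Real microscope hardware is replaced by a synthetic phantom with exact
ground truth, so every stage of the pipeline is testable end to end without
any deposited data.

## Registration core

Translation between two volumes `a`, `b` is estimated by phase
correlation: the cross-power spectrum `F(a)·conj(F(b))` is normalized to
(at most) unit modulus and inverse-transformed; the surface peak sits at
the content shift, disambiguated from FFT wraparound by mapping peak
indices into `[-dim/2, dim/2)`.

Numerical choices:

* **Sign convention.** The returned shift `s` satisfies "`b` is `a` with
  content moved by `+s` voxels"; every caller documents direction, and
  antisymmetry (`shift(a,b) = -shift(b,a)`) is tested.
* **Normalization guard.** The spectrum is divided by
  `max(|·|, 0.03·max|·|)`. Pure whitening hands noise-dominated high
  frequencies the same weight as signal, which on smooth (blob-like)
  content destroys subpixel accuracy; the relative guard downweights
  low-magnitude bins while leaving phases untouched, so noiseless integer
  recovery remains exact (verified exhaustively) while fractional-shift
  error at 5 % noise drops from ~1 voxel to ≤ 0.15 voxel. The behaviour is
  flat across guard values 0.01–0.3.
* **Subpixel refinement.** Separable three-point parabolic fit through the
  peak and its circular neighbours per axis,
  `Δ = 0.5(c₋ − c₊)/(c₋ − 2c₀ + c₊)`, forced to 0 for non-concave or
  non-finite fits. Cheap and adequate for stage feedback; the residual
  parabola-on-sinc bias is ~0.1 voxel.
* **Windowing.** A separable Hann window is applied before the FFT when
  registering acquired (non-periodic) frames; it is off in tests of exact
  circular shifts and for Fourier-resampled (hence circular) test data,
  where it would suppress sparse content and is not needed.
* **Confidence.** The surface peak divided by the coherent-peak ceiling
  (mean normalized-spectrum magnitude), clipped to [0, 1]; a near-constant
  surface (correlation mass spread uniformly, e.g. a constant frame
  against anything) is assigned 0. Identical or noiselessly shifted pairs
  score ≈ 1, tracked phantom frame pairs 0.5–0.7, and the post-processing
  fallback floor of 0.03 trips only on degenerate pairs.
* **Ties** at equal peak height break toward the smallest lexicographic
  `(z, y, x)` index (C-order argmax), for determinism.
* Registration operates on intensities as acquired: no log transform, no
  background subtraction.

An FFT-free oracle (`oracle_shift`, exhaustive spatial-domain circular
cross-correlation, O(N²)) provides an independent reference for the
estimator on small volumes; scikit-image's `phase_cross_correlation` is a
second, external cross-check in the test suite.

## Phantom

The phantom stands in for an embryo whose nuclei are all labelled,
imaged from the late-somite stage onward while the tailbud elongates.

**Growth model.** Nuclei advect along the body axis (default `+x`) with
velocity `elongation_rate · w(p)`, where `w` ramps linearly from 0 at the
anterior-most nucleus to 1 at the posterior tip (recomputed per frame) —
posterior tissue moves fastest, anterior tissue is effectively anchored,
as with an agarose-mounted embryo whose tail grows freely. Per-axis
Gaussian jitter models cell-scale motility. Divisions duplicate a nucleus
(daughter records the mother's id); Poisson-distributed new nuclei appear
in a posterior progenitor zone. No cell death, no excluded volume.

**Image formation.** Each nucleus renders as a separable Gaussian blob
(sd = PSF sigma in µm, peak amplitude = its intensity) into the
stage-positioned FOV grid, clipped at the borders, over a constant
background. Shot noise uses expected photons `signal·photon_scale`
(Poisson below 20 expected photons, Gaussian of matching variance above —
exact low-signal behaviour at full-array speed) plus Gaussian read noise.
Volumes are float32. Two RNG streams (tissue, camera) derive from the
master seed by fixed offsets, so changing the noise realisation never
changes the trajectory.

**Defaults and why.** Voxels (2.0, 0.5, 0.5) µm on a (40, 192, 192) grid
— anisotropic, light-sheet-like, making isotropic downscaling non-trivial
in both directions (z is interpolated up, y/x block-averaged down). PSF
(1.5, 0.75, 0.75) µm. Growth: `elongation_rate` 2 µm/frame (1 µm/min at
2-min framing), `proliferation_prob` 0.01/frame, `addition_rate`
0.1/frame in a 20 µm posterior zone, jitter 0.2 µm; initial tissue of
150 nuclei in a (40, 60, 60) µm box centred in the FOV. These are the
study conditions for the open/closed-loop contrast: without corrections
the tissue centroid (≈ 1 µm/frame) leaves the tolerated FOV margin by
frame ≈ 40 < 50; with corrections it is retained across 120 frames
(4 simulated hours) in every seed tried, with ≥ 9 µm to spare. They were
fixed by simulation — including the influx level, see below — before the
acceptance assertions were frozen.

## Online tracking loop

Frames are acquired every `frame_interval` = 2 min. Every
`registration_stride` = 5 frames (one event per 10 minutes) the current
as-acquired volume is registered against the volume from the previous
event; the estimated sample drift, multiplied by `gain` (default 1, full
re-centring) and clamped per axis to a quarter of the FOV extent, is
commanded to the stage before the next frame.

Because the reference frame may predate the previous stage move, the
apparent image shift equals sample drift minus intervening stage motion;
the controller adds back its own known stage delta. Without this term a
constant drift is only half-compensated on average and the sample is
eventually lost — the virtual loop makes this failure mode easy to
demonstrate.

Degenerate registrations (constant frames) log a warning and apply zero
correction. An actuation-latency hook (`latency_frames`, default 0) and a
pre-registration downsample factor (default 1) exist but are off by
default. The session log records, per frame, the stage offset at
acquisition, the estimated drift and applied correction at events, the
ground-truth centroid, and whether the centroid is at least `margin`
(default 5 µm) inside every FOV face.

**What retention does and does not show.** A rigid-shift estimator applied
to an internally stretching tissue has no single "true" translation: the
measured shift tracks the (window-weighted) bulk of the visible content,
while the whole-tissue centroid is additionally pulled posteriorly by
progenitor influx — nuclei that *appear* register as new content, not as
displacement, so no image-based drift estimator can follow that component.
The centroid therefore creeps toward the posterior FOV face at a rate
roughly proportional to the influx; at influx levels several-fold higher
than the default the creep consumes the full FOV slack within the 120-frame
run in 5–15 % of seeds. At the default influx the loop retains the
centroid with ≥ 9 µm to spare in every seed tried (30 distinct seeds).
Real embryos are more forgiving in one respect (the tailbud is a compact
bright object, not an endless uniform strip) and less in others
(occlusion, bleaching, optical degradation), so passing here demonstrates
the control loop's correctness, not microscope-grade robustness.

## Post-acquisition processing

1. **Isotropic downscaling** to 1 µm³ voxels: per axis, area (block)
   averaging with partial-block support when coarsening, linear
   interpolation at cell centres when refining; physical extent is
   conserved to within one target voxel and mean intensity to < 0.5 %.
   Registration then runs on the isotropic grid, so voxel shifts equal
   micrometre shifts.
2. **Sequential registration**: consecutive pairs are phase-correlated
   (consecutive frames are most similar as appearance evolves over hours)
   and pairwise shifts prefix-summed into cumulative shifts relative to
   frame 0. A session log, when provided, initializes each pair with the
   known stage jump (the moving frame is pre-rolled by the rounded jump);
   pairs with confidence below 0.03 fall back to the stage-log prior (or
   zero) and are flagged. No global loop closure — a time series is a
   single chain.
3. **Global resampling**: the union bounding box of all shifted frames is
   allocated once (guarded by a voxel budget, default 2²⁸ voxels), and
   each frame is placed by trilinear interpolation at its cumulative
   shift, zeros outside data. A 1 nm tolerance keeps subpixel residues
   from inflating the box.

`stabilization_report` maps ground-truth nucleus positions into the
as-acquired and the registered global grids and reports per-frame RMS
displacement relative to frame 0 before and after registration; on a
rigid stage-jump phantom the after-registration RMS is ≤ 1 voxel
(typically ≈ 0.15, interpolation and subpixel error only).

## Formats and reproducibility

Volumes travel as multi-page TIFF plus an authoritative JSON sidecar for
voxel size (TIFF resolution tags are written too but z-spacing conventions
inside TIFF alone are unreliable); tracks, session logs and shifts are
CSV with fixed headers; configuration is YAML validated field by field
with unknown keys rejected by name. Every pipeline output is reproducible
from (config, seed): integer outputs bit-exactly, floats to writing
precision. KLB and TGMM/MaMuT XML formats are out of scope (external
tools' formats); segmentation and single-cell tracking themselves are out
of scope — the phantom's exact track table replaces them for validation.

## Problem sizes in tests and the acceptance script

The test suite exercises the full default FOV where the property demands
it (noise-robust recovery, the 20-seed × 120-frame open/closed contrast)
and reduced grids (16–48 voxels per axis) elsewhere; the acceptance
script re-measures the same quantities with 10 seeds for the loop study
and 12-frame series for stabilization and determinism. All seeds derive
from the single `--seed` argument.

## Known limitations

* Rigid translation only: no rotation, scale, non-rigid deformation, or
  multi-resolution search.
* The phantom's kinematics are a caricature (linear velocity ramp, no
  mechanics, no somites, no optical artefacts such as stripes or
  attenuation); conclusions about real-data robustness are limited
  accordingly.
* Drift accumulation over the registration chain is not re-optimized
  globally.
* A single 3-axis stage is modelled; no actuation overshoot, and frames
  are never dropped during moves.
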