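# Methods

This note documents the models, numerical choices and limitations behind
`cbctdose`. All lengths are millimetres in a fixed world frame; grids are
axis-aligned with the origin at the centre of voxel (0,0,0) and arrays
indexed `[x, y, z]` with +z superior. Displacement fields use the pull
(backward-sampling) convention throughout: a field on grid A maps a point
`x` in A to `x + d(x)` in the image being sampled, so warping an image from
B onto A uses a field defined on A. Forward fields (planning CT → CBCT) live
on the CT grid; backward fields (CBCT → CT) on the day grid.

## Synthetic 4D thorax phantom

The phantom is an *analytic* HU function of continuous coordinates: a
soft-tissue body ellipsoid (40 HU) in air (−1000 HU), two lung ellipsoids
(−750 HU) truncated inferiorly by a flat diaphragm plane, a spinal-cord
cylinder (100 HU), a spherical tumor (60 HU, default radius 10 mm ≈ 4.2 cc)
and seeded vessel-like spheroids (−100 HU, radius 4 mm) that double as
landmarks. Tissue boundaries blend over 3 mm (smoothstep on an approximate
signed distance) so that voxelization and trilinear resampling are well
conditioned; with sharp edges, interpolation error at boundaries would
dominate every image-space comparison.

Breathing is a 10-phase cosine law with phase 0 = end of inhale as the
reference: the amplitude factor at phase p is `(1 − cos(2πp/10))/2`. A
material point at reference position `x` sits at `x + s_p(x)` in phase p,
where `s_p` is superior–inferior, equal to the diaphragm amplitude `A_d`
(default 10 mm; clinical lung excursions are typically 5–13 mm) below the
diaphragm and tapering linearly to zero at the lung apex. A localized smooth
blend carries the tumor with its own amplitude `A_t` (default 8 mm); inside
the blend's plateau the map is an exact translation, so the tumor
centre-of-mass displacement follows the `A_t` law exactly and the field is
analytically invertible there.

Phase images are produced by evaluating the analytic anatomy at the
numerically inverted motion map (fixed-point iteration; the map is
contractive because the taper slope is ≈0.1). This construction makes `s_p`
the **exact** pull-field that warps phase p back onto the reference — the
emitted ground truth is analytic, never the product of a registration.
Landmark correspondences are the vessel centres and their analytic images.

CBCT-like degradation applies, in order: an optional rigid setup shift
(trilinear resample), a global intensity scale/offset (default 0.95 / −10 HU),
additive Gaussian noise (default 20 HU), and cylindrical field-of-view
truncation to air fill (default 120 mm diameter, which clips the lateral
thorax the way a treatment-machine scan clips a lung patient). All stages
are seeded; identical seeds give bitwise-identical volumes. The generator
does **not** model scatter/cupping artifacts, breathing hysteresis or
irregular traces, or textured tissues — so passing tests demonstrate the
pipeline's correctness under a known smooth deformation and a realistic
intensity transform, not its accuracy on clinical CBCT.

Default grid: 64³ voxels at 2.5 mm isotropic (a 16 cm cube). This is the
scale at which all quality figures are quoted; the 32³/5 mm variant used for
orchestration tests is below the resolution the registration defaults are
designed for and is exercised only for plumbing and determinism.

## Deformable registration

Two stages, mirroring the block-matching-then-dense-local-correlation
architecture used by clinical CT↔CBCT registration tools:

**Stage 1 — block matching.** At the coarsest pyramid level, non-overlapping
blocks (16 mm) search exhaustively over integer-voxel offsets (±20 mm) for
the maximum Pearson correlation; ties go to the smaller displacement. The
discrete peak is refined per axis by parabolic interpolation of the
correlation surface, except when the peak correlation is already exactly 1
(sub-voxel refinement of a perfect match would only import the asymmetry of
its neighbours). Blocks must have real structure (intensity SD > 10 HU) and
a winning correlation above 0.4 to vote; votes are splatted into a dense
field by normalized Gaussian weighting. At finer levels the block match is
repeated on the *residual* (the moving image warped by the current field)
with a search radius shrinking by 4× per level, and composed into the field;
blocks whose warped content samples outside the moving volume are excluded.

**Stage 2 — dense refinement.** A demons-style iteration on locally
normalized intensities: both images are normalized to
`(I − μ_σ(I)) / sqrt(var_σ(I) + floor²)` with a Gaussian window (σ = 3
voxels) and a 5 HU variance floor. Local normalization cancels the global
and slowly varying intensity transformation between CT and CBCT, which is
what makes a local-correlation criterion appropriate for this image pair;
the variance floor keeps flat regions at zero instead of amplifying
interpolation residue into unit-scale pseudo-structure. The update force is
the classic gradient-scaled difference with step normalization κ = 0.8 ×
voxel size (bounding each update by κ/2), **gated by a fixed-image structure
confidence** `var/(var + 15²)` so that structureless regions — where any
apparent force is noise — receive no update. Fluid regularization smooths
each update (σ = 2 mm) and diffusion regularization smooths the total field
(σ = 2.5 mm). Each level is pre-smoothed by 1 voxel to suppress noise
chasing. Iterations stop on convergence (mean update < 0.02 mm) or
divergence (mean update growing ≥ 2 % for 3 consecutive iterations, which
abandons the level and flags the result). The mean windowed correlation is
recorded per iteration. Registration-internal warps use edge extension
rather than a constant fill: a constant fill fabricates an intensity step at
the volume boundary whenever the background levels of the two images differ,
and local normalization amplifies that step into a runaway force.

Measured on the phantom (64³): identity registration returns an exactly zero
field; a 6 mm rigid shift of a fully-imaged body is recovered to ≈0.1 mm; the
pooled landmark TRE over phases 3/5/7 drops to ≈6 % of its pre-registration
value; the full degraded-CBCT pipeline reproduces the day anatomy to
≈10–14 HU mean absolute error over the body.

**FOV handling.** Cropping to the CBCT field of view masks CT voxels to air
without changing the grid, so the registered field stays on the full
lattice. Expansion back to the CT field of view zeroes the field outside the
FOV, blurs with a Gaussian (default σ = 6 mm) so the displacement decays
smoothly to zero, and restores the original values deeper than 3σ inside
the FOV (where the blur's influence is below 0.2 %).

**Inversion.** `b_{k+1}(x) = −f(x + b_k(x))` from `b_0 = 0`, stopping when
the mean composition residual `|f(x + b(x)) + b(x)|` falls below the
tolerance (default 0.1 mm). The forward field is sampled with edge extension
during inversion: the breathing field is constant below the diaphragm, so
the zero-fill alternative would invent a discontinuity at the inferior grid
face and the residual there would equal the full amplitude.
Non-convergence flags the result rather than raising.

## Phase matching

The diaphragm position of a phase is read from a lung mask: for each axial
column through the lung, the most inferior lung voxel; the position is the
mean over the central 50 % of each lung component's columns (central by
in-plane distance to the component's column centroid), which rejects thin
lateral columns on the curved lung boundary. Lung masks are segmented per
phase by three-class Otsu thresholding (air / lung / soft tissue), followed
by a one-voxel morphological opening and small-component removal to delete
partial-volume shells at air–tissue interfaces and noise speckle. Otsu-based
thresholds are invariant to affine intensity maps, so the pairing is
unchanged by the CBCT's global scale and offset; a fixed HU threshold
remains available as a parameter. Each CBCT phase is paired with the CT
phase minimizing the absolute diaphragm difference. Because a cosine trace
visits every non-extreme height twice, exact ties are structural: among tied
CT phases the CBCT phase's own index is preferred, then the smallest index
(a pure smallest-index rule would silently map phase 9 onto phase 1 of an
identical set).

## Pseudo-CT and dose

Intensity overrides (e.g. dental artifacts) are applied to the planning CT
first, in list order; the pseudo-CT then samples the overridden CT at
`x + b(x)` inside the FOV and patches outside with the matching-phase
planning CT shifted by the recorded couch correction — the same convention a
clinical implementation uses, which makes FOV-truncation effects testable.

The dose engine is deliberately minimal and explicitly **non-clinical**: for
voxels inside a rectangular divergent aperture,
`dose = weight · exp(−μ · radiological depth) · (SAD/d)²`, with the
radiological depth ray-marched (1–2 mm steps) through density
`(HU + 1000)/1000` clamped at zero, μ = 0.005 mm⁻¹ (megavoltage water-like
scale) and SAD = 1000 mm. It reproduces exponential depth dose with
inverse-square divergence (R² > 0.999 against the closed form on a water
slab), which is sufficient to exercise warping, accumulation and DVH
machinery; it has no scatter, penumbra or heterogeneity corrections and no
MLC/VMAT model. Plan doses are normalized so the mean GTV dose equals the
prescription (default 12 Gy × fractions, an SBRT-like schedule).

Dose warping is direct trilinear pull-sampling with zero fill — no
mass/energy-transfer correction, matching interpolation-based clinical dose
warping and shares its known limitation in strong-gradient/compression
regions. 4D accumulation uses uniform 1/10 phase weights (phase-sorted 4D
convention). Course accumulation warps each daily dose through the replan
chain (each link is a field on the predecessor plan's grid) and sums on the
pretreatment CT; with an identity chain the sum is exact to the last bit.

## QA metrics

`D_q` is the dose received by at least q % of the structure volume, computed
as the `(1 − q/100)` quantile of the voxel doses with linear interpolation
between sorted voxels (verified to agree exactly with an independent
brute-force sort oracle on grids up to 32³); this fixes the DVH convention,
which differs subtly between planning systems. `Vx` is the percentage of ROI
voxels at or above x Gy. Percent-of-plan values are ratios of like metrics
× 100. DICE and symmetric mean surface distance (via Euclidean distance
transforms with anisotropic sampling) quantify propagated-contour
agreement; warning flags trip **strictly above** a 10 % volume change and a
3 mm centre-of-mass shift. TRE pools per-landmark errors across cases
(pooled mean ± SD) and also reports per-case statistics.

## Workflow model

Each fraction advances through PENDING → CBCT_READY → PSEUDO_CT_READY →
TXDOSE_READY → CUMULATIVE_READY, strictly in order; the schedule (patient,
plan chain, fractions, CBCT paths, couch corrections, statuses) round-trips
losslessly through a small XML schema with validation errors naming the
offending element. The orchestrator `run_course` is deterministic for a
fixed seed, isolates per-fraction failures (an unreadable CBCT flags only
its own fraction), and writes volumes, QA CSVs, a text summary and the final
schedule. Record-and-verify database polling and e-mail notification are
out of scope; the filesystem and logs stand in for both.

## Problem sizes used in tests

The full suite runs the quality-bearing checks (translation recovery, TRE
ratio, pseudo-CT fidelity, inversion residual) on the default 64³ phantom
and the orchestration checks (fixtures, fault injection, five-fraction
determinism) on a 32³ variant in the fast registration preset; the
acceptance script uses the same sizes. These choices keep a complete run in
the minutes range on one CPU while measuring the method at its design
resolution.

## Known limitations

- Axis-aligned geometry only (no oblique direction cosines, no DICOM REG).
- The phantom's smooth, hysteresis-free motion and piecewise-constant HU are
  easier than clinical data for both registration and segmentation; the
  quality figures above are upper bounds on clinical performance.
- The dose engine is a pedagogical stand-in; absolute dose values have no
  clinical meaning, only their relative/geometric behaviour is tested.
- Dose warping without mass correction can violate integral-dose
  conservation under compressive fields (verified only under rigid shifts).
- The demons refinement leaves the field interpolation-determined in large
  structureless regions; agreement between forward and inverse registration
  is therefore asserted only where image structure constrains the field.
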