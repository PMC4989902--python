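# Methods

## Model and procedure

The package treats a PCLS contraction movie as a sequence of observations
of a 2-D deformation of the reference frame. All kinematic quantities are
Lagrangian: indexed by reference-frame position (X, Y), with the deformed
position (x, y) = (X + u, Y + v).

**Displacement estimation.** Dense optical flow between the reference
frame and each frame of interest. The backend is pyramidal coarse-to-fine
TV-L1 (iterative Lucas–Kanade is available as a faster alternative); the
module's contract is behavioral, enforced by the synthetic validation
suite: sub-0.2 px mean error on known translations, ≥0.95 correlation
with the analytic contraction field, and strain residuals ≤0.01 under
pure rigid motion. Estimated fields are smoothed with a Gaussian of
σ = 4 px before differentiation: flow noise is amplified by the spatial
derivative, and smoothing well below the strain evaluation spacing
suppresses it without biasing smooth deformations (it leaves linear
fields exactly invariant). `num_warp` is set to 20 because frame corners
under a slice rotation of ~10° move by tens of pixels, which the usual
5 warps per pyramid level cannot track.

**Strain evaluation.** F is estimated at grid points (default spacing
7 px) from four displacement samples at (X±h, Y), (X, Y±h) with h = 7 px
by central differences, then E = (FᵀF − I)/2, eigenvalues from the
invariants (closed form), eigenvector from the better-conditioned row of
(E − λI)w = 0. Central differences are exact for affine displacement
fields, so rigid motions and homogeneous stretches incur no stencil
error; for curved fields the error is O(h²). Strains are zeroed outside
the tissue mask. The evaluation grid insets by h from the frame edge.

Repeated eigenvalue (E₁₁ = E₂₂, E₁₂ = 0): any direction is an
eigenvector; the x-axis is returned and the pipeline re-orients it
radially toward the lumen center. A strain exactly tangential to the
radial direction keeps the solver's sign (deterministic, measure-zero
case).

**Tissue mask.** Tissue is textured; lumen and agarose voids are smooth.
The local variance over a 7 px window is smoothed and thresholded by Otsu
on *log*-variance (the lumen/tissue variance contrast spans orders of
magnitude, while linear-variance Otsu can split the broad tissue mode
instead). A median-ratio guard maps all-texture frames to a full mask and
featureless frames to an empty one. The mask is invariant to global
intensity rescaling. For strain evaluation, the segmented lumen dilated
by 4 px (≈ h/2) is removed from the mask so that difference stencils stay
predominantly on texture-constrained flow; without this margin the
wall-adjacent strains are biased by the unconstrained flow inside the
featureless lumen.

**Lumen segmentation.** Two candidates per frame — Otsu thresholding of
the smoothed frame, and flood-fill growing from a seed (frame center, or
the previous frame's centroid) — each cleaned to a single filled
component and screened for a smooth interior (variance well below the
frame's). The candidate whose contour lies on the sharper intensity edge
(higher mean Sobel gradient) wins; ties go to the larger region. The
winner is then re-thresholded at the half-height between the lumen
interior and surrounding-tissue intensity levels. This refinement exists
because the two candidates place the boundary at slightly different
intensity levels; anchoring it at the edge half-height makes the
boundary consistent across frames, which is what matters when the
readout is an area *ratio* over time (it reduced the boundary bias from
~2–3 μm to <0.7 μm on synthetic movies).

**Radial binning.** Distances are the Euclidean distance transform of the
complement of the lumen mask, in μm. By default the *reference-frame*
lumen defines distance: the strains are Lagrangian, indexed by reference
position, so binning them against the reference boundary keeps both
quantities in one frame; a per-frame variant is available by
configuration. Bins are half-open [k·15, (k+1)·15) μm; empty bins are
missing (NaN), not zero, and masked-out points are excluded from means
(including them would drag bin means toward zero). The count-weighted
mean over bins equals the global mean exactly.

Note on wall-bin values: for the reference contraction (R₀ = 100 μm →
r₀ = 80 μm, area-preserving) the closed forms at the wall are
E_rr = ((R₀/r₀)² − 1)/2 = 0.28125 and E_θθ = ((r₀/R₀)² − 1)/2 = −0.18.
The 0–15 μm bin *mean* is lower for E_rr (≈0.21–0.23 even for exact
analytic strains) because E_rr decays quickly with R; E_θθ decays slowly
and its bin mean stays near the wall value. Validation therefore compares
pipeline bins against the identically binned closed forms rather than
against the pointwise wall values.

**Spokes.** Boundary points of the fitted lumen ellipse at angularly
equispaced polar angles, rays along the outward ellipse normal, 8
sections × 7 rays by default, samples every 7 px (8.05 μm at 1.15 μm/px)
out to 400 μm. Displacement at continuous positions by bilinear
interpolation (exact for linear fields); strain at a sample point from
four bilinear displacement samples at ±h offsets, with the same central
differences and eigen-decomposition as the dense maps. "Radial" and
"circumferential" spoke strains are the major/minor eigenvalues, not
projections of E onto the ray. Samples whose stencil leaves the frame
are dropped with the count decremented. The sample exactly on the wall
cannot resolve E_rr's one-sided kink there (the stencil straddles the
lumen), so quantitative comparisons start one stencil half-width out.

## Synthetic ground truth

The simulator emulates the relevant features of a bright-field PCLS
recording: band-limited speckle texture (Gaussian noise low-passed to a
~3 px correlation length — the scale that drives flow accuracy), a
bright smooth lumen disc with a soft (~1.5 px) edge, additive Gaussian
sensor noise (σ = 0.01 by default), and calibration of 1.15 μm/px with
frames seconds-to-minutes apart. Default geometry: lumen radius
R₀ = 100 μm contracting to 80 μm, with a logistic radius trajectory
(fast narrowing then an asymptotic phase, relaxation after t₁ = 600 s)
mimicking the canonical agonist/relaxant caliber curve.

Contraction kinematics are area-preserving in-plane,
r(R) = √(R² − R₀² + r₀²), chosen because parenchyma is nearly
incompressible at these scales and because it yields closed-form strains
E_rr = ((∂r/∂R)² − 1)/2 and E_θθ = ((r/R)² − 1)/2 with the observed sign
structure (radial stretch, circumferential compression, both decaying
away from the wall). An exponential-decay mode
(r(R) − R = (r₀ − R₀)e^{−(R−R₀)/L}, L = 120 μm) localizes deformation
faster, emulating the sharp strain drop-off seen beyond ~120 μm in real
slices. Frames are rendered by backward warping through the inverse map
(fixed-point inversion, cubic-spline resampling — bilinear resampling
blurs the speckle anisotropically, which a flow estimator misreads as
deformation). An optional stiff circular inclusion (displacement blended
to zero by a smoothstep) emulates a neighboring vessel/airway for
heterogeneity tests.

What the simulator does **not** emulate: phase-contrast halos, uneven
illumination, out-of-plane motion and focus drift, biological texture
change over time (tissue compaction alters the speckle itself, not just
its position), multiple simultaneously contracting airways, and the
irregular (non-elliptical) lumen shapes of real airways. Passing tests
therefore demonstrate correctness of the measurement chain under
realistic texture and noise, not robustness to every acquisition
artifact; on real data the contrast percentiles, mask parameters and
flow settings in `AnalysisConfig` are the knobs to revisit.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `pixel_size_um` | 1.15 | spatial calibration, μm/px |
| `frame_interval_s` | 2.0 | temporal calibration, s/frame |
| `grid_spacing_px` | 7 | strain evaluation grid spacing |
| `stencil_h_px` | 7 | central-difference half-width |
| `flow.num_warp` | 20 | TV-L1 warps per pyramid level |
| `flow.smooth_sigma` | 4 px | Gaussian smoothing of the flow field |
| `bin_width_um` | 15 | radial distance bin width |
| `lumen_exclusion_dilation_px` | 4 | rim margin excluded from strain support |
| `n_sections` / `n_spokes` | 8 / 7 | spokes geometry |
| `spoke_radial_step_um` / `spoke_max_length_um` | 8.05 / 400 | spoke sampling |

Grid spacing and h are tied (7 px) so the strain resolution is
self-consistent with the displacement-display block size; both are
configurable.

## Problem sizes and numerical choices

Validation and the acceptance script run on 384×384 px movies
(442×442 μm at 1.15 μm/px, airway wall at 100 μm radius) with 2–6
frames; this size holds the full radial decay of the contraction field
while keeping a TV-L1 solve at a few seconds, and the recovered
quantities are unchanged at larger frames. Determinism is exact: no
stage uses unseeded randomness, and repeated runs produce byte-identical
CSV output.

Degenerate inputs: constant frames stretch to all-zero with a warning;
an empty tissue mask yields an all-zero strain field with a warning; a
frame with no plausible lumen raises a segmentation error (the caliber
series tolerates up to 20% failed frames by interpolation); distances
requested beyond the kymograph extent raise with the valid range.

## Known limitations

- Strains within ~h px of the lumen rim are extrapolated by the flow
  regularizer rather than measured; the exclusion margin removes the
  worst of it, but the first distance bin remains the least accurate
  (≈10% of peak on the synthetic benchmark, versus ≈1% further out).
- The ellipse model assumes one convex principal airway; collapsed or
  branching lumina will fit poorly (the spokes geometry degrades
  gracefully but the normal directions lose meaning).
- Direct reference-to-frame flow fails for very large deformations
  (lumen radius change ≳25% of frame size); `compose_incremental` chains
  frame-to-frame fields for those cases at the cost of error
  accumulation.
- 2-D analysis only: through-plane motion appears as apparent in-plane
  strain and cannot be distinguished from it.
- No stresses: converting strains to stresses requires a constitutive
  model of the tissue, which is out of scope.
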