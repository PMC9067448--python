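# Methods

## Coordinate conventions

All geometry lives in a single right–anterior–superior (RAS) millimetre
world frame.  DICOM's LPS coordinates are converted on read; NIfTI affines
are taken as-is.  Voxel indices are 0-based and voxel *centres* carry the
world coordinate, which makes marching-cubes vertex placement and
centerline coordinates exact rather than half-voxel-shifted.  4-D rasters
are rejected: the pipeline is defined on single-echo 3-D volumes.

## Vessel enhancement

The enhancement is the Jerman vesselness: from the image Hessian at
Gaussian scale *s*, with eigenvalues sorted by magnitude
|λ₁| ≤ |λ₂| ≤ |λ₃| and sign-flipped for bright structures, the regularized
eigenvalue is

    λρ = λ₃            if λ₃ > τ·max λ₃   (per-scale global maximum)
       = τ·max λ₃      if 0 < λ₃ ≤ τ·max λ₃
       = 0             otherwise

and the response V is 0 where λ₂ ≤ 0 or λρ ≤ 0, exactly 1 where
λ₂ ≥ λρ/2 > 0, and λ₂²(λρ − λ₂)(3/(λ₂+λρ))³ in between — a polynomial that
meets the clamped branch continuously (at λ₂ = λρ/2 it evaluates to 1).
The multiscale response is the pointwise maximum over scales.

Parameter choices:

- **Scales** default to {0.5, 0.75, 1.0, 1.5, 2.0} mm.  Facial-artery radii
  run roughly 0.5–1.5 mm; the Gaussian scale of maximal response tracks the
  vessel radius, so this set brackets the targets with one coarser scale
  for partial-volume-thickened trunks.
- **τ = 0.5**, the sensitive end of the recommended range, favouring thin
  low-contrast vessels.  Lower τ inflates the plateau region of V; higher τ
  sharpens it but drops faint vessels.
- **γ = 2 normalization**: each Hessian component is multiplied by s²,
  making responses comparable across scales (the standard choice for
  second-derivative filters).
- **Anisotropy**: derivative filters use a *physical* σ of s mm per axis,
  converted to voxel units by the per-axis spacing, and derivatives are
  rescaled to per-mm units, so anisotropic grids are handled exactly.
- **Boundaries**: reflect padding, avoiding the spurious rim responses of
  zero padding.

### Discrete derivative kernels

Gaussian derivative kernels are sampled analytically and then corrected in
two ways: the second-derivative kernel is mean-subtracted so its DC
response is exactly zero (a constant image must yield an exactly zero
Hessian, and vesselness must be exactly invariant under intensity shifts),
and both derivative kernels are moment-normalized so a ramp has derivative
exactly 1 and a parabola x² has second derivative exactly 2 despite kernel
truncation (at 4σ).  Eigenvalues whose magnitude falls below a
floating-point noise floor (10⁻¹⁰ of the intensity range, scale-adjusted)
are zeroed, so homogeneous regions cannot acquire clamp-branch responses
from rounding noise.

## Segmentation and the subcutaneous band

Thresholding the normalized response at 0.5 is the default (Otsu available
as `auto`).  The anatomical restriction "between the skin surface and the
skull" is implemented as a depth band: the head is segmented automatically
(Otsu threshold, largest 26-connected component, binary closing), the
spacing-aware Euclidean distance to the head surface is computed, and
voxels deeper than `band_depth_mm` (default 15 mm, a generous skin-to-skull
distance over the face) are discarded.  The pipeline additionally excludes
the outermost 2 mm (`skin_offset_mm`): subcutaneous arteries run beneath
the dermis, and the skin–air boundary — a curved step edge — produces weak
but systematic tube-like Hessian signatures at coarse scales that would
otherwise survive thresholding as a thin surface shell.  The offset
parameter defaults to 0 at the function level and to 2 mm in the pipeline
configuration.

Components smaller than 20 voxels (26-connectivity) are removed as noise.
Meshing runs marching cubes at iso-level 0.5 on the binary field — a
reproducible, parameter-free choice — after padding by one background
voxel so surfaces close.  A binary iso-surface is a staircase whose area
systematically overshoots a smooth shape's by up to ~10%; an optional
clamped Gaussian pre-smoothing (`smooth_sigma_vox≈0.8`) recovers analytic
areas to ~1% when mesh metrics matter more than strict binariness.

Centerlines come from 3-D thinning (Lee's algorithm), decomposed into
branches at voxels with ≥ 3 skeleton neighbours; branches shorter than
3 mm are pruned.  Traversal order is fixed by lexicographic voxel order,
so outputs are bit-reproducible.  A compact blob legitimately yields no
centerlines.

## Anatomy labeling

The study identified arteries by expert comparison with maximum-intensity
projections; this package substitutes a deterministic, reproducible
heuristic.  Each of the 18 artery/side combinations gets a spherical
region whose centroid is a fixed affine combination of 68-point landmarks
(left-side weights in `data/atlas_regions.json`; right-side regions use
the mirror-partner indices) and whose radius scales with the
outer-interocular span.  Affine combinations make the construction exactly
equivariant under similarity transforms, and mirrored index pairs make
left/right regions mirror exactly across the midsagittal plane (fitted by
least squares through the nine midline landmarks).  A centerline takes the
label whose region contains the largest fraction of its points if that
fraction reaches 0.5, with ties broken by centroid distance and then fixed
label order; everything else stays "unclassified".  The region geometry is
calibration data, not science — the weights were chosen once so that each
region sits on its artery's anatomical territory for a canonical face.

## Registration and projection

Model-to-subject matching is a 7-parameter similarity transform (faces are
rigid at this scale; affine freedom would only absorb noise), estimated in
closed form: centroid alignment, SVD of the cross-covariance with a
reflection guard (the smallest singular axis is flipped if det < 0, so the
rotation is always proper), scale from the variance ratio.  The reported
RMS residual is per coordinate axis, √(SSR/3n) — for isotropic noise σ it
estimates σ itself rather than the √3-larger per-point distance.

Camera-pose recovery minimizes 2-D landmark reprojection error through a
pinhole camera (u = fx·X/Z + cx) by Gauss–Newton on (rotation, translation),
with axis-angle increments composed on the left and a step-halving
safeguard.  The deterministic initialization back-projects the 2-D
landmarks at a nominal 500 mm depth and fits a similarity transform to the
model, folding the fitted scale into the initial depth.  Iteration stops at
step norm 10⁻¹⁰ or 100 iterations.  On noise-free correspondences the
recovered pose reprojects to < 10⁻⁶ px.  Lens distortion and depth-aware
occlusion are out of scope (the AR projection itself is depth-free).

## Accuracy statistics

Deviations are recorded per patient and artery/side in millimetres;
a dash or blank means the artery was not visualized.  Group statistics use
the sample standard deviation (n−1; groups of ≤ 1 record report SD 0).
The overall mean and SD are the *unweighted means of the 18 per-side group
means and sample SDs* — this aggregation, not the per-record pooled one,
is what the summary numbers of the source table correspond to; the pooled
alternative is available from the raw records.  Percentages use
denominator 2 × n\_subjects (one artery per side), and the brace-exclusion
recomputation shrinks the denominator to 2 × (n\_subjects − excluded)
while keeping the visualized labial counts, under the assumption that
every artifacted labial artery belongs to a brace wearer.  Printed values
round half-up (two decimals for mm, one for percentages), matching how
0.625 appears as 0.63 in the source tables.

Projection scoring uses nearest-point distance from each ground-truth mark
to the same-labeled projected curve (segment-accurate, not vertex-only),
scaled by a pixels-to-mm factor; marks whose artery has no curve score as
not visualized.

## Synthetic phantoms

The generator emulates bright-blood contrast, not MR physics: an
ellipsoidal head of uniform background intensity (default 100) with
tubular arteries of Gaussian cross-section, peak 200 and σ = radius/2 — a
differentiable profile mimicking partial-volume blur, planted 4 mm beneath
the skin along surface-parallel arcs centred on each artery's atlas
region.  The default phantom is 160³ voxels at 0.5 mm isotropic (the
acquisition voxel size is not public; 0.5 mm is a plausible high-resolution
choice), with 5%-of-peak Gaussian noise; a Rician option (magnitude of a
complex Gaussian) reflects the statistics of magnitude MR images.  The
default head gets a 1.5 mm logistic skin edge, standing in for
partial-volume smoothing at the skin–air boundary; a hard indicator edge is
available and is the `PhantomSpec` default.  Landmarks sit at fixed
parametric (azimuth, elevation) positions on the head surface with exactly
mirrored bilateral pairs.  All randomness is a pure function of the seed.

What the phantoms do **not** model: flow saturation and slab-boundary
artifacts, vessel tortuosity and branching trees, intensity
inhomogeneity, dental-brace metal artifacts (represented only by deleting
labial vessels from a spec), and realistic face shape.  Passing phantom
tests therefore demonstrates the correctness of the numerics and the
internal consistency of the chain — not clinical segmentation accuracy on
real MRA, which only patient data could establish.

Tests and the acceptance script run the chain on 120³ (60 mm) phantom
heads with proportionally scaled anatomy, keeping a full run in tens of
seconds while leaving all algorithmic parameters at their defaults.

## Known limitations

- The band interpretation of "separation" is a declared reconstruction;
  the original algorithm is unpublished.
- The region atlas is a geometric stand-in for expert labeling; closely
  spaced arteries (angular vs lateral nasal) rely on its calibration.
- Binary marching cubes trades surface fidelity for parameter-freeness
  (see above).
- Pose estimation assumes known intrinsics and a roughly frontal view;
  profile-view initialization has not been hardened.
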