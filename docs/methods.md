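# Methods

This note records the model behind `lamina3d`, the parameter choices that
matter, the numerical conventions, and what the synthetic validation does
and does not establish.

## Imaging model

The lamina is treated as a thin emitter shell imaged by a diffraction-
limited confocal microscope.  The PSF is modelled as an anisotropic 3D
Gaussian, circularly symmetric in the lateral plane, with widths
σ_r = 62 nm (lateral) and σ_z = 190 nm (axial) — the Gaussian is an
excellent least-squares fit to the confocal PSF for these purposes.  The
defaults correspond to a 63×/NA 1.32 oil objective at λ ≈ 509 nm emission.
Photon (shot) noise dominates in weakly emitting live-cell samples, so the
phantom simulator applies pure Poisson noise; dark current and read noise
are not modelled.

Recorded stacks are (z, y, x) with per-axis spacing in nm carried in a JSON
sidecar.  Reference acquisition settings: 162.8 nm axial spacing; 52.6 or
69.3 nm lateral spacing depending on scan settings.  All measurements are
designed to be independent of these voxel sizes.

## Isotropization

Two steps, both required before voxel-based measurement:

1. **Resampling** by linear interpolation onto an isotropic grid at the
   lateral density (default 60 nm).  Only upsampling is supported; the
   paper-scale use case is 160 nm → 60 nm axially.  When the lateral axes
   already sit at the target spacing only z is interpolated; otherwise full
   trilinear.  Voxel centres sit at `index · spacing`.
2. **Blur equalization.**  Since Gaussian variances add, a lateral blur of
   σ_r,blur = √(σ_z² − σ_r²) ≈ 180 nm makes the total blur isotropic.
   Exact values are kept unrounded internally; integer-nm reporting rounds
   half away from zero.  The lateral PSF extent is reported as λ/NA
   truncated to integer nm (385 nm for the defaults) to match the
   conventional printed figure, even though the Abbe half-width criterion
   is usually quoted as λ/(2NA); we follow the printed arithmetic and note
   the factor-of-two tension rather than silently resolving it.

All Gaussian filtering uses mirror (reflect) boundaries.  The boundary rule
is our choice — lamina signal can approach stack faces, and mirroring
avoids the darkening that zero-padding would cause there.

## Segmentation

Unsharp masking with a locally adaptive threshold:

    i_um = i_iso − (α · i_blur + β),    mask = (i_um ≥ 0)

with `i_blur` a separable Gaussian smoothing of the isotropic image at
σ_L = 60 nm (≈1 voxel, ≈1/6 of the lateral PSF extent — enough smoothing
without destroying the thin shell) in both lateral axes and σ_A = 900 nm
axially (15 voxels at 60 nm, ≈3/4 of the 1169 nm axial PSF extent).  Sigmas
are stored in nm and converted through the actual grid spacing, so "15
voxels" holds only at 60 nm sampling.

With 0 < α < 1 and β > 0 the threshold surface exceeds the image in dim
background and undercuts it on the bright shell; the crossing intensity is
I_c = β/(1−α).  Because Poisson noise grows with intensity on an absolute
scale, I_c is set below the mid-intensity at max[i_blur]/3; with α = 0.9
this gives β = max[i_blur]/30.  β is recomputed per image from the
smoothed maximum (taking the max after smoothing suppresses single hot
voxels; no percentile clamp is applied).  A `beta_override` exists for
reproducing fixed-β runs.  Ties at exactly zero go to the lamina; with
real-valued images the choice is immaterial.

The thresholded surface may have small holes; a morphological closing with
an exact Euclidean lattice ball of radius 2.7 voxels (81 offsets) repairs
them.  The radius is large enough to bridge one–two-voxel punctures and
small enough to leave the nuclear interior open.  Closing is applied before
any quality control and no connected-component filtering is applied by
default.  The erosion half of the closing treats out-of-volume voxels as
foreground so the operation stays extensive up to the image border.

**Quality control.**  A mask is "usable" when the largest 26-connected
foreground component holds ≥ 90% of mask voxels and the 6-connected
background splits into at least two components (an enclosed nuclear
interior exists).  The 90% figure and the cavity test are this package's
operationalization of a usable closed shell; both are configurable.

## Measurement

Masked intensities are taken from the isotropic image.  Outliers beyond
4σ of the raw masked mean are clipped to the bound, then intensities are
min–max normalized to [0, 1] — clipping strictly before normalization.
`i_average` is the voxel mean; `i_skewness` is the third standardized
moment with the population (n-denominator) standard deviation.  At lamina
voxel counts (10⁴–10⁶) the n vs n−1 distinction is negligible, but the
convention is fixed.  A single-pass shifted-moment accumulator
(`streaming_skewness`) reproduces the direct evaluation to 1e-10 relative
and serves histogram/stream use.

**Curvature.**  Principal curvatures are estimated on the gray-scale
isotropic volume; the mask only selects evaluation sites.  Gradients come
from Gaussian derivative filters at σ_g = 3 voxels (≈180 nm); the surface
normal is the principal eigenvector of the gradient structure tensor (GST)
averaged at σ_w = 7 voxels (≈420 nm).  Both scales were chosen for
stability: ±1 voxel in σ_g moves K_naaGc by well under 15% on the standard
phantom, and σ_w > σ_g is required so the tensor average spans the shell
ridge.

The shape operator is assembled from spatial derivatives of the sign-free
orientation tensor M = n nᵀ rather than from the Hessian divided by the
gradient magnitude.  The reason is geometric: on the ridge of a thin
bright shell the image gradient vanishes while the surface is perfectly
well defined, so any |∇i|-normalized formula diverges exactly where the
lamina is brightest.  Differentiating the orientation field sidesteps this
(and the eigenvector sign ambiguity).  One correction is needed: Gaussian-
smoothing M before differentiation shrinks it away from a rank-1
projector, attenuating the apparent normal rotation rate by the local
eigenvalue gap along each tangent direction; the gap is measured per voxel
and divided out.  On analytic spherical shells this estimator recovers
K = 1/R² to ~2% and the 4π calibration to within 4% for radii 15–40
voxels.

Voxels whose window-averaged gradient magnitude √trace(GST) falls below
10⁻³ of the masked maximum, or whose orientation-tensor eigenvalue gap
falls below 0.05, carry no reliable orientation; they are excluded from
the curvature average and counted in the output.  Because the normal
orientation is ambiguous, κ₁ and κ₂ are defined up to a common sign flip;
their product K — the only quantity used downstream — is unambiguous.

`A_CH` is the facet-area sum of the convex hull of mask voxel centres,
scaled to nm².  The hull deliberately ignores internal structure and
invaginations, giving a smooth envelope of lamina dimensions.  Using voxel
centres places the hull half a voxel inside the physical voxel boundary —
sub-1% at nuclear scale and accepted.  `K_naaGc = A_CH · mean|K|` is then
dimensionless and voxel-size independent.

Note that K_naaGc measured on a *segmented* mask exceeds the ideal-sphere
value 4π even for a spherical phantom: PSF blurring thickens the mask, so
its hull wraps the outer mask surface.  The descriptor is a comparative
shape statistic, not an absolute geometric invariant of the mid-surface;
the 4π calibration is verified on ground-truth shell masks.

**Spatial maps** project the masked normalized intensity and |K| along one
axis, dividing by the per-column mask count; empty columns are NaN.  The
per-column normalization is this package's choice of projection rule.  The
intensity–curvature correlation is a plain Pearson ρ over mask voxels
between normalized intensity and |K| (log-binning is display-only).

## Classification

Fisher linear discriminant: w ∝ S_w⁻¹(μ₁ − μ₂) with the pooled
within-class scatter, offset at the midpoint of the projected class means
(equal priors — the studied class sizes, 28 vs 21, are near-balanced).
The quadratic classifier uses Gaussian class-conditionals with per-class
ML covariances, equal priors.  Features are standardized internally before
the solves, making assignments exactly invariant to per-feature units; a
ridge of 10⁻⁶·trace/d (in standardized space) is added only when a matrix
is near-singular, with a log message.

Evaluation defaults to resubstitution, matching the original protocol; a
leave-one-out mode exists behind a flag and logs that it departs from that
convention.  Per-class results carry the binomial standard error
√(p(1−p)/N) rounded to integer percent and a one-sided exact binomial
p-value against chance (0.5).  Published significance bounds computed with
a different confidence-limit construction are not reproduced here; the
exact binomial tail is reported instead.

## Synthetic phantoms

`PhantomSpec` describes an ellipsoidal shell (default semi-axes 1450 ×
1900 × 1650 nm, the flattened-ellipsoid habit of cultured hMSC nuclei)
of 80 nm thickness — sub-resolution, mid-range of the lamina's physical
30–100 nm.  The shell is rendered as a radial box profile antialiased over
half a voxel with an erf edge (hard voxelization of a sub-resolution shell
would alias), then blurred by the anisotropic Gaussian PSF, scaled so the
blurred peak equals `base_photons` (default 800 expected photons, a
realistic live-cell GFP signal), and Poisson-sampled.

Invaginations are Gaussian-profile inward displacements of the surface
(depth ~600 nm, footprint σ ~500 nm by default — resolvable after PSF
blur); hotspots are multiplicative intensity patches (local lamin
accumulation).  The control class carries two mild hotspots (amplitude
1.1–1.4); the apoptotic-like class carries three invaginations
(depth 450–750 nm) and three strong hotspots (amplitude 2.2–3.8) —
the two morphological signatures of caspase-8 activation.  Control cells
are rendered at 52.6 nm lateral sampling and apoptotic-like cells at
69.3 nm, mirroring the different scan settings of the two recorded
populations and exercising the voxel-size independence of the features.
All per-cell randomness derives from one master seed through numpy
seed-sequence spawning.

**What the phantoms do not emulate:** the fibrous meshwork texture of the
real lamina, intranuclear lamina structures, neighbouring cells and
background fluorescence, depth-dependent aberrations, and detector noise
beyond the Poisson term.  Passing tests therefore establish that the
pipeline is correct and stable under its stated imaging model, not that
real populations of any particular biology will separate at the same
accuracy.

## Problem sizes and runtime choices

Validation runs use nuclei of 1.4–2.1 µm semi-axes in fields of roughly
80–150 voxels per side, 20 cells per class for the population study, and
sphere calibrations at radii 15–40 voxels.  These sizes keep the full
suite and the reproduction script in the minutes range on a single CPU
while leaving every stage (resampling ratio, PSF scales, closing radius,
curvature scales) at its real-data value.

## Known limitations

- Single nucleus per field; no scene splitting.
- Upsampling-only resampling; downsampled acquisitions are out of scope.
- The Gaussian PSF is scalar and depth-invariant; no deconvolution is
  attempted or needed by the method.
- Curvature scales σ_g/σ_w are expressed in voxels and assume ≈60 nm
  isotropic sampling; markedly different target spacings would warrant
  re-deriving them from the PSF.
- QC thresholds are heuristics for closed-shell usability, not biological
  ground truth.
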