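# lamina3d

Unbiased 3D quantification and classification of the **nuclear lamina** from
confocal fluorescence z-stacks.

The nuclear lamina is a thin (30–100 nm) intermediate-filament shell lining
the inner nuclear membrane.  Its shape changes early and visibly when a cell
changes fate — most dramatically during apoptosis, when the surface
invaginates and lamin proteins accumulate locally.  `lamina3d` turns those
qualitative observations into numbers: it segments the lamina surface from a
recorded z-stack, measures three voxel-size-independent shape descriptors per
cell, and uses them to separate cell populations with classical discriminant
classifiers.  A phantom generator produces synthetic nuclei with exact ground
truth, so every stage of the pipeline is testable without microscope data.

## Method

Confocal stacks are anisotropic twice over: voxels are coarser axially than
laterally, and the point spread function (PSF, modelled as a 3D Gaussian with
widths σ_r laterally and σ_z axially) blurs more along the optical axis.
The pipeline first makes the image isotropic in both senses, then segments,
then measures:

1. **Isotropization.**  Linear interpolation resamples the stack to an
   isotropic grid (≈60 nm).  Because Gaussian variances add, blurring
   laterally with σ_r,blur = √(σ_z² − σ_r²) equalizes the blur in all
   directions (62 nm and 190 nm give σ_r,blur ≈ 180 nm).
2. **Segmentation by unsharp masking.**  A heavily smoothed copy of the
   image (σ_L laterally, σ_A axially) scaled by α and offset by β forms a
   local threshold surface; voxels where
   `i_iso − (α·i_blur + β) ≥ 0` belong to the lamina.  The crossing
   intensity I_c = β/(1−α) is set to max[i_blur]/3, below the
   mid-intensity, because photon (Poisson) noise is absolutely larger at
   high intensity.  A morphological closing with a digital sphere of radius
   2.7 voxels (81 voxels) repairs small holes without sealing the nuclear
   interior.
3. **Measurement.**  Per cell:
   - `i_average` — mean lamina intensity after 4σ outlier clipping and
     min–max normalization to [0, 1];
   - `i_skewness` — third standardized moment of the normalized
     intensities (asymmetric lamin accumulation);
   - `K_naaGc` — normalized average absolute Gaussian curvature:
     `A_CH · mean|κ₁·κ₂|` over lamina voxels, where A_CH is the convex-hull
     area of the mask.  Dimensionless, voxel-size independent, and exactly
     4π for an ideal sphere.  Curvature comes from Gaussian derivative
     filters (scale σ_g) and a gradient-structure-tensor surface normal
     (averaging scale σ_w) evaluated on the gray-scale volume.
4. **Classification.**  Fisher linear and Gaussian quadratic discriminants
   on any 2- or 3-feature subset; confusion matrices with binomial standard
   errors √(p(1−p)/N) and one-sided exact binomial p-values against chance.

## Worked example

Measure a synthetic spherical nucleus (radius 1.2 µm, 60 nm shell, Poisson
noise) straight from the library:

```python
import lamina3d as l3

spec = l3.PhantomSpec(
    semi_axes=(1200.0, 1200.0, 1200.0), shell_thickness=60.0,
    spacing=(60.0, 60.0, 60.0), base_photons=1000.0, seed=1,
)
stack = l3.image_phantom(l3.render_shell(spec), spec)
fv = l3.measure_cell(stack, l3.OpticsConfig(), cell_id="sphere_R20")
print(f"cell={fv.cell_id}  i_average={fv.i_average:.3f}  "
      f"i_skewness={fv.i_skewness:.3f}  K_naaGc={fv.K_naaGc:.2f}")
```

prints

```
cell=sphere_R20  i_average=0.617  i_skewness=-0.486  K_naaGc=19.67
```

The near-symmetric intensity distribution gives a small skewness, and
`K_naaGc` lands above the ideal-sphere value 4π ≈ 12.57 because the
segmented mask is several voxels thick after PSF blurring, so its convex
hull wraps the outer mask surface; evaluated on the ground-truth shell mask
the same phantom yields 12.9 (see the reproduction script below).  What
matters for classification is that the descriptor responds to shape:
invaginated phantoms score systematically higher than smooth ones.

The full synthetic study — 20 control cells (smooth ellipsoids, mild
hotspots, 52.6 nm lateral sampling) against 20 apoptotic-like cells (added
invaginations, strong hotspots, 69.3 nm sampling) — runs from the shell:

```sh
lamina3d demo --seed 0 --out demo_out
```

and writes `features.csv`, `confusion.json`, and a decision-boundary
scatter plot.  With the default effect sizes the two-feature Fisher
classifier (K_naaGc, i_average) separates the populations completely.

Individual stages are available as `lamina3d phantom | segment | measure |
classify`; all parameters live in a YAML config whose defaults are shipped
with the package (`paper_defaults.yaml`).

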