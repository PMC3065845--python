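# Default configuration for the lamina quantification pipeline.
# All widths are in nanometres unless marked as voxels.
optics:
  emission_wavelength: 509.0
  numerical_aperture: 1.32
  magnification: 63.0
  psf_sigma_lateral: 62.0   # sigma_r
  psf_sigma_axial: 190.0    # sigma_z
isotropy:
  target_spacing_nm: 60.0
segmentation:
  sigma_l_nm: 60.0          # lateral threshold-surface smoothing
  sigma_a_nm: 900.0         # axial threshold-surface smoothing (15 voxels at 60 nm)
  alpha: 0.9
  ic_fraction: 0.3333333333333333
  closing_radius_vox: 2.7
measurement:
  clip_k: 4.0
  sigma_g_vox: 3.0
  sigma_w_vox: 7.0
classification:
  features: [K_naaGc, i_average]
  model: linear
  mode: resubstitution
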