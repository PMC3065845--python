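"""Isotropization of anisotropic confocal stacks.

Confocal stacks are anisotropic in two independent ways: the voxel grid is
coarser axially than laterally, and the point spread function is wider
axially than laterally.  Voxel-based shape measurements require both to be
equalized.  This module removes the sampling anisotropy by linear
interpolation onto an isotropic grid, and the blur anisotropy by an extra
lateral Gaussian smoothing whose width follows from additivity of variances:

    sigma_r_blur**2 = sigma_z**2 - sigma_r**2

so that the lateral blur after correction matches the axial blur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import VoxelGrid3D, round_half_away

__all__ = [
    "IsotropyParams",
    "resample_isotropic",
    "blur_correction_sigma",
    "apply_lateral_blur",
    "effective_lateral_sigma",
]

_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class IsotropyParams:
    """Target spacing and PSF widths for the two-step isotropization."""

    target_spacing: float = 60.0  # nm; the lateral sampling density
    sigma_r: float = 62.0  # nm, lateral PSF width
    sigma_z: float = 190.0  # nm, axial PSF width

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ValueError("target spacing must be positive")
        if self.sigma_r > self.sigma_z:
            raise ValueError("sigma_r must not exceed sigma_z")

    @property
    def sigma_r_blur(self) -> float:
        return blur_correction_sigma(self.sigma_r, self.sigma_z)


def blur_correction_sigma(sigma_r: float, sigma_z: float) -> float:
    """Lateral blur width (nm) that equalizes lateral and axial PSF blur.

    Returns ``sqrt(sigma_z**2 - sigma_r**2)``, exact and unrounded; use
    :func:`lamina3d.volume_io.round_half_away` for integer-nm reporting.
    """
    if sigma_r < 0 or sigma_z < 0:
        raise ValueError("sigmas must be non-negative")
    if sigma_r > sigma_z:
        raise ValueError(
            f"sigma_r={sigma_r} exceeds sigma_z={sigma_z}: correction sigma would be imaginary"
        )
    return math.sqrt(sigma_z**2 - sigma_r**2)


def effective_lateral_sigma(sigmas: list[float]) -> float:
    """Total width of a cascade of Gaussian filters (root-sum-square of sigmas)."""
    if any(s < 0 for s in sigmas):
        raise ValueError("sigmas must be non-negative")
    return math.sqrt(sum(s**2 for s in sigmas))


def resample_isotropic(grid: VoxelGrid3D, target_spacing: float) -> VoxelGrid3D:
    """Resample a stack onto an isotropic grid by linear interpolation.

    Only upsampling is supported (target spacing no larger than any input
    spacing): the intended use is refining the coarse axial sampling down to
    the lateral density, e.g. 160 nm -> 60 nm.  Voxel centres sit at
    ``index * spacing``; the physical extent is preserved to within one
    voxel.  Axes already sampled at the target spacing are passed through
    unchanged; otherwise full trilinear interpolation is used.  The output
    is real-valued regardless of the input dtype.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    for s in grid.spacing:
        if target_spacing > s * (1 + _SPACING_RTOL):
            raise ValueError(
                f"downsampling requested (target {target_spacing} nm > input {s} nm); "
                "only upsampling to the lateral density is supported"
            )

    values = np.asarray(grid.values, dtype=np.float64)
    factors = [s / target_spacing for s in grid.spacing]
    new_shape = [int(math.floor((n - 1) * f)) + 1 for n, f in zip(values.shape, factors)]

    axes_to_interp = [
        ax for ax, f in enumerate(factors) if abs(f - 1.0) > _SPACING_RTOL
    ]
    if not axes_to_interp:
        out = values.copy()
    else:
        coords = np.meshgrid(
            *[
                np.arange(n_new) / f if ax in axes_to_interp else np.arange(n_new, dtype=float)
                for ax, (n_new, f) in enumerate(zip(new_shape, factors))
            ],
            indexing="ij",
        )
        out = ndimage.map_coordinates(values, coords, order=1, mode="nearest")
    return VoxelGrid3D(
        out,
        (target_spacing,) * 3,
        list(grid.provenance) + [f"resample_isotropic(target={target_spacing}nm)"],
    )


def apply_lateral_blur(grid: VoxelGrid3D, sigma_r_blur: float) -> VoxelGrid3D:
    """Blur the two lateral axes with a circularly symmetric Gaussian.

    ``sigma_r_blur`` is in nm and is converted to voxels by the grid
    spacing.  The axial axis is untouched.  Boundaries are mirrored.
    """
    if sigma_r_blur < 0:
        raise ValueError("sigma must be non-negative")
    if not grid.is_isotropic:
        raise ValueError("apply_lateral_blur expects an isotropically sampled grid")
    if sigma_r_blur == 0:
        return grid.with_values(np.asarray(grid.values, dtype=np.float64), "apply_lateral_blur(0)")
    sigma_vox = sigma_r_blur / grid.spacing[1]
    out = ndimage.gaussian_filter(
        np.asarray(grid.values, dtype=np.float64), sigma=(0, sigma_vox, sigma_vox), mode="mirror"
    )
    return grid.with_values(out, f"apply_lateral_blur(sigma={sigma_r_blur}nm)")


def isotropize(grid: VoxelGrid3D, params: IsotropyParams) -> VoxelGrid3D:
    """Full two-step correction: resample, then equalize the blur laterally."""
    resampled = resample_isotropic(grid, params.target_spacing)
    return apply_lateral_blur(resampled, params.sigma_r_blur)
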