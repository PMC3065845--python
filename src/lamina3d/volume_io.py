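"""Stack input/output and optics configuration.

All volumes in this package are ordered ``(z, y, x)`` with per-axis physical
voxel spacing in nanometres.  Stacks travel as multi-page grayscale TIFF files
accompanied by a JSON sidecar that carries the voxel spacing and a free-text
processing history; TIFF resolution tags alone are not a reliable carrier for
axial spacing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelGrid3D",
    "OpticsConfig",
    "LaminaMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "psf_extents",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class VoxelGrid3D:
    """A 3D scalar intensity field with physical voxel spacing.

    Parameters
    ----------
    values
        3D array ordered ``(z, y, x)``.  Non-negative integers on ingest from
        the microscope; real-valued after isotropization.
    spacing
        Physical voxel size ``(dz, dy, dx)`` in nm; all entries positive.
    provenance
        Free-text processing history, one entry per pipeline stage.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3D (z, y, x) array, got ndim={self.values.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        dz, dy, dx = self.spacing
        return dz == dy == dx

    def with_values(self, values: np.ndarray, note: str | None = None) -> "VoxelGrid3D":
        """Copy carrying new values (and optionally a new provenance entry)."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return VoxelGrid3D(values, self.spacing, prov)


@dataclass
class LaminaMask:
    """Binary voxel set marking lamina membership, on an isotropic grid."""

    values: np.ndarray
    spacing: float  # isotropic voxel size, nm
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D (z, y, x) array")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class OpticsConfig:
    """Confocal optics: emission wavelength, objective, Gaussian PSF widths.

    The confocal point spread function is modelled as an anisotropic 3D
    Gaussian, circularly symmetric in the lateral plane (width ``psf_sigma_
    lateral``) and wider axially (``psf_sigma_axial``).
    """

    emission_wavelength: float = 509.0  # nm
    numerical_aperture: float = 1.32
    magnification: float = 63.0
    psf_sigma_lateral: float = 62.0  # nm
    psf_sigma_axial: float = 190.0  # nm

    def __post_init__(self) -> None:
        if self.emission_wavelength <= 0:
            raise ValueError("emission wavelength must be positive")
        if not 0 < self.numerical_aperture < 1.6:
            raise ValueError("numerical aperture must lie in (0, 1.6)")
        if self.psf_sigma_lateral > self.psf_sigma_axial:
            raise ValueError(
                "lateral PSF sigma must not exceed axial sigma "
                "(blur matching would need an imaginary kernel)"
            )


def psf_extents(optics: OpticsConfig) -> tuple[int, int]:
    """Total lateral and axial PSF extents in integer nm.

    The lateral extent follows the Abbe criterion arithmetic lambda/NA
    (truncated to integer nm); the axial extent is 4*lambda/NA**2 (rounded
    to the nearest nm, halves away from zero).
    """
    lam = optics.emission_wavelength
    na = optics.numerical_aperture
    lateral = int(lam / na)  # truncation matches the conventional figure
    axial = round_half_away(4.0 * lam / na**2)
    return lateral, axial


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_stack(path: str | Path, spacing: tuple[float, float, float] | None = None) -> VoxelGrid3D:
    """Read a single-channel multi-page TIFF into a :class:`VoxelGrid3D`.

    ``spacing`` overrides the sidecar; one of the two must provide it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[np.newaxis]
    if values.ndim != 3:
        raise ValueError("multi-channel input unsupported: expected one grayscale page per z-slice")
    provenance = [f"read_stack({path.name})"]
    sidecar = _sidecar_path(path)
    if spacing is None:
        if not sidecar.exists():
            raise ValueError(f"no spacing given and no sidecar found at {sidecar}")
        meta = json.loads(sidecar.read_text())
        spacing = tuple(meta["spacing_nm"])
        provenance = list(meta.get("provenance", [])) + provenance
    elif sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = list(meta.get("provenance", [])) + provenance
    return VoxelGrid3D(values, spacing, provenance)


def write_stack(grid: VoxelGrid3D, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus JSON sidecar.

    Integer grids round-trip bit-exactly; real grids are stored as float32.
    """
    path = Path(path)
    values = grid.values
    if not np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.float32)
    tifffile.imwrite(path, values, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"spacing_nm": list(grid.spacing), "provenance": grid.provenance}, indent=2)
    )
    return path


def write_mask(mask: LaminaMask, path: str | Path, *, scale255: bool = True) -> Path:
    """Write a binary mask as 8-bit TIFF ({0,255} by default, {0,1} otherwise)."""
    path = Path(path)
    hi = 255 if scale255 else 1
    tifffile.imwrite(path, (mask.values.astype(np.uint8) * hi), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {"spacing_nm": [mask.spacing] * 3, "provenance": mask.provenance, "mask": True},
            indent=2,
        )
    )
    return path


def read_mask(path: str | Path, spacing: float | None = None) -> LaminaMask:
    """Read an 8-bit mask TIFF (any nonzero voxel is foreground)."""
    grid = read_stack(path, None if spacing is None else (spacing,) * 3)
    dz, dy, dx = grid.spacing
    if not (dz == dy == dx):
        raise ValueError("masks must live on an isotropic grid")
    return LaminaMask(grid.values != 0, dz, grid.provenance)
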