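"""Voxel containers for CT-like volumes and tumor masks.

Arrays are indexed ``(x, y, z)``, 0-based, with voxel-center physical
coordinates ``origin + index * spacing`` (spacing in mm).  This convention is
used everywhere in the package; the I/O layer transposes to/from the
slice-major layout that NIfTI/NRRD readers hand back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "RegionMask"]


@dataclass
class VoxelVolume:
    """A 3D scalar grid in Hounsfield units with physical spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        HU values.  Anisotropic spacing (e.g. 1.5 mm slices) is supported.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm, each strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected 3 dimensions, got {self.intensities.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have 3 components")
        for s in self.spacing:
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"spacing must be positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, intensities: np.ndarray) -> "VoxelVolume":
        """New volume on the same grid (shape/spacing/origin) with other data."""
        if intensities.shape != self.shape:
            raise ValueError("intensities shape differs from grid shape")
        return VoxelVolume(intensities, self.spacing, self.origin)


@dataclass
class RegionMask:
    """Binary tumor mask aligned voxel-for-voxel with a companion volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels) != 0
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def check_companion(self, volume: VoxelVolume, atol_mm: float = 1e-4) -> None:
        """Raise unless this mask shares the companion volume's grid."""
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing, atol=atol_mm):
            raise ValueError(
                f"mask spacing {self.spacing} does not match volume spacing "
                f"{volume.spacing} within {atol_mm} mm"
            )


def require_extractable(volume: VoxelVolume, mask: RegionMask) -> None:
    """Invariants demanded before any feature extraction."""
    mask.check_companion(volume)
    if mask.n_foreground < 1:
        raise ValueError("empty mask: at least one foreground voxel required")
    region = volume.intensities[mask.voxels]
    if not np.all(np.isfinite(region)):
        raise ValueError("non-finite intensities inside the mask")
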