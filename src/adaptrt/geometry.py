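"""Raster geometry primitives shared by every stage of the pipeline.

Conventions (used consistently across the package):

* Arrays are indexed ``[i, j, k]`` over the anatomical axes ``(z, y, x)``,
  matching the slice-major layout of CT stacks.
* ``spacing`` and ``origin`` are given in array-axis order ``(z, y, x)`` in mm.
* Grids are axis-aligned; the physical position of voxel ``(i, j, k)`` is its
  *center*: ``origin + (i, j, k) * spacing``.
* Displacement vectors are stored with components in ``(z, y, x)`` order, mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates


@dataclass
class ImageVolume:
    """A 3D scalar raster with physical geometry.

    Parameters
    ----------
    voxels : (nz, ny, nx) ndarray
        Scalar samples (arbitrary intensity units for images, Gy for dose).
    spacing : (3,) float array
        Voxel size per array axis (z, y, x), mm; all > 0.
    origin : (3,) float array
        Physical position (mm) of the center of voxel (0, 0, 0).
    axes : str
        Orientation descriptor; only axis-aligned ``"zyx"`` grids are
        supported.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: str = "zyx"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.voxels.size == 0:
            raise ValueError("volume has no voxels")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ValueError(f"origin must have 3 components, got {self.origin}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def physical_points(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Physical (z, y, x) positions (mm) of voxel centers.

        ``indices`` is an (n, 3) integer array; ``None`` means every voxel
        (returned as an (nz, ny, nx, 3) array).
        """
        if indices is None:
            grids = np.meshgrid(
                *[np.arange(n) for n in self.shape], indexing="ij"
            )
            idx = np.stack(grids, axis=-1).astype(float)
            return self.origin + idx * self.spacing
        indices = np.asarray(indices, dtype=float)
        return self.origin + indices * self.spacing

    def continuous_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical (z, y, x) points to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def sample(
        self, points: np.ndarray, outside: float = 0.0, order: int = 1
    ) -> np.ndarray:
        """Trilinear sample at physical points; outside the grid -> ``outside``."""
        idx = self.continuous_index(points)
        return map_coordinates(
            self.voxels.astype(float, copy=False),
            idx.reshape(-1, 3).T,
            order=order,
            mode="constant",
            cval=outside,
        ).reshape(idx.shape[:-1])

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=voxels)

    # --- SimpleITK bridge (axis order reversed: sitk uses (x, y, z)) -------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels))
        img.SetSpacing(tuple(self.spacing[::-1]))
        img.SetOrigin(tuple(self.origin[::-1]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise ValueError("only axis-aligned (identity direction) grids are supported")
        return cls(
            voxels=sitk.GetArrayFromImage(img),
            spacing=np.asarray(img.GetSpacing())[::-1],
            origin=np.asarray(img.GetOrigin())[::-1],
        )


@dataclass
class DoseGrid(ImageVolume):
    """Full-course absorbed dose (Gy) on a raster grid; values >= 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.voxels < 0):
            raise ValueError("dose values must be non-negative")


@dataclass
class DeformationField:
    """Dense per-voxel displacement u (mm) on the planning grid.

    For a plan-grid position ``x`` the corresponding daily-anatomy position is
    ``x + u(x)`` (forward tissue displacement, plan -> daily).
    """

    displacements: np.ndarray  # (nz, ny, nx, 3), components (dz, dy, dx) mm
    spacing: np.ndarray
    origin: np.ndarray
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (nz, ny, nx, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        """Per-voxel |u| in mm."""
        return np.linalg.norm(self.displacements, axis=-1)

    def matches_grid(self, vol: ImageVolume, atol: float = 1e-6) -> bool:
        return (
            self.shape == vol.shape
            and np.allclose(self.spacing, vol.spacing, atol=atol)
            and np.allclose(self.origin, vol.origin, atol=atol)
        )

    @classmethod
    def zero_like(cls, vol: ImageVolume) -> "DeformationField":
        return cls(
            displacements=np.zeros(vol.shape + (3,)),
            spacing=vol.spacing.copy(),
            origin=vol.origin.copy(),
        )


def resample_to_grid(
    vol: ImageVolume, reference: ImageVolume, outside: float = 0.0, order: int = 1
) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``reference`` (trilinear by default)."""
    pts = reference.physical_points()
    values = vol.sample(pts, outside=outside, order=order)
    out = ImageVolume(
        voxels=values, spacing=reference.spacing.copy(), origin=reference.origin.copy()
    )
    return out


def resample_mask_to_grid(mask: ImageVolume, reference: ImageVolume) -> np.ndarray:
    """Resample a binary mask with trilinear interpolation + 0.5 threshold."""
    soft = resample_to_grid(
        mask.with_voxels(mask.voxels.astype(float)), reference, outside=0.0
    )
    return soft.voxels >= 0.5
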