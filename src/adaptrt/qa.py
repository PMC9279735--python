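"""Deformable-registration confidence metrics and review flags.

Two per-structure checks flag questionable deformations for review:

* normalized cross-correlation (NCC) below 0.85 between the daily image
  pulled back to plan anatomy by the recovered field and the plan image,
  evaluated over the structure region dilated by a configurable margin;
* any voxel of the structure displaced by more than 7 mm.

Both thresholds are configurable; the defaults follow common practice for
head-and-neck setup imagery (the displacement cut trades over-flagging below
~5 mm against missed errors above ~9 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import DeformationField, ImageVolume
from .registration import warp_image
from .rt_io import Structure

DEFAULT_THRESHOLDS = {"ncc": 0.85, "displacement_mm": 7.0}
DEFAULT_DILATION_MM = 5.0


@dataclass
class QAResult:
    structure: str
    ncc: float | None                 # in [-1, 1]; None when undefined
    max_displacement: float           # mm, max |u| within the structure
    flags: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def ncc_score(a: np.ndarray, b: np.ndarray) -> float | None:
    """Zero-mean normalized cross-correlation; None for zero-variance input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        return None
    return float(np.clip((da * db).sum() / denom, -1.0, 1.0))


def _dilate_mm(mask: np.ndarray, spacing: np.ndarray, radius_mm: float) -> np.ndarray:
    if radius_mm <= 0:
        return mask
    r = np.maximum(np.ceil(radius_mm / spacing).astype(int), 0)
    zz, yy, xx = np.ogrid[-r[0]:r[0] + 1, -r[1]:r[1] + 1, -r[2]:r[2] + 1]
    ball = (
        (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    ) <= radius_mm**2
    return ndimage.binary_dilation(mask, structure=ball)


def structure_qa(
    plan_image: ImageVolume,
    daily_image: ImageVolume,
    dvf: DeformationField,
    structure: Structure,
    thresholds: dict | None = None,
    dilation_mm: float = DEFAULT_DILATION_MM,
    realigned: ImageVolume | None = None,
) -> QAResult:
    """Compute DIR confidence metrics for one structure.

    ``daily_image`` must already live on the plan grid (as produced inside
    :func:`adaptrt.registration.register`; pass the resampled daily volume).
    ``realigned`` may supply the precomputed pull-back warp of the daily
    image to avoid re-warping per structure.  A zero-variance region makes
    the NCC undefined: the structure is flagged for review with reason
    ``ncc_undefined``.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if not structure.mask.any():
        raise ValueError(f"structure {structure.name!r} has an empty mask")
    if not dvf.matches_grid(plan_image):
        raise ValueError("deformation field is not on the plan grid")

    region = _dilate_mm(structure.mask, plan_image.spacing, dilation_mm)
    if realigned is None:
        realigned = warp_image(
            daily_image, dvf, background=float(daily_image.voxels.min())
        )
    ncc = ncc_score(plan_image.voxels[region], realigned.voxels[region])

    mags = dvf.magnitude()[structure.mask]
    max_disp = float(mags.max())

    flags = []
    if ncc is None:
        flags.append("ncc_undefined")
    elif ncc < th["ncc"]:
        flags.append("low_ncc")
    if max_disp > th["displacement_mm"]:
        flags.append("large_displacement")
    return QAResult(
        structure=structure.name, ncc=ncc, max_displacement=max_disp, flags=flags
    )
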