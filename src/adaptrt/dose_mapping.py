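"""Lagrangian per-structure dose estimation and cumulative projection.

Each structure is tracked as the fixed set of plan-grid tissue voxels; at
fraction ``f`` the voxel that sits at plan position ``x`` has moved to
``x + u_f(x)``, and — with the planned dose held fixed in room coordinates
(no dose recalculation) — the full-course-equivalent dose it is receiving is
``d̂_f(x) = D_plan(x + u_f(x))``.

The projected cumulative dose after fraction ``k`` of ``N`` delivers 1/N of
the full-course grid per fraction and assumes the latest anatomy holds for
the remainder of the course:

    D_sum,k(x) = (1/N) * Σ_{f<=k} d̂_f(x) + ((N−k)/N) * d̂_k(x)

so the day-of-treatment dose D_day,k = d̂_k and D_sum,N is the plain
per-fraction mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import DeformationField, DoseGrid
from .rt_io import Structure

log = logging.getLogger(__name__)

# fraction of structure voxels allowed to sample outside the dose grid
# before the structure is flagged unreliable for the fraction
OUT_OF_GRID_LIMIT = 0.10


@dataclass
class StructureDoseSamples:
    """Per-voxel full-course-equivalent dose for one structure, one fraction."""

    structure: str
    voxel_ids: np.ndarray          # (n, 3) plan-grid indices, fixed across fractions
    dose_full_course: np.ndarray   # (n,) Gy, d̂_f(x)
    voxel_volume: float            # cm^3
    out_of_grid: int = 0
    reliable: bool = True

    def __post_init__(self) -> None:
        if np.any(self.dose_full_course < 0):
            raise ValueError("dose samples must be non-negative")


@dataclass
class AccumulatedDose:
    """Day dose and projected cumulative dose after fraction k of N."""

    structure: str
    fraction: int                  # k, 1-based
    total_fractions: int           # N
    voxel_ids: np.ndarray
    day: np.ndarray                # D_day,k(x) Gy
    cumulative: np.ndarray         # D_sum,k(x) Gy
    voxel_volume: float


def warp_structure(mask: np.ndarray, dvf: DeformationField) -> np.ndarray:
    """Forward-map a plan-grid mask onto the daily grid.

    Every plan voxel splats its mask indicator trilinearly at its displaced
    position; the accumulated indicator mass is normalized by the total
    splatted mass (so volume contraction does not inflate occupancy) and
    thresholded at 0.5.  Used for display and for DIR-confidence regions;
    dose sampling itself never needs this (it pulls dose values instead).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dvf.shape:
        raise ValueError("mask and deformation field shapes differ")
    if not mask.any():
        log.warning("warp_structure called with an empty mask")
        return np.zeros(mask.shape, dtype=bool)
    shape = np.array(mask.shape)
    idx = np.indices(mask.shape).reshape(3, -1).T
    disp_vox = dvf.displacements.reshape(-1, 3) / dvf.spacing
    pos = idx + disp_vox
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    values = mask.ravel().astype(float)
    num = np.zeros(mask.shape, dtype=float)
    den = np.zeros(mask.shape, dtype=float)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                corner = lo + np.array([dz, dy, dx])
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                ok = np.all((corner >= 0) & (corner < shape), axis=1)
                tgt = tuple(corner[ok].T)
                np.add.at(num, tgt, (w * values)[ok])
                np.add.at(den, tgt, w[ok])
    with np.errstate(invalid="ignore"):
        occ = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
    return occ >= 0.5


def daily_dose(
    plan_dose: DoseGrid, dvf: DeformationField, structure: Structure
) -> StructureDoseSamples:
    """Sample the planned dose at each structure voxel's daily position."""
    if not dvf.matches_grid(plan_dose):
        raise ValueError("deformation field is not on the plan dose grid")
    if structure.mask.shape != plan_dose.shape:
        raise ValueError("structure mask is not on the plan grid")
    ids = np.argwhere(structure.mask)
    if len(ids) == 0:
        raise ValueError(f"structure {structure.name!r} has an empty mask")
    pts = plan_dose.physical_points(ids) + dvf.displacements[structure.mask]
    idx = plan_dose.continuous_index(pts)
    inside = np.all((idx >= 0) & (idx <= np.array(plan_dose.shape) - 1), axis=1)
    doses = plan_dose.sample(pts, outside=0.0)
    doses = np.maximum(doses, 0.0)
    n_out = int((~inside).sum())
    reliable = n_out <= OUT_OF_GRID_LIMIT * len(ids)
    if n_out:
        log.info(
            "%s: %d/%d voxels sampled outside the dose grid%s",
            structure.name, n_out, len(ids), "" if reliable else " (flagged unreliable)",
        )
    return StructureDoseSamples(
        structure=structure.name,
        voxel_ids=ids,
        dose_full_course=doses,
        voxel_volume=plan_dose.voxel_volume_cc,
        out_of_grid=n_out,
        reliable=reliable,
    )


def accumulate(
    samples_by_fraction: list[StructureDoseSamples], total_fractions: int
) -> AccumulatedDose:
    """Combine fractions 1..k into day and projected-cumulative dose."""
    if not samples_by_fraction:
        raise ValueError("need at least one fraction of samples")
    k = len(samples_by_fraction)
    n = total_fractions
    first = samples_by_fraction[0]
    for s in samples_by_fraction[1:]:
        if s.structure != first.structure or not np.array_equal(
            s.voxel_ids, first.voxel_ids
        ):
            raise ValueError("samples do not share voxel identity across fractions")
    stack = np.stack([s.dose_full_course for s in samples_by_fraction])
    latest = stack[-1]
    cumulative = stack.sum(axis=0) / n + (n - k) / n * latest
    return AccumulatedDose(
        structure=first.structure,
        fraction=k,
        total_fractions=n,
        voxel_ids=first.voxel_ids,
        day=latest.copy(),
        cumulative=cumulative,
        voxel_volume=first.voxel_volume,
    )
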