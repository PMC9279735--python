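"""Intensity-based deformable registration of plan anatomy to daily anatomy.

The engine is a multi-resolution optical-flow scheme of the demons family:
at each level of a Gaussian pyramid an intensity-difference (brightness
constancy) force drives a dense displacement field that is regularized by
Gaussian smoothing, coarse-to-fine with field upsampling between levels.
The daily volume is intensity-normalized against the plan volume first
(histogram matching by default) because cone-beam intensities are not
calibrated HU and the flow force assumes comparable brightness.

The recovered field ``u`` lives on the planning grid and is the *forward*
tissue displacement: the tissue element at plan position ``x`` sits at
``x + u(x)`` in the daily anatomy, i.e. ``daily(x + u(x)) ~= plan(x)``.
This makes Lagrangian dose sampling direct (no field inversion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .geometry import DeformationField, ImageVolume, resample_to_grid

log = logging.getLogger(__name__)

NORMALIZATIONS = ("histogram_match", "z_score", "none")


@dataclass
class RegistrationParams:
    """Knobs of the deformable registration.

    pyramid_levels
        Number of resolution levels (>= 1); level ``l`` shrinks by ``2**l``.
    iterations_per_level
        Iteration cap at each level.
    smoothness_weight
        Standard deviation (in voxels) of the Gaussian regularization of the
        displacement field; larger = smoother, stiffer deformation.
    intensity_normalization
        One of ``histogram_match``, ``z_score``, ``none``.
    convergence_tol
        Stop a level early when the RMS field update falls below this (mm).
    """

    pyramid_levels: int = 3
    iterations_per_level: int = 100
    smoothness_weight: float = 1.8
    intensity_normalization: str = "histogram_match"
    convergence_tol: float = 0.02
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.smoothness_weight <= 0:
            raise ValueError("smoothness_weight must be > 0")
        if self.intensity_normalization not in NORMALIZATIONS:
            raise ValueError(
                f"intensity_normalization must be one of {NORMALIZATIONS}"
            )


def _normalize(daily: sitk.Image, plan: sitk.Image, how: str) -> sitk.Image:
    if how == "none":
        return daily
    if how == "histogram_match":
        f = sitk.HistogramMatchingImageFilter()
        f.SetNumberOfHistogramLevels(256)
        f.SetNumberOfMatchPoints(12)
        f.ThresholdAtMeanIntensityOn()
        return f.Execute(daily, plan)
    stats = sitk.StatisticsImageFilter()
    stats.Execute(daily)
    dm, ds = stats.GetMean(), max(stats.GetSigma(), 1e-9)
    stats.Execute(plan)
    pm, ps = stats.GetMean(), max(stats.GetSigma(), 1e-9)
    return (daily - dm) / ds * ps + pm


def _overlap_fraction(a: ImageVolume, b: ImageVolume) -> float:
    lo = np.maximum(a.origin, b.origin)
    hi = np.minimum(
        a.origin + (np.array(a.shape) - 1) * a.spacing,
        b.origin + (np.array(b.shape) - 1) * b.spacing,
    )
    ext = np.maximum(hi - lo, 0.0)
    own = (np.array(a.shape) - 1) * a.spacing
    return float(np.prod(ext / np.maximum(own, 1e-9)))


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(
        img, [0.5 * factor * s for s in img.GetSpacing()]
    )
    return sitk.Shrink(smoothed, [factor] * 3)


def register(
    plan_image: ImageVolume,
    daily_image: ImageVolume,
    params: RegistrationParams | None = None,
) -> DeformationField:
    """Estimate the dense plan->daily deformation field.

    The daily volume is resampled onto the planning grid (single-grid math),
    intensity-normalized, and registered coarse-to-fine.  Deterministic given
    inputs and parameters.  Raises if the volumes share no physical overlap;
    non-convergence at the iteration cap returns the field with
    ``converged=False`` and a logged warning.
    """
    params = params or RegistrationParams()
    if _overlap_fraction(plan_image, daily_image) <= 0.0:
        raise ValueError("plan and daily volumes have no physical overlap")

    fixed = sitk.Cast(plan_image.to_sitk(), sitk.sitkFloat32)
    daily_on_plan = resample_to_grid(
        daily_image, plan_image, outside=float(daily_image.voxels.min())
    )
    moving = sitk.Cast(daily_on_plan.to_sitk(), sitk.sitkFloat32)
    moving = _normalize(moving, fixed, params.intensity_normalization)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(int(params.iterations_per_level))
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(float(params.smoothness_weight))
    demons.SetMaximumRMSError(float(params.convergence_tol))

    levels = list(range(params.pyramid_levels - 1, -1, -1))  # coarse -> fine
    dvf_img: sitk.Image | None = None
    converged = True
    for level in levels:
        factor = 2**level
        f_l = _shrink(fixed, factor)
        m_l = _shrink(moving, factor)
        if dvf_img is not None:
            dvf_img = sitk.Resample(
                dvf_img, f_l, sitk.Transform(), sitk.sitkLinear, 0.0,
                sitk.sitkVectorFloat64,
            )
            dvf_img = demons.Execute(f_l, m_l, dvf_img)
        else:
            dvf_img = demons.Execute(f_l, m_l)
        rms = demons.GetRMSChange()
        iters = demons.GetElapsedIterations()
        log.debug("level %d: %d iterations, RMS change %.4f", level, iters, rms)
        # With per-iteration Gaussian regularization the update RMS never
        # reaches zero on noisy data; treat a sub-half-voxel residual update
        # at the finest level as stationary.
        stationary = max(params.convergence_tol, 0.5 * float(min(plan_image.spacing)))
        if level == 0 and rms > stationary and iters >= params.iterations_per_level:
            converged = False
            log.warning(
                "registration hit the iteration cap with RMS update %.3f mm "
                "(> %.3f mm): field may not be stationary", rms, stationary,
            )

    assert dvf_img is not None
    if dvf_img.GetSize() != fixed.GetSize():
        dvf_img = sitk.Resample(
            dvf_img, fixed, sitk.Transform(), sitk.sitkLinear, 0.0,
            sitk.sitkVectorFloat64,
        )
    # sitk vector components are (x, y, z); flip to array order (z, y, x)
    disp = sitk.GetArrayFromImage(dvf_img)[..., ::-1]
    return DeformationField(
        displacements=disp,
        spacing=plan_image.spacing.copy(),
        origin=plan_image.origin.copy(),
        converged=converged,
        meta={"params": params},
    )


def warp_image(
    moving: ImageVolume, dvf: DeformationField, background: float = 0.0
) -> ImageVolume:
    """Pull-back warp: ``output(x) = moving(x + u(x))``, trilinear.

    With the plan->daily field from :func:`register`, warping the *daily*
    image yields it re-aligned to the plan anatomy.  Out-of-field samples
    take ``background``.
    """
    if not dvf.matches_grid(moving):
        raise ValueError("deformation field geometry does not match the moving volume")
    pts = moving.physical_points() + dvf.displacements
    return moving.with_voxels(moving.sample(pts, outside=background))
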