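"""Synthetic head-and-neck phantom courses with exact ground truth.

The phantom is defined *analytically*: anatomy (body ellipsoid, SIB target
spheres, parotid ellipsoids, cord cylinder, mandible arc), a smooth
soft-tissue texture, and a Gaussian-falloff dose model are all closed-form
functions of physical position.  Daily anatomy is produced by composing a
per-fraction smooth drift field (parotid medial shift, target shrinkage,
body-contour shrinkage) with a random rigid setup error; because the plan
intensity function is analytic, the daily image is evaluated *exactly* at
the inverse-mapped positions (no interpolation error), and the ground-truth
deformation field is known in the same convention as the registration module
(forward tissue displacement, plan grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DeformationField, DoseGrid, ImageVolume
from .rt_io import PlanContext, Structure


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry, intensity and dose model of the synthetic plan.

    Lengths in mm, physical axes in array order (z, y, x) with the grid
    centered on the origin.  The dose model assigns each target a plateau at
    its SIB prescription with a Gaussian falloff of scale ``dose_falloff_mm``
    outside; structures take the maximum over targets, which produces the
    steep lateral gradient at the parotids.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    total_fractions: int = 35
    prescriptions: dict = field(default_factory=lambda: {"PTV70": 70.0, "PTV63": 63.0})
    target_radii: dict = field(default_factory=lambda: {"PTV70": 14.0, "PTV63": 24.0})
    dose_falloff_mm: float = 40.0
    body_semiaxes: tuple[float, float, float] = (58.0, 80.0, 85.0)
    parotid_semiaxes: tuple[float, float, float] = (18.0, 12.0, 10.0)
    parotid_center_x: float = 67.0
    cord_y: float = 60.0
    cord_radius: float = 5.0
    mandible_center: tuple[float, float] = (14.0, -26.0)  # (z, y) of arc plane
    mandible_major_r: float = 30.0
    mandible_minor_r: float = 6.0
    edge_width_mm: float = 1.5
    n_texture_blobs: int = 12
    texture_amplitude: float = 30.0

    @property
    def origin(self) -> np.ndarray:
        return -(np.array(self.shape) - 1) * np.array(self.spacing) / 2.0


@dataclass
class CourseTruth:
    """Ground-truth generative parameters of a simulated treatment course.

    ``parotid_drift_mm_per_fraction`` moves both parotids medially (toward
    the dose plateau) by that amount per fraction; shrink rates are
    fractional contractions per fraction about the target / body centers;
    rigid setup errors are drawn per fraction from ``seed``.  After
    :func:`simulate_course` the per-fraction rigid errors and DVFs are
    recorded on the instance.
    """

    n_fractions: int = 16
    parotid_drift_mm_per_fraction: float = 0.5
    target_shrink_per_fraction: float = 0.004
    body_shrink_per_fraction: float = 0.0015
    setup_sigma_mm: float = 1.5
    rotation_sigma_deg: float = 0.5
    noise_sigma: float = 5.0
    n_streaks: int = 0
    seed: int = 0
    # filled by simulate_course:
    setup_translations: np.ndarray | None = None   # (F, 3) mm, (z, y, x)
    setup_rotations_deg: np.ndarray | None = None  # (F,) about z


# ---------------------------------------------------------------------------
# Analytic anatomy / dose model
# ---------------------------------------------------------------------------

class _Model:
    """Closed-form intensity and dose as functions of (…, 3) point arrays."""

    def __init__(self, cfg: PhantomConfig, seed: int):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        body = np.array(cfg.body_semiaxes)
        self.tex_centers = rng.uniform(-0.6, 0.6, size=(cfg.n_texture_blobs, 3)) * body
        self.tex_amp = rng.uniform(
            -cfg.texture_amplitude, cfg.texture_amplitude, cfg.n_texture_blobs
        )
        self.tex_sigma = rng.uniform(10.0, 18.0, cfg.n_texture_blobs)
        self.parotid_centers = {
            "parotid_L": np.array([0.0, 0.0, +cfg.parotid_center_x]),
            "parotid_R": np.array([0.0, 0.0, -cfg.parotid_center_x]),
        }

    # -- signed distances (negative inside), mm-scaled ---------------------
    def _sd_ellipsoid(self, p, center, semiaxes):
        r = np.linalg.norm((p - center) / np.asarray(semiaxes), axis=-1)
        return (r - 1.0) * float(np.mean(semiaxes))

    def _sd_sphere(self, p, center, radius):
        return np.linalg.norm(p - center, axis=-1) - radius

    def sd_body(self, p):
        return self._sd_ellipsoid(p, np.zeros(3), self.cfg.body_semiaxes)

    def sd_target(self, p, name):
        return self._sd_sphere(p, np.zeros(3), self.cfg.target_radii[name])

    def sd_parotid(self, p, side):
        return self._sd_ellipsoid(
            p, self.parotid_centers[side], self.cfg.parotid_semiaxes
        )

    def sd_cord(self, p):
        c = self.cfg
        rho = np.sqrt((p[..., 1] - c.cord_y) ** 2 + p[..., 2] ** 2)
        radial = rho - c.cord_radius
        # keep the cylinder inside the body ellipsoid at its posterior offset
        z_half = 0.9 * c.body_semiaxes[0] * np.sqrt(
            max(1.0 - (c.cord_y / c.body_semiaxes[1]) ** 2, 0.0)
        )
        axial = np.abs(p[..., 0]) - z_half
        return np.maximum(radial, axial)

    def sd_mandible(self, p):
        c = self.cfg
        zc, yc = c.mandible_center
        rho = np.sqrt((p[..., 1] - yc) ** 2 + p[..., 2] ** 2)
        d_ring = np.sqrt((rho - c.mandible_major_r) ** 2 + (p[..., 0] - zc) ** 2)
        sd = d_ring - c.mandible_minor_r
        return np.where(p[..., 1] <= yc + 1e-9, sd, sd + (p[..., 1] - yc))

    def _occ(self, sd):
        return 1.0 / (1.0 + np.exp(np.clip(sd / self.cfg.edge_width_mm, -60, 60)))

    def intensity(self, p: np.ndarray) -> np.ndarray:
        """HU-like plan intensity at physical points ``p`` (..., 3)."""
        tex = np.zeros(p.shape[:-1])
        for c, a, s in zip(self.tex_centers, self.tex_amp, self.tex_sigma):
            d2 = np.sum((p - c) ** 2, axis=-1)
            tex += a * np.exp(-d2 / (2 * s * s))
        body = self._occ(self.sd_body(p))
        out = -1000.0 + body * (1040.0 + tex)
        out += 40.0 * self._occ(self.sd_parotid(p, "parotid_L"))
        out += 40.0 * self._occ(self.sd_parotid(p, "parotid_R"))
        out += 80.0 * self._occ(self.sd_target(p, "PTV70"))
        out += 30.0 * self._occ(self.sd_target(p, "PTV63"))
        out -= 20.0 * self._occ(self.sd_cord(p))
        out += 660.0 * self._occ(self.sd_mandible(p))
        return out

    def dose(self, p: np.ndarray) -> np.ndarray:
        """Full-course dose (Gy): max over per-target Gaussian-falloff plateaus."""
        sigma = self.cfg.dose_falloff_mm
        d = np.zeros(p.shape[:-1])
        for name, rx in self.cfg.prescriptions.items():
            dist = np.maximum(self.sd_target(p, name), 0.0)
            d = np.maximum(d, rx * np.exp(-((dist / sigma) ** 2)))
        return d


# ---------------------------------------------------------------------------
# Plan generation
# ---------------------------------------------------------------------------

def make_plan_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> tuple[ImageVolume, PlanContext, DoseGrid]:
    """Build a deterministic synthetic planning bundle.

    The returned plan satisfies its own constraints (every target V95 = 100%
    on the dose plateau; spared-parotid planned Dmean < 20 Gy); violations
    indicate an infeasible configuration and raise.
    """
    cfg = config or PhantomConfig()
    model = _Model(cfg, seed)
    grid = ImageVolume(
        voxels=np.zeros(cfg.shape, dtype=np.float32),
        spacing=np.array(cfg.spacing),
        origin=cfg.origin,
    )
    pts = grid.physical_points()
    image = ImageVolume(
        model.intensity(pts).astype(np.float32), grid.spacing.copy(), grid.origin.copy()
    )
    dose = DoseGrid(model.dose(pts), grid.spacing.copy(), grid.origin.copy())

    structures = [Structure("body", "external", model.sd_body(pts) < 0)]
    for name, rx in cfg.prescriptions.items():
        structures.append(
            Structure(name, "target", model.sd_target(pts, name) < 0, prescription=rx)
        )
    for side in ("parotid_L", "parotid_R"):
        structures.append(Structure(side, "oar", model.sd_parotid(pts, side) < 0))
    structures.append(Structure("spinal_cord", "oar", model.sd_cord(pts) < 0))
    structures.append(Structure("mandible", "oar", model.sd_mandible(pts) < 0))

    for s in structures:
        if s.voxel_count == 0:
            raise ValueError(f"phantom structure {s.name!r} is empty: infeasible geometry")
    names = [s.name for s in structures]
    if len(set(names)) != len(names):
        raise ValueError("duplicate structure names: infeasible configuration")

    plan = PlanContext(total_fractions=cfg.total_fractions, structures=structures)

    # plan-validity checks on the analytic dose
    for name, rx in cfg.prescriptions.items():
        tdose = dose.voxels[plan.structure(name).mask]
        v95 = 100.0 * np.mean(tdose >= 0.95 * rx)
        if v95 <= 95.0:
            raise ValueError(f"planned {name} V95 = {v95:.1f}% <= 95%: infeasible plan")
    for side in ("parotid_L", "parotid_R"):
        dmean = float(dose.voxels[plan.structure(side).mask].mean())
        if dmean >= 20.0:
            raise ValueError(
                f"planned {side} Dmean = {dmean:.2f} Gy >= 20 Gy: infeasible plan"
            )
    return image, plan, dose


# ---------------------------------------------------------------------------
# Course simulation
# ---------------------------------------------------------------------------

class CourseSimulator:
    """Evaluate the per-fraction forward drift+setup field and daily images."""

    def __init__(self, cfg: PhantomConfig, truth: CourseTruth, model_seed: int = 0):
        self.cfg = cfg
        self.truth = truth
        self.model = _Model(cfg, model_seed)
        rng = np.random.default_rng(truth.seed)
        f = truth.n_fractions
        truth.setup_translations = rng.normal(0.0, truth.setup_sigma_mm, size=(f, 3))
        truth.setup_rotations_deg = rng.normal(0.0, truth.rotation_sigma_deg, size=f)
        self._noise_rng_seed = rng.integers(0, 2**31 - 1)

    # window ~1 inside a region, smooth Gaussian decay outside it
    @staticmethod
    def _window(scaled_excess: np.ndarray, decay: float = 0.5) -> np.ndarray:
        e = np.maximum(scaled_excess, 0.0)
        return np.exp(-((e / decay) ** 2))

    def forward_displacement(self, p: np.ndarray, fraction: int) -> np.ndarray:
        """Ground-truth tissue displacement u_f at points ``p`` (mm)."""
        t = self.truth
        cfg = self.cfg
        u = np.zeros_like(p, dtype=float)

        # parotid medial drift (toward x = 0), windowed around each parotid
        shift = t.parotid_drift_mm_per_fraction * fraction
        if shift != 0.0:
            pad = np.array(cfg.parotid_semiaxes) + 12.0
            for side, c in self.model.parotid_centers.items():
                r = np.linalg.norm((p - c) / pad, axis=-1)
                w = self._window(r - 1.0)
                direction = -np.sign(c[2])
                u[..., 2] += direction * shift * w

        # target shrinkage: contraction about the target center
        s = t.target_shrink_per_fraction * fraction
        if s != 0.0:
            r_t = max(cfg.target_radii.values()) + 10.0
            r = np.linalg.norm(p / r_t, axis=-1)
            w = self._window(r - 1.0)
            u += -s * p * w[..., None]

        # body-contour shrinkage about the body center
        b = t.body_shrink_per_fraction * fraction
        if b != 0.0:
            r = np.linalg.norm(p / np.array(cfg.body_semiaxes), axis=-1)
            w = self._window(r - 1.0)
            u += -b * p * w[..., None]

        # rigid setup error (translation + small in-plane rotation)
        assert t.setup_translations is not None
        trans = t.setup_translations[fraction - 1]
        ang = np.deg2rad(t.setup_rotations_deg[fraction - 1])
        if ang != 0.0:
            ca, sa = np.cos(ang), np.sin(ang)
            y, x = p[..., 1], p[..., 2]
            u[..., 1] += (ca * y - sa * x) - y
            u[..., 2] += (sa * y + ca * x) - x
        u += trans
        return u

    def _invert_forward(self, grid_pts: np.ndarray, fraction: int) -> np.ndarray:
        """Solve y = x - u_f(y) by fixed-point iteration (smooth small fields)."""
        y = grid_pts - self.forward_displacement(grid_pts, fraction)
        for _ in range(12):
            y = grid_pts - self.forward_displacement(y, fraction)
        return y

    def daily_volume(self, grid: ImageVolume, fraction: int) -> ImageVolume:
        pts = grid.physical_points()
        pulled = self._invert_forward(pts, fraction)
        vox = self.model.intensity(pulled)
        t = self.truth
        if t.noise_sigma > 0 or t.n_streaks > 0:
            rng = np.random.default_rng(self._noise_rng_seed + fraction)
            if t.noise_sigma > 0:
                vox = vox + rng.normal(0.0, t.noise_sigma, size=vox.shape)
            for _ in range(t.n_streaks):
                vox = _add_streak(vox, rng)
        return ImageVolume(vox.astype(np.float32), grid.spacing.copy(), grid.origin.copy())

    def truth_dvf(self, grid: ImageVolume, fraction: int) -> DeformationField:
        pts = grid.physical_points()
        return DeformationField(
            displacements=self.forward_displacement(pts, fraction),
            spacing=grid.spacing.copy(),
            origin=grid.origin.copy(),
        )


def _add_streak(vox: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Paint one bright random chord across a random axial slice."""
    nz, ny, nx = vox.shape
    i = rng.integers(0, nz)
    j0, j1 = rng.integers(0, ny, 2)
    k0, k1 = rng.integers(0, nx, 2)
    n = max(ny, nx) * 2
    jj = np.clip(np.linspace(j0, j1, n).round().astype(int), 0, ny - 1)
    kk = np.clip(np.linspace(k0, k1, n).round().astype(int), 0, nx - 1)
    vox[i, jj, kk] += rng.uniform(200.0, 500.0)
    return vox


def simulate_course(
    plan_image: ImageVolume,
    truth: CourseTruth,
    config: PhantomConfig | None = None,
    model_seed: int = 0,
) -> tuple[list[ImageVolume], list[DeformationField]]:
    """Generate daily setup volumes and ground-truth DVFs for a course.

    The ground-truth fields are returned in the registration convention
    (forward tissue displacement on the plan grid).  Raises if the drift
    would push a parotid center outside the grid.
    """
    cfg = config or PhantomConfig()
    sim = CourseSimulator(cfg, truth, model_seed)
    half_extent = cfg.origin + (np.array(cfg.shape) - 1) * np.array(cfg.spacing)
    for f in range(1, truth.n_fractions + 1):
        drift = truth.parotid_drift_mm_per_fraction * f
        if cfg.parotid_center_x - abs(drift) < 0 or abs(drift) > half_extent[2]:
            raise ValueError(f"drift pushes parotid outside the grid at fraction {f}")
    dailies, dvfs = [], []
    for f in range(1, truth.n_fractions + 1):
        dailies.append(sim.daily_volume(plan_image, f))
        dvfs.append(sim.truth_dvf(plan_image, f))
    return dailies, dvfs
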