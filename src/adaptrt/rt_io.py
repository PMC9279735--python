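"""Planning-bundle and daily-volume I/O in two dialects.

``fixture``
    A portable desk-scale format: NRRD raster volumes plus a single
    ``plan.json`` sidecar holding the plan context (fraction count, SIB
    prescriptions, structure roles).  Write -> read round-trips are value- and
    geometry-exact.

``dicom``
    DICOM-RT objects: a CT image series, an RT Structure Set (contour
    sequences, rasterized to masks on the planning grid) and an RT Dose
    (``DoseGridScaling`` honored, resampled trilinearly onto the planning
    grid).  Only axis-aligned axial geometry is supported.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import Dataset, FileDataset
from pydicom.uid import generate_uid

from .geometry import DoseGrid, ImageVolume, resample_mask_to_grid, resample_to_grid

log = logging.getLogger(__name__)

ROLES = ("target", "oar", "external", "other")


@dataclass
class Structure:
    """A named region of interest as a binary raster on a reference grid."""

    name: str
    role: str
    mask: np.ndarray
    prescription: float | None = None  # Gy, SIB level; targets only

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.mask = np.asarray(self.mask).astype(bool)
        if self.role == "target":
            if self.prescription is None or self.prescription <= 0:
                raise ValueError(f"target {self.name!r} needs a positive prescription")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class PlanContext:
    """Course-level plan data: fraction count, prescriptions, structures."""

    total_fractions: int
    structures: list[Structure] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_fractions < 1:
            raise ValueError("total_fractions must be >= 1")

    @property
    def prescriptions(self) -> dict[str, float]:
        return {
            s.name: float(s.prescription)
            for s in self.structures
            if s.role == "target" and s.prescription
        }

    @property
    def max_prescription(self) -> float:
        rx = self.prescriptions
        if not rx:
            raise ValueError("plan has no target prescriptions")
        return max(rx.values())

    @property
    def dose_per_fraction(self) -> float:
        """Highest SIB level divided by N (the 2 Gy/fraction pattern)."""
        return self.max_prescription / self.total_fractions

    def structure(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"structure {name!r} not in plan")


# ---------------------------------------------------------------------------
# Contour rasterization
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized crossing-number (even-odd) point-in-polygon test.

    A point on a left/bottom edge counts as inside, on a right/top edge as
    outside (half-open semantics), which makes voxel counts unambiguous when
    polygon edges pass exactly through voxel-center lines.
    """
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses = (ey1 > py) != (ey2 > py)
        with np.errstate(invalid="ignore"):
            xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_contours(
    contours: list[tuple[float, np.ndarray]], grid: ImageVolume
) -> np.ndarray:
    """Rasterize per-slice closed polygons to a binary mask on ``grid``.

    Parameters
    ----------
    contours
        List of ``(z_mm, polygon)`` pairs; each polygon is an (n, 2) array of
        (x, y) vertices in mm describing a closed planar contour.  Multiple
        polygons on one slice combine with the even-odd rule (holes subtract).
    grid
        Defines the raster geometry; a voxel is inside iff its *center* is
        inside the polygon.

    Slices are matched to the nearest grid plane; contours farther than half
    a slice spacing from any plane are skipped with a warning.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    nz = grid.shape[0]
    ys = grid.origin[1] + np.arange(grid.shape[1]) * grid.spacing[1]
    xs = grid.origin[2] + np.arange(grid.shape[2]) * grid.spacing[2]
    px, py = np.meshgrid(xs, ys)  # (ny, nx)
    for z_mm, poly in contours:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("each contour must be an (n>=3, 2) polygon")
        fidx = (z_mm - grid.origin[0]) / grid.spacing[0]
        i = int(round(fidx))
        if i < 0 or i >= nz or abs(fidx - i) > 0.5 + 1e-9:
            warnings.warn(
                f"contour at z={z_mm} mm is farther than half a slice spacing "
                "from any grid plane; skipped"
            )
            continue
        mask[i] ^= _points_in_polygon(px, py, poly)
    return mask


# ---------------------------------------------------------------------------
# Fixture dialect
# ---------------------------------------------------------------------------

def _write_nrrd(vol: ImageVolume, path: Path) -> None:
    sitk.WriteImage(vol.to_sitk(), str(path))


def _read_nrrd(path: Path) -> ImageVolume:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return ImageVolume.from_sitk(sitk.ReadImage(str(path)))


def write_plan_bundle(
    out_dir: str | Path,
    plan_image: ImageVolume,
    plan: PlanContext,
    dose: DoseGrid,
) -> Path:
    """Write a fixture-dialect planning bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_nrrd(plan_image.with_voxels(plan_image.voxels.astype(np.float32)), out / "image.nrrd")
    _write_nrrd(
        ImageVolume(dose.voxels.astype(np.float32), dose.spacing, dose.origin),
        out / "dose.nrrd",
    )
    meta = {"total_fractions": plan.total_fractions, "structures": []}
    for s in plan.structures:
        fname = f"mask_{s.name}.nrrd"
        _write_nrrd(
            ImageVolume(s.mask.astype(np.uint8), plan_image.spacing, plan_image.origin),
            out / fname,
        )
        meta["structures"].append(
            {"name": s.name, "role": s.role, "prescription": s.prescription, "mask": fname}
        )
    (out / "plan.json").write_text(json.dumps(meta, indent=2))
    return out


def write_daily_volume(path: str | Path, vol: ImageVolume) -> None:
    _write_nrrd(vol.with_voxels(vol.voxels.astype(np.float32)), Path(path))


def _read_fixture_bundle(bundle_dir: Path):
    meta_path = bundle_dir / "plan.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing plan.json in {bundle_dir}")
    meta = json.loads(meta_path.read_text())
    if "total_fractions" not in meta:
        raise ValueError("plan.json is missing required field 'total_fractions'")
    image = _read_nrrd(bundle_dir / "image.nrrd")
    dose_vol = _read_nrrd(bundle_dir / "dose.nrrd")
    structures = []
    for s in meta.get("structures", []):
        mvol = _read_nrrd(bundle_dir / s["mask"])
        if not mvol.same_grid(image):
            mask = resample_mask_to_grid(mvol, image)
        else:
            mask = mvol.voxels.astype(bool)
        structures.append(
            Structure(
                name=s["name"], role=s["role"], mask=mask, prescription=s.get("prescription")
            )
        )
    if not dose_vol.same_grid(image):
        mean_before = float(dose_vol.voxels.mean())
        dose_vol = resample_to_grid(dose_vol, image)
        log.info(
            "dose grid resampled onto planning grid (mean %.3f -> %.3f Gy)",
            mean_before,
            float(dose_vol.voxels.mean()),
        )
    dose = DoseGrid(dose_vol.voxels, dose_vol.spacing, dose_vol.origin)
    plan = PlanContext(total_fractions=int(meta["total_fractions"]), structures=structures)
    return image, plan, dose


# ---------------------------------------------------------------------------
# DICOM dialect
# ---------------------------------------------------------------------------

def _require(ds: Dataset, tag_name: str):
    if tag_name not in ds:
        raise ValueError(f"DICOM object is missing required field {tag_name}")
    return getattr(ds, tag_name)


def _read_ct_series(ct_dir: Path) -> ImageVolume:
    files = sorted(p for p in ct_dir.iterdir() if p.suffix.lower() == ".dcm")
    slices = []
    for p in files:
        ds = pydicom.dcmread(str(p))
        if getattr(ds, "Modality", "") == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {ct_dir}")
    for ds in slices:
        _require(ds, "ImagePositionPatient")
        _require(ds, "PixelSpacing")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    if len(slices) < 2:
        raise ValueError("a 3D CT series requires at least 2 slices")
    zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    dz = np.diff(zs)
    if np.ptp(dz) > 0.01:
        raise ValueError(f"non-uniform slice spacing (range {dz.min():.3f}-{dz.max():.3f} mm)")
    first = slices[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    arr = np.stack(
        [d.pixel_array * float(getattr(d, "RescaleSlope", 1.0))
         + float(getattr(d, "RescaleIntercept", 0.0)) for d in slices]
    )
    origin = np.array(
        [zs[0], float(first.ImagePositionPatient[1]), float(first.ImagePositionPatient[0])]
    )
    return ImageVolume(arr.astype(np.float32), np.array([dz[0], row_sp, col_sp]), origin)


def _read_rtdose(path: Path) -> DoseGrid:
    ds = pydicom.dcmread(str(path))
    scaling = float(_require(ds, "DoseGridScaling"))
    _require(ds, "ImagePositionPatient")
    _require(ds, "PixelSpacing")
    offsets = np.array([float(v) for v in _require(ds, "GridFrameOffsetVector")])
    dz = np.diff(offsets)
    if len(dz) and np.ptp(dz) > 0.01:
        raise ValueError("non-uniform dose grid frame offsets")
    arr = ds.pixel_array.astype(np.float64) * scaling
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    ipp = ds.ImagePositionPatient
    origin = np.array([float(ipp[2]) + offsets[0], float(ipp[1]), float(ipp[0])])
    spacing = np.array([dz[0] if len(dz) else 1.0, row_sp, col_sp])
    return DoseGrid(arr, spacing, origin)


def _read_rtstruct(path: Path, grid: ImageVolume, roles: dict) -> list[Structure]:
    ds = pydicom.dcmread(str(path))
    names = {}
    for roi in _require(ds, "StructureSetROISequence"):
        names[int(roi.ROINumber)] = str(roi.ROIName)
    structures = []
    for rc in _require(ds, "ROIContourSequence"):
        name = names[int(rc.ReferencedROINumber)]
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.array([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours.append((float(pts[0, 2]), pts[:, :2]))  # (z, (x, y) polygon)
        mask = rasterize_contours(contours, grid)
        cfg = roles.get(name, {})
        structures.append(
            Structure(
                name=name,
                role=cfg.get("role", "other"),
                mask=mask,
                prescription=cfg.get("prescription"),
            )
        )
    return structures


def _read_dicom_bundle(bundle_dir: Path, structure_roles: dict | None):
    image = _read_ct_series(bundle_dir)
    dose_paths = sorted(bundle_dir.glob("RD*.dcm")) or [bundle_dir / "rtdose.dcm"]
    struct_paths = sorted(bundle_dir.glob("RS*.dcm")) or [bundle_dir / "rtstruct.dcm"]
    dose = _read_rtdose(dose_paths[0])
    roles = structure_roles or {}
    structures = _read_rtstruct(struct_paths[0], image, roles)
    if not dose.same_grid(image):
        dose_res = resample_to_grid(dose, image)
        dose = DoseGrid(dose_res.voxels, dose_res.spacing, dose_res.origin)
    n = roles.get("__total_fractions__")
    if n is None:
        raise ValueError("DICOM dialect requires 'total_fractions' in the structure config")
    plan = PlanContext(total_fractions=int(n), structures=structures)
    return image, plan, dose


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def read_plan_bundle(
    paths: str | Path,
    dialect: str = "fixture",
    structure_roles: dict | None = None,
    required_structures: list[str] | None = None,
):
    """Read a planning bundle: (plan image, plan context, dose on plan grid).

    ``paths`` is the bundle directory.  The dose grid and any off-grid masks
    are resampled onto the planning image grid (dose trilinear, masks by 0.5
    threshold).  ``required_structures`` (e.g. the names referenced by the
    endpoint config) must all be present, else a hard error is raised.
    """
    bundle_dir = Path(paths)
    if not bundle_dir.exists():
        raise FileNotFoundError(bundle_dir)
    if dialect == "fixture":
        image, plan, dose = _read_fixture_bundle(bundle_dir)
    elif dialect == "dicom":
        image, plan, dose = _read_dicom_bundle(bundle_dir, structure_roles)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if required_structures:
        have = {s.name for s in plan.structures}
        missing = [n for n in required_structures if n not in have]
        if missing:
            raise ValueError(f"structures referenced by config but absent from plan: {missing}")
    return image, plan, dose


def read_daily_volume(path: str | Path, dialect: str = "fixture") -> ImageVolume:
    """Read one daily setup volume in physical coordinates (not resampled)."""
    p = Path(path)
    if dialect == "fixture":
        vol = _read_nrrd(p)
    elif dialect == "dicom":
        vol = _read_ct_series(p)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if vol.shape[0] < 2:
        raise ValueError("daily volume must be 3D (>= 2 slices)")
    return vol


# ---------------------------------------------------------------------------
# Minimal DICOM writer (valid uncompressed axial objects; used for testing
# the DICOM reading path and for exporting desk-scale bundles)
# ---------------------------------------------------------------------------

def _base_ds(path: Path, sop_class: str) -> FileDataset:
    meta = pydicom.dataset.FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "PHANTOM"
    return ds


def write_dicom_bundle(
    out_dir: str | Path,
    plan_image: ImageVolume,
    plan: PlanContext,
    dose: DoseGrid,
) -> Path:
    """Write a minimal DICOM-RT bundle (CT series, RT Dose, RT Structure Set).

    Structure masks are exported as per-slice rectangular-boundary contours of
    their connected voxel rows; intended for round-trip testing, not clinical
    interchange.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame_uid = generate_uid()
    series_uid = generate_uid()
    nz, ny, nx = plan_image.shape
    dz, dy, dx = plan_image.spacing
    oz, oy, ox = plan_image.origin
    arr = np.clip(np.round(plan_image.voxels + 1024), 0, 4095).astype(np.uint16)
    for i in range(nz):
        ds = _base_ds(out / f"CT_{i:04d}.dcm", "1.2.840.10008.5.1.4.1.1.2")
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [ox, oy, oz + i * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
        ds.PixelData = arr[i].tobytes()
        ds.save_as(str(out / f"CT_{i:04d}.dcm"), enforce_file_format=True)

    scaling = max(float(dose.voxels.max()), 1e-6) / 65000.0
    dd = _base_ds(out / "RD_dose.dcm", "1.2.840.10008.5.1.4.1.1.481.2")
    dd.Modality = "RTDOSE"
    dd.SeriesInstanceUID = generate_uid()
    dd.FrameOfReferenceUID = frame_uid
    dd.DoseUnits, dd.DoseType, dd.DoseSummationType = "GY", "PHYSICAL", "PLAN"
    dd.DoseGridScaling = scaling
    dd.ImagePositionPatient = [ox, oy, oz]
    dd.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    dd.PixelSpacing = [dy, dx]
    dd.GridFrameOffsetVector = [i * dz for i in range(nz)]
    dd.Rows, dd.Columns, dd.NumberOfFrames = ny, nx, nz
    dd.BitsAllocated, dd.BitsStored, dd.HighBit = 16, 16, 15
    dd.PixelRepresentation = 0
    dd.SamplesPerPixel = 1
    dd.PhotometricInterpretation = "MONOCHROME2"
    dd.PixelData = np.round(dose.voxels / scaling).astype(np.uint16).tobytes()
    dd.save_as(str(out / "RD_dose.dcm"), enforce_file_format=True)

    rs = _base_ds(out / "RS_structs.dcm", "1.2.840.10008.5.1.4.1.1.481.3")
    rs.Modality = "RTSTRUCT"
    rs.SeriesInstanceUID = generate_uid()
    rs.StructureSetLabel = "PHANTOM"
    rs.StructureSetROISequence = []
    rs.ROIContourSequence = []
    for num, s in enumerate(plan.structures, start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        rs.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for i in range(nz):
            sl = s.mask[i]
            if not sl.any():
                continue
            for poly in _mask_slice_polygons(sl, dy, dx, oy, ox):
                c = Dataset()
                z = oz + i * dz
                c.ContourGeometricType = "CLOSED_PLANAR"
                pts = np.column_stack(
                    [poly[:, 0], poly[:, 1], np.full(len(poly), z)]
                ).ravel()
                c.NumberOfContourPoints = len(poly)
                c.ContourData = [f"{v:.4f}" for v in pts]
                rc.ContourSequence.append(c)
        rs.ROIContourSequence.append(rc)
    rs.save_as(str(out / "RS_structs.dcm"), enforce_file_format=True)
    return out


def _mask_slice_polygons(sl: np.ndarray, dy: float, dx: float, oy: float, ox: float):
    """Represent each contiguous run of mask rows as rectangle polygons.

    A simple exact polygonalization for row-convex masks: one rectangle per
    maximal run of set voxels in each row, merged is not attempted.  Voxel
    centers of the run are enclosed with a half-voxel margin so that
    rasterization recovers the original voxels.
    """
    polys = []
    ny, nx = sl.shape
    for j in range(ny):
        row = sl[j]
        k = 0
        while k < nx:
            if row[k]:
                k0 = k
                while k < nx and row[k]:
                    k += 1
                x0 = ox + (k0 - 0.49) * dx
                x1 = ox + ((k - 1) + 0.49) * dx
                y0 = oy + (j - 0.49) * dy
                y1 = oy + (j + 0.49) * dy
                polys.append(
                    np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
                )
            else:
                k += 1
    return polys
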