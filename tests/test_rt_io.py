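"""I/O dialects, contour rasterization and grid reconciliation."""

import numpy as np
import pytest

from adaptrt.geometry import DoseGrid, ImageVolume, resample_to_grid
from adaptrt.rt_io import (
    PlanContext,
    Structure,
    rasterize_contours,
    read_daily_volume,
    read_plan_bundle,
    write_daily_volume,
    write_dicom_bundle,
    write_plan_bundle,
)


def _square(cx, cy, half):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


def _grid(shape=(3, 24, 24), spacing=(2.0, 1.0, 1.0)):
    return ImageVolume(
        np.zeros(shape, dtype=np.float32), np.array(spacing),
        origin=np.zeros(3),
    )


class TestRasterization:
    def test_square_on_voxel_center_lines_is_half_open(self):
        # 10x10 mm square with edges through voxel centers -> 10x10 voxels
        grid = _grid()
        mask = rasterize_contours([(0.0, _square(5.0, 5.0, 5.0))], grid)
        assert mask[0].sum() == 100
        assert mask[1].sum() == 0

    def test_empty_contour_list_gives_empty_mask(self):
        assert rasterize_contours([], _grid()).sum() == 0

    def test_concentric_squares_make_a_ring(self):
        grid = _grid()
        outer = _square(10.0, 10.0, 8.0)
        inner = _square(10.0, 10.0, 4.0)
        mask = rasterize_contours([(0.0, outer), (0.0, inner)], grid)
        assert mask[0].sum() == 16 * 16 - 8 * 8

    def test_contour_beyond_grid_planes_is_skipped_with_warning(self):
        # nearest grid plane is more than half a slice spacing away
        grid = _grid()  # planes at z = 0, 2, 4
        with pytest.warns(UserWarning, match="skipped"):
            mask = rasterize_contours([(7.0, _square(5, 5, 5))], grid)
        assert mask.sum() == 0

    def test_agrees_with_brute_force_point_in_polygon(self):
        """Even-odd rasterization matches a per-point scalar ray-cast oracle."""

        def oracle_inside(x, y, poly):
            inside = False
            n = len(poly)
            for a in range(n):
                x1, y1 = poly[a]
                x2, y2 = poly[(a + 1) % n]
                if (y1 > y) != (y2 > y):
                    if x < x1 + (y - y1) * (x2 - x1) / (y2 - y1):
                        inside = not inside
            return inside

        rng = np.random.default_rng(7)
        grid = _grid(shape=(1, 16, 16))
        for _ in range(20):
            n_vert = rng.integers(3, 9)
            poly = rng.uniform(-1.3, 16.3, size=(n_vert, 2))
            mask = rasterize_contours([(0.0, poly)], grid)[0]
            for j in range(16):
                for k in range(16):
                    assert mask[j, k] == oracle_inside(float(k), float(j), poly)


@pytest.fixture
def tiny_bundle():
    rng = np.random.default_rng(3)
    img = ImageVolume(
        rng.normal(0, 50, size=(6, 10, 10)).astype(np.float32),
        np.array([2.0, 1.5, 1.5]), np.array([-5.0, -7.0, -7.0]),
    )
    mask = np.zeros((6, 10, 10), dtype=bool)
    mask[2:4, 3:7, 3:7] = True
    dose = DoseGrid(
        np.abs(rng.normal(30, 5, size=(6, 10, 10))).astype(np.float32),
        img.spacing.copy(), img.origin.copy(),
    )
    plan = PlanContext(
        total_fractions=30,
        structures=[Structure("PTV60", "target", mask, prescription=60.0)],
    )
    return img, plan, dose


class TestFixtureDialect:
    def test_bundle_round_trip_is_exact(self, tmp_path, tiny_bundle):
        img, plan, dose = tiny_bundle
        write_plan_bundle(tmp_path / "b", img, plan, dose)
        img2, plan2, dose2 = read_plan_bundle(tmp_path / "b", dialect="fixture")
        np.testing.assert_array_equal(img2.voxels, img.voxels)
        np.testing.assert_array_equal(dose2.voxels, dose.voxels)
        np.testing.assert_allclose(img2.spacing, img.spacing)
        np.testing.assert_allclose(img2.origin, img.origin)
        s, s2 = plan.structures[0], plan2.structures[0]
        np.testing.assert_array_equal(s2.mask, s.mask)
        assert plan2.total_fractions == 30 and s2.prescription == 60.0

    def test_daily_volume_round_trip(self, tmp_path, tiny_bundle):
        img, _, _ = tiny_bundle
        write_daily_volume(tmp_path / "f1.nrrd", img)
        vol = read_daily_volume(tmp_path / "f1.nrrd")
        np.testing.assert_array_equal(vol.voxels, img.voxels)

    def test_missing_structure_named_in_config_is_hard_error(self, tmp_path, tiny_bundle):
        img, plan, dose = tiny_bundle
        write_plan_bundle(tmp_path / "b", img, plan, dose)
        with pytest.raises(ValueError, match="absent"):
            read_plan_bundle(
                tmp_path / "b", required_structures=["PTV60", "parotid_L"]
            )

    def test_coarse_dose_grid_resampled_with_mean_preserved(self, tmp_path):
        """A 2x-coarser smooth dose resamples onto the plan grid trilinearly,
        matching direct analytic evaluation within 2% in the mean."""

        def dose_fn(p):
            return 30.0 + 10.0 * np.sin(p[..., 1] / 20.0) * np.cos(p[..., 2] / 25.0)

        img = ImageVolume(
            np.zeros((8, 20, 20), dtype=np.float32),
            np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]),
        )
        coarse = ImageVolume(
            np.zeros((4, 10, 10)), np.array([4.0, 4.0, 4.0]), np.array([2.0, 2.0, 2.0])
        )
        coarse_dose = DoseGrid(
            dose_fn(coarse.physical_points()), coarse.spacing, coarse.origin
        )
        plan = PlanContext(
            total_fractions=30,
            structures=[
                Structure("PTV", "target", np.ones(img.shape, bool), prescription=60.0)
            ],
        )
        write_plan_bundle(tmp_path / "b", img, plan, coarse_dose)
        _, _, dose2 = read_plan_bundle(tmp_path / "b")
        assert dose2.same_grid(img)
        analytic = dose_fn(img.physical_points())
        # interior comparison (outside the coarse grid the resampler pads)
        sl = (slice(1, -1),) * 3
        rel = abs(dose2.voxels[sl].mean() - analytic[sl].mean()) / analytic[sl].mean()
        assert rel < 0.02


class TestDicomDialect:
    def test_dicom_bundle_round_trip(self, tmp_path, tiny_bundle):
        img, plan, dose = tiny_bundle
        write_dicom_bundle(tmp_path / "d", img, plan, dose)
        img2, plan2, dose2 = read_plan_bundle(
            tmp_path / "d", dialect="dicom",
            structure_roles={
                "__total_fractions__": 30,
                "PTV60": {"role": "target", "prescription": 60.0},
            },
        )
        # CT stored as integer HU: exact to rounding
        assert np.abs(img2.voxels - np.round(img.voxels)).max() <= 0.5
        np.testing.assert_allclose(img2.spacing, img.spacing)
        np.testing.assert_allclose(img2.origin, img.origin)
        # dose honors DoseGridScaling: quantization only
        assert np.abs(dose2.voxels - dose.voxels).max() < 0.01
        np.testing.assert_array_equal(
            plan2.structure("PTV60").mask, plan.structure("PTV60").mask
        )

    def test_rtdose_scaling_contract(self, tmp_path, tiny_bundle):
        import pydicom

        img, plan, dose = tiny_bundle
        write_dicom_bundle(tmp_path / "d", img, plan, dose)
        ds = pydicom.dcmread(str(tmp_path / "d" / "RD_dose.dcm"))
        value = ds.pixel_array[2, 4, 4] * ds.DoseGridScaling
        assert value == pytest.approx(float(dose.voxels[2, 4, 4]), abs=1e-3)


class TestDailyVolume:
    def test_93_slices_at_2mm_span_184mm(self, tmp_path):
        vol = ImageVolume(
            np.zeros((93, 4, 4), dtype=np.float32),
            np.array([2.0, 2.0, 2.0]), np.zeros(3),
        )
        write_daily_volume(tmp_path / "v.nrrd", vol)
        v = read_daily_volume(tmp_path / "v.nrrd")
        extent = (v.shape[0] - 1) * v.spacing[0]
        assert extent == pytest.approx(184.0)

    def test_single_slice_volume_is_rejected(self, tmp_path):
        vol = ImageVolume(
            np.zeros((1, 4, 4), dtype=np.float32), np.ones(3), np.zeros(3)
        )
        write_daily_volume(tmp_path / "v.nrrd", vol)
        with pytest.raises(ValueError, match="3D"):
            read_daily_volume(tmp_path / "v.nrrd")

    def test_nonuniform_dicom_slice_spacing_is_rejected(self, tmp_path, tiny_bundle):
        img, plan, dose = tiny_bundle
        out = write_dicom_bundle(tmp_path / "d", img, plan, dose)
        # corrupt one slice position
        import pydicom

        p = sorted(out.glob("CT_*.dcm"))[3]
        ds = pydicom.dcmread(str(p))
        ds.ImagePositionPatient[2] = float(ds.ImagePositionPatient[2]) + 0.7
        ds.save_as(str(p), enforce_file_format=True)
        with pytest.raises(ValueError, match="non-uniform"):
            read_daily_volume(tmp_path / "d", dialect="dicom")
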