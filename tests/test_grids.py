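"""Geometry layer: resampling, rasterization, lateralization, file I/O."""

import numpy as np
import pytest

from xeromics.grids import (
    DoseGrid,
    GridError,
    OrganMask,
    lateralize,
    rasterize_mask,
    read_rt_dose,
    read_rt_structures,
    read_volume,
    resample_mask,
    resample_to_isotropic,
    write_volume,
)

from conftest import ball_mask


def affine_grid(a, b, shape=(11, 9, 7), spacing=(2.0, 2.0, 3.0)):
    g = DoseGrid(np.zeros(shape), spacing)
    x, _, _ = g.coordinate_grids()
    return DoseGrid(a + b * x, spacing)


class TestResampling:
    def test_constant_field_stays_constant(self):
        g = DoseGrid(np.full((9, 9, 7), 20.0), (2.0, 2.0, 3.0))
        r = resample_to_isotropic(g, 1.0)
        assert r.spacing == (1.0, 1.0, 1.0)
        np.testing.assert_allclose(r.values, 20.0)

    def test_trilinear_exact_on_affine_field(self):
        g = affine_grid(a=5.0, b=1.5)
        r = resample_to_isotropic(g, 1.0)
        x, _, _ = r.coordinate_grids()
        np.testing.assert_allclose(r.values, 5.0 + 1.5 * x, atol=1e-9)

    def test_extent_preserved_within_one_voxel(self):
        g = affine_grid(a=1.0, b=0.5)
        r = resample_to_isotropic(g, 1.0)
        for axis in range(3):
            assert abs(r.extent[axis] - g.extent[axis]) <= 1.0

    def test_mean_dose_preserved_on_smooth_field(self, rng, small_geometry):
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(rng.uniform(0, 40, size=(16, 16, 12)), sigma=2.5)
        g = DoseGrid(vals, (2.0, 2.0, 3.0))
        mask_before = np.ones(g.shape, bool)
        r = resample_to_isotropic(g, 1.0)
        assert abs(r.values.mean() - g.values.mean()) / g.values.mean() < 0.01

    def test_idempotent_at_same_spacing(self, rng):
        g = DoseGrid(rng.uniform(0, 30, (12, 10, 8)), (1.0, 1.0, 1.0))
        once = resample_to_isotropic(g, 1.0)
        twice = resample_to_isotropic(once, 1.0)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    @pytest.mark.parametrize("target", [0.0, -1.0])
    def test_nonpositive_target_rejected(self, target):
        g = affine_grid(1, 1)
        with pytest.raises(GridError):
            resample_to_isotropic(g, target)

    def test_degenerate_axis_named_in_error(self):
        g = DoseGrid(np.zeros((5, 1, 5)), (1, 1, 1))
        with pytest.raises(GridError, match="'y'"):
            resample_to_isotropic(g, 1.0)

    def test_mask_resampling_stays_binary(self, small_geometry):
        m = ball_mask(small_geometry, (15, 15, 15), 12)
        coarse = OrganMask(m.values[::2, ::2, ::2], (2, 2, 2), m.origin)
        fine = resample_mask(coarse, 1.0)
        assert fine.values.dtype == bool
        # volume approximately preserved
        assert abs(fine.volume - coarse.volume) / coarse.volume < 0.1


class TestRasterization:
    def test_square_contour_voxel_count(self, small_geometry):
        square = np.array([[4.5, 4.5], [14.5, 4.5], [14.5, 14.5], [4.5, 14.5]])
        m = rasterize_mask([(10.0, square)], small_geometry)
        assert m.values[:, :, 10].sum() == 100
        assert m.voxel_count == 100

    def test_empty_contour_list(self, small_geometry):
        m = rasterize_mask([], small_geometry)
        assert m.voxel_count == 0

    def test_circle_area(self, small_geometry):
        # off-lattice center avoids voxel centers sitting exactly on the rim
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        circle = np.column_stack([15.3 + 5 * np.cos(theta), 14.6 + 5 * np.sin(theta)])
        m = rasterize_mask([(12.0, circle)], small_geometry)
        count = m.values[:, :, 12].sum()
        assert abs(count - np.pi * 25) / (np.pi * 25) < 0.05

    def test_self_intersecting_polygon_rejected(self, small_geometry):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(GridError, match="contour 0"):
            rasterize_mask([(10.0, bowtie)], small_geometry)

    def test_slice_outside_grid_rejected(self, small_geometry):
        square = np.array([[1.0, 1.0], [5.0, 1.0], [5.0, 5.0], [1.0, 5.0]])
        with pytest.raises(GridError, match="outside"):
            rasterize_mask([(99.0, square)], small_geometry)


def two_gland_setup(left_mean, right_mean, nx=40):
    geo = DoseGrid(np.zeros((nx, 15, 15)), (1, 1, 1))
    left = ball_mask(geo, (30, 7, 7), 5)   # +x side = patient left
    right = ball_mask(geo, (9, 7, 7), 5)
    vals = np.zeros(geo.shape)
    vals[left.values] = left_mean
    vals[right.values] = right_mean
    dose = DoseGrid(vals, geo.spacing, geo.origin)
    import dataclasses

    left = dataclasses.replace(left, laterality="left")
    right = dataclasses.replace(right, laterality="right")
    return dose, left, right


class TestLateralize:
    def test_right_hotter_triggers_flip(self):
        dose, left, right = two_gland_setup(20.0, 30.0)
        res = lateralize(dose, left, right)
        assert res.flipped
        assert res.ipsi_mask.laterality == "right"
        assert res.mean_dose_ipsi == pytest.approx(30.0)
        assert res.mean_dose_contra == pytest.approx(20.0)

    def test_left_hotter_no_flip(self):
        dose, left, right = two_gland_setup(30.0, 20.0)
        res = lateralize(dose, left, right)
        assert not res.flipped
        assert res.ipsi_mask.laterality == "left"

    def test_tie_no_flip(self):
        dose, left, right = two_gland_setup(25.0, 25.0)
        res = lateralize(dose, left, right)
        assert not res.flipped
        assert res.ipsi_mask.laterality == "left"

    def test_flip_involution(self):
        """A lateralized volume set never flips again."""
        dose, left, right = two_gland_setup(10.0, 28.0)
        first = lateralize(dose, left, right)
        assert first.flipped
        second = lateralize(first.dose, first.ipsi_mask, first.contra_mask)
        assert not second.flipped

    def test_mean_doses_unchanged_by_flip(self):
        dose, left, right = two_gland_setup(12.0, 31.0)
        res = lateralize(dose, left, right)
        from xeromics.grids import mean_dose

        assert mean_dose(res.dose, res.ipsi_mask) == pytest.approx(31.0)
        assert mean_dose(res.dose, res.contra_mask) == pytest.approx(12.0)

    def test_volume_invariant_under_flip(self):
        dose, left, right = two_gland_setup(10.0, 28.0)
        res = lateralize(dose, left, right)
        assert res.ipsi_mask.volume == right.volume
        assert res.contra_mask.volume == left.volume

    def test_geometry_mismatch_rejected(self):
        dose, left, right = two_gland_setup(10.0, 20.0)
        bad = OrganMask(right.values[:-1], right.spacing, right.origin)
        with pytest.raises(GridError):
            lateralize(dose, left, bad)


class TestVolumeIO:
    def test_dose_round_trip(self, tmp_path, rng):
        g = DoseGrid(rng.uniform(0, 50, (8, 7, 6)), (1.0, 2.0, 2.5), (1.0, -3.0, 10.0))
        path = tmp_path / "dose.nrrd"
        write_volume(path, g)
        back = read_volume(path, kind="dose")
        np.testing.assert_allclose(back.values, g.values)
        np.testing.assert_allclose(back.spacing, g.spacing)
        np.testing.assert_allclose(back.origin, g.origin)

    def test_mask_round_trip_preserves_count(self, tmp_path, small_geometry):
        m = ball_mask(small_geometry, (15, 15, 15), 7)
        path = tmp_path / "mask.nrrd"
        write_volume(path, m)
        back = read_volume(path)
        assert isinstance(back, OrganMask)
        assert back.voxel_count == m.voxel_count
        np.testing.assert_array_equal(back.values, m.values)


def _write_rt_dose(path, ints, scaling, spacing_yx=(2.0, 2.0), dz=3.0):
    """Build a minimal RTDOSE object from an integer grid (z, y, x order)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.Modality = "RTDOSE"
    nz, ny, nx = ints.shape
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.PixelSpacing = [spacing_yx[0], spacing_yx[1]]
    ds.GridFrameOffsetVector = [i * dz for i in range(nz)]
    ds.ImagePositionPatient = [0.0, 0.0, 0.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.DoseGridScaling = scaling
    ds.DoseUnits = "GY"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = ints.astype("<u4").tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomIO:
    def test_rt_dose_scaling_applied(self, tmp_path, rng):
        ints = rng.integers(0, 1000, size=(4, 6, 5)).astype(np.uint32)
        s = 0.0123
        path = tmp_path / "rtdose.dcm"
        _write_rt_dose(path, ints, s)
        dose = read_rt_dose(path)
        # stored (z, y, x) k-values become s*k on the (x, y, z) grid
        np.testing.assert_allclose(dose.values, ints.transpose(2, 1, 0) * s)
        assert dose.spacing == (2.0, 2.0, 3.0)

    def test_missing_scaling_rejected(self, tmp_path, rng):
        ints = rng.integers(0, 10, size=(2, 3, 3)).astype(np.uint32)
        path = tmp_path / "rtdose.dcm"
        _write_rt_dose(path, ints, 1.0)
        import pydicom

        ds = pydicom.dcmread(str(path))
        del ds.DoseGridScaling
        ds.save_as(str(path), enforce_file_format=True)
        with pytest.raises(GridError, match="DoseGridScaling"):
            read_rt_dose(path)

    def test_rt_struct_contours(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
        from pydicom.sequence import Sequence

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = FileDataset("rs", {}, file_meta=meta, preamble=b"\0" * 128)
        roi = Dataset()
        roi.ROINumber = 1
        roi.ROIName = "Parotid_L"
        roi.ReferencedFrameOfReferenceUID = pydicom.uid.generate_uid()
        ds.StructureSetROISequence = Sequence([roi])
        contour = Dataset()
        contour.ContourGeometricType = "CLOSED_PLANAR"
        contour.NumberOfContourPoints = 3
        contour.ContourData = [0.0, 0.0, 5.0, 10.0, 0.0, 5.0, 0.0, 10.0, 5.0]
        rc = Dataset()
        rc.ReferencedROINumber = 1
        rc.ContourSequence = Sequence([contour])
        ds.ROIContourSequence = Sequence([rc])
        path = tmp_path / "rtstruct.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        contours = read_rt_structures(path)
        assert list(contours) == ["Parotid_L"]
        z, poly = contours["Parotid_L"][0]
        assert z == 5.0
        assert poly.shape == (3, 2)
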