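"""Geometry, transforms, segmentation, registration, dose resampling."""

import numpy as np
import pytest
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from lungntcp.exceptions import RegistrationError, SegmentationError
from lungntcp.imaging import (
    RegistrationConfig,
    map_dose_to_followup,
    register_rigid,
    sample_at,
    segment_lungs,
)
from lungntcp.phantom import generate_ct_pair, lung_mask_truth
from lungntcp.volume import ImageVolume, RigidTransform

from conftest import SMALL_MIN_LUNG_CM3, small_config


class TestRigidTransform:
    @pytest.mark.parametrize(
        "t,r",
        [
            ((0, 0, 0), (0, 0, 0)),
            ((4.0, -2.0, 3.0), (0, 0, 0)),
            ((1.5, 2.5, -3.5), (10.0, -5.0, 7.0)),
            ((-12.0, 0.4, 8.0), (-30.0, 15.0, 45.0)),
        ],
    )
    def test_inverse_composes_to_identity(self, t, r):
        T = RigidTransform(t, r, center=(48.0, 48.0, 48.0))
        assert np.allclose(T.compose(T.inverse()), np.eye(4), atol=1e-10)
        assert np.allclose(T.inverse().compose(T), np.eye(4), atol=1e-10)

    def test_apply_rotation_about_center(self):
        T = RigidTransform((0, 0, 0), (0, 0, 90.0), center=(10.0, 10.0, 0.0))
        # 90 deg about z: (11,10,0) -> center + Rz*(1,0,0) = (10,11,0)
        assert T.apply(np.array([11.0, 10.0, 0.0])) == pytest.approx(
            [10.0, 11.0, 0.0], abs=1e-12
        )

    def test_shifted_adds_translation(self):
        T = RigidTransform((1.0, 2.0, 3.0))
        assert T.shifted((0.0, 0.0, -3.0)).translation == (1.0, 2.0, 0.0)

    def test_json_roundtrip(self, tmp_path):
        T = RigidTransform((4.0, -2.0, 3.0), (1.0, 0.0, -2.0), (47.5, 47.5, 47.5))
        T.to_json(tmp_path / "t.json")
        assert RigidTransform.from_json(tmp_path / "t.json") == T


def _write_ct_series(directory, volume):
    """Minimal synthetic DICOM CT series for reader tests."""
    directory.mkdir(exist_ok=True)
    series_uid = generate_uid()
    for k in range(volume.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows = volume.shape[1]
        ds.Columns = volume.shape[0]
        ds.PixelSpacing = [volume.spacing[1], volume.spacing[0]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[0],
            volume.origin[1],
            volume.origin[2] + k * volume.spacing[2],
        ]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        stored = (volume.data[:, :, k].T + 1024).astype(np.uint16)  # (rows, cols)
        ds.PixelData = stored.tobytes()
        ds.save_as(
            str(directory / f"slice{k:03d}.dcm"), enforce_file_format=True
        )


class TestVolumeIO:
    def test_nifti_roundtrip_negative_origin(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = ImageVolume(
            rng.normal(size=(8, 9, 10)).astype(np.float32),
            spacing=(0.94, 0.94, 3.0),
            origin=(-120.0, -85.5, 40.0),
        )
        vol.to_nifti(tmp_path / "v.nii.gz")
        back = ImageVolume.from_nifti(tmp_path / "v.nii.gz")
        assert np.array_equal(back.data, vol.data)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)

    def test_dicom_ct_series_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        hu = rng.integers(-1000, 1000, size=(6, 7, 5)).astype(float)
        vol = ImageVolume(hu, spacing=(0.94, 0.94, 3.0), origin=(-10.0, 5.0, 2.0))
        _write_ct_series(tmp_path / "ct", vol)
        back = ImageVolume.from_dicom_ct_series(tmp_path / "ct")
        assert np.array_equal(back.data, vol.data)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)


class TestSegmentLungs:
    def test_phantom_lungs_in_mask_body_out(self, small_shifted):
        cfg, planning, followup, dose, truth = small_shifted
        mask = segment_lungs(
            planning, min_component_volume_cm3=SMALL_MIN_LUNG_CM3
        )
        truth_lung = lung_mask_truth(cfg)
        # every interior lung voxel captured (erode truth by the noise margin)
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(truth_lung, iterations=2)
        assert np.all(mask.data[interior])
        # body wall (between the lungs) excluded
        cx = np.round(np.asarray(cfg.shape) / 2).astype(int)
        assert not mask.data[cx[0], cx[1], cx[2]]

    def test_dense_nodule_included_by_hole_filling(self):
        cfg = small_config(hu_noise_sd=0.0, misalignment=RigidTransform(), seed=2)
        planning = generate_ct_pair(cfg)[0]
        center = np.array([17, 32, 32])
        ax = [np.arange(s) for s in cfg.shape]
        r2 = (
            ((ax[0] - center[0]) ** 2)[:, None, None]
            + ((ax[1] - center[1]) ** 2)[None, :, None]
            + ((ax[2] - center[2]) ** 2)[None, None, :]
        )
        nodule = r2 <= 2.5**2
        planning.data[nodule] = 0.0  # 5 mm soft-tissue nodule inside the lung
        mask = segment_lungs(planning, min_component_volume_cm3=SMALL_MIN_LUNG_CM3)
        assert np.all(mask.data[nodule])

    def test_all_air_volume_fails(self):
        vol = ImageVolume(np.full((32, 32, 32), -1000.0), (1, 1, 1))
        with pytest.raises(SegmentationError):
            segment_lungs(vol)

    def test_invariant_to_body_brightening(self, small_shifted):
        cfg, planning, *_ = small_shifted
        mask1 = segment_lungs(planning, min_component_volume_cm3=SMALL_MIN_LUNG_CM3)
        brighter = planning.with_data(
            np.where(planning.data > -400.0, planning.data + 500.0, planning.data)
        )
        mask2 = segment_lungs(brighter, min_component_volume_cm3=SMALL_MIN_LUNG_CM3)
        assert np.array_equal(mask1.data, mask2.data)


class TestRegisterRigid:
    def test_self_registration_is_identity(self, small_shifted):
        _, planning, *_ = small_shifted
        cfg = RegistrationConfig(translation_only=True)
        T, ncc = register_rigid(planning, planning, cfg)
        assert ncc == pytest.approx(1.0, abs=1e-6)
        assert np.asarray(T.translation) == pytest.approx((0, 0, 0), abs=1e-6)

    def test_recovers_known_shift(self, small_shifted):
        cfg, planning, followup, dose, truth = small_shifted
        T, ncc = register_rigid(
            followup, planning, RegistrationConfig(translation_only=True)
        )
        err = np.abs(np.asarray(T.translation) - truth.misalignment.translation)
        assert np.all(err <= 0.5 * np.asarray(cfg.spacing))
        assert ncc > 0.9

    def test_optimum_not_worse_than_identity(self, small_shifted):
        _, planning, followup, *_ = small_shifted
        T, ncc = register_rigid(
            followup, planning, RegistrationConfig(translation_only=True)
        )
        # identity NCC computed directly on the overlapping full arrays
        a = followup.data.astype(float).ravel()
        b = planning.data.astype(float).ravel()
        a, b = a - a.mean(), b - b.mean()
        ncc_id = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
        assert ncc >= ncc_id - 1e-12

    def test_recovery_improves_with_finer_levels(self, small_shifted):
        cfg, planning, followup, dose, truth = small_shifted
        true_t = np.asarray(truth.misalignment.translation)
        errs = []
        for levels in [(4,), (4, 2), (4, 2, 1)]:
            T, _ = register_rigid(
                followup,
                planning,
                RegistrationConfig(levels=levels, translation_only=True),
            )
            errs.append(np.linalg.norm(np.asarray(T.translation) - true_t))
        # finer levels never degrade the recovery beyond the simplex
        # convergence tolerance (all levels may already sit at the floor)
        tol = RegistrationConfig().xatol_mm
        assert errs[1] <= errs[0] + tol
        assert errs[2] <= errs[1] + tol
        assert errs[2] <= 0.5  # and the finest is well inside half a voxel

    def test_no_overlap_fails(self):
        rng = np.random.default_rng(0)
        a = ImageVolume(rng.normal(size=(16, 16, 16)), (1, 1, 1), (0, 0, 0))
        b = ImageVolume(rng.normal(size=(16, 16, 16)), (1, 1, 1), (1000, 0, 0))
        with pytest.raises(RegistrationError):
            register_rigid(a, b, RegistrationConfig(translation_only=True))


class TestMapDose:
    def _dose(self, shape=(12, 13, 14), origin=(0, 0, 0)):
        rng = np.random.default_rng(3)
        return ImageVolume(
            rng.uniform(0, 60, size=shape), (1, 1, 1), origin, kind="Gy"
        )

    def test_identity_congruent_is_copy(self):
        dose = self._dose()
        out = map_dose_to_followup(dose, RigidTransform(), dose)
        assert np.array_equal(out.data, dose.data)

    def test_integer_shift_matches_bruteforce(self):
        dose = self._dose()
        T = RigidTransform(translation=(2.0, -1.0, 3.0))
        out = map_dose_to_followup(dose, T, dose)
        expected = np.full(dose.shape, np.nan)
        for i in range(dose.shape[0]):
            for j in range(dose.shape[1]):
                for k in range(dose.shape[2]):
                    ii, jj, kk = i + 2, j - 1, k + 3
                    if (
                        0 <= ii < dose.shape[0]
                        and 0 <= jj < dose.shape[1]
                        and 0 <= kk < dose.shape[2]
                    ):
                        expected[i, j, k] = dose.data[ii, jj, kk]
        assert np.array_equal(np.isnan(out.data), np.isnan(expected))
        assert np.array_equal(out.data[~np.isnan(out.data)], expected[~np.isnan(expected)])

    def test_nearest_never_interpolates(self):
        dose = self._dose()
        T = RigidTransform(translation=(0.4, -1.7, 2.2), rotation_deg=(3.0, 0, 0),
                           center=(6.0, 6.0, 7.0))
        out = map_dose_to_followup(dose, T, dose)
        finite = out.data[np.isfinite(out.data)]
        assert np.all(np.isin(finite, dose.data))
        assert finite.max() <= dose.data.max()

    def test_sample_at_outside_is_nan(self):
        dose = self._dose()
        vals = sample_at(dose, np.array([[100.0, 0.0, 0.0], [5.0, 5.0, 5.0]]))
        assert np.isnan(vals[0]) and np.isfinite(vals[1])
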