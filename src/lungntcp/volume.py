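"""Image volumes, rigid transforms, and NIfTI / DICOM input-output.

Conventions, fixed package-wide:

* world frame is patient LPS, in mm;
* voxel indices are 0-based, axis order (x, y, z);
* a voxel center's world position is ``origin + index * spacing``
  (axis-aligned grids only -- oblique DICOM orientations are rejected);
* sampling is at voxel centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.spatial.transform import Rotation

__all__ = ["ImageVolume", "RigidTransform", "load_volume"]

#: Sentinel for voxels with no valid value (e.g. outside the dose block).
NO_VALUE = np.nan

_KINDS = ("HU", "Gy", "mask")


@dataclass
class ImageVolume:
    """A 3D scalar grid (CT in HU, dose in Gy, or a boolean mask).

    ``data`` is indexed ``[ix, iy, iz]``; ``spacing`` and ``origin`` are
    per-axis mm in the LPS world frame.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def center_world(self) -> np.ndarray:
        """World coordinates of the geometric center of the voxel grid."""
        n = np.array(self.shape, dtype=float)
        return np.asarray(self.origin) + (n - 1) / 2.0 * np.asarray(self.spacing)

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(
            self.spacing
        )

    def world_to_index(self, world) -> np.ndarray:
        """Continuous (fractional) voxel index of world positions."""
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_world_coords(self) -> list[np.ndarray]:
        """Per-axis voxel-center world coordinates (three 1D arrays)."""
        return [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]

    def voxel_world_points(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (N, 3), C-ordered."""
        ax = self.axis_world_coords()
        pts = np.empty(self.shape + (3,))
        pts[..., 0] = ax[0][:, None, None]
        pts[..., 1] = ax[1][None, :, None]
        pts[..., 2] = ax[2][None, None, :]
        return pts.reshape(-1, 3)

    def same_geometry(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "ImageVolume":
        return replace(self, data=data, kind=kind or self.kind)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # -- NIfTI I/O ---------------------------------------------------------

    def to_nifti(self, path: str | Path) -> Path:
        """Write as NIfTI. Internal LPS becomes NIfTI's RAS by negating x, y."""
        affine = np.diag([-self.spacing[0], -self.spacing[1], self.spacing[2], 1.0])
        affine[:3, 3] = [-self.origin[0], -self.origin[1], self.origin[2]]
        arr = self.data.astype(np.uint8 if self.kind == "mask" else np.float32)
        img = nib.Nifti1Image(arr, affine)
        img.header.set_xyzt_units("mm")
        path = Path(path)
        nib.save(img, str(path))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path, kind: str = "HU") -> "ImageVolume":
        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-4):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        data = np.asarray(img.dataobj, dtype=float)
        steps = np.diag(rot).copy()
        origin_ras = affine[:3, 3].copy()
        # Flip axes with negative steps so spacing is positive.
        for a in range(3):
            if steps[a] < 0:
                data = np.flip(data, axis=a)
                origin_ras[a] = origin_ras[a] + steps[a] * (data.shape[a] - 1)
                steps[a] = -steps[a]
        # RAS -> LPS: negate x and y; an array ascending in RAS x/y descends
        # in LPS, so flip those axes and move the origin to the other end.
        for a in (0, 1):
            data = np.flip(data, axis=a)
            origin_ras[a] = -(origin_ras[a] + steps[a] * (data.shape[a] - 1))
        origin = (origin_ras[0], origin_ras[1], origin_ras[2])
        vol = cls(data, tuple(steps), origin, kind=kind)
        if kind == "mask":
            vol.data = vol.data > 0.5
        return vol

    # -- DICOM I/O ---------------------------------------------------------

    @classmethod
    def from_dicom_ct_series(cls, directory: str | Path) -> "ImageVolume":
        """Read a DICOM CT slice series: sorted by position, HU-rescaled."""
        files = sorted(Path(directory).glob("*.dcm"))
        if not files:
            raise FileNotFoundError(f"no .dcm files in {directory}")
        slices = [pydicom.dcmread(str(f)) for f in files]
        iop = [float(v) for v in slices[0].ImageOrientationPatient]
        if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-4):
            raise ValueError("only axial identity-orientation CT series supported")
        slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
        zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
        dz = np.diff(zs)
        if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
            raise ValueError("non-uniform slice spacing")
        ps = [float(v) for v in slices[0].PixelSpacing]  # (row, col) = (y, x)
        planes = []
        for s in slices:
            slope = float(getattr(s, "RescaleSlope", 1.0))
            inter = float(getattr(s, "RescaleIntercept", 0.0))
            planes.append(s.pixel_array.astype(float) * slope + inter)
        # (z, y, x) -> (x, y, z)
        data = np.stack(planes).transpose(2, 1, 0)
        origin = (
            float(slices[0].ImagePositionPatient[0]),
            float(slices[0].ImagePositionPatient[1]),
            zs[0],
        )
        spacing = (ps[1], ps[0], float(dz[0]) if len(dz) else 1.0)
        return cls(data, spacing, origin, kind="HU")

    @classmethod
    def from_dicom_rtdose(cls, path: str | Path) -> "ImageVolume":
        """Read a DICOM RTDOSE grid, applying DoseGridScaling."""
        ds = pydicom.dcmread(str(path))
        scaling = float(ds.DoseGridScaling)
        arr = ds.pixel_array.astype(float) * scaling  # (frames=z, rows=y, cols=x)
        offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
        dz = np.diff(offsets)
        if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
            raise ValueError("non-uniform GridFrameOffsetVector")
        ps = [float(v) for v in ds.PixelSpacing]
        ipp = [float(v) for v in ds.ImagePositionPatient]
        data = arr.transpose(2, 1, 0)
        spacing = (ps[1], ps[0], float(dz[0]) if len(dz) else 1.0)
        origin = (ipp[0], ipp[1], ipp[2] + offsets[0])
        return cls(data, spacing, origin, kind="Gy")

    def to_dicom_rtdose(self, path: str | Path) -> Path:
        """Write a minimal RTDOSE file (uint32 pixels with DoseGridScaling)."""
        if self.kind != "Gy":
            raise ValueError("only dose volumes can be written as RTDOSE")
        dmax = float(np.nanmax(self.data))
        scaling = (dmax / (2**31)) if dmax > 0 else 1.0
        pixels = np.nan_to_num(self.data, nan=0.0) / scaling
        arr = pixels.transpose(2, 1, 0).astype(np.uint32)  # (z, y, x)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.481.2"
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.DoseUnits = "GY"
        ds.DoseType = "PHYSICAL"
        ds.DoseSummationType = "PLAN"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.NumberOfFrames = self.shape[2]
        ds.Rows = self.shape[1]
        ds.Columns = self.shape[0]
        ds.BitsAllocated = 32
        ds.BitsStored = 32
        ds.HighBit = 31
        ds.PixelRepresentation = 0
        ds.DoseGridScaling = scaling
        ds.PixelSpacing = [self.spacing[1], self.spacing[0]]  # (row, col)
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = list(self.origin)
        ds.GridFrameOffsetVector = [i * self.spacing[2] for i in range(self.shape[2])]
        ds.PixelData = arr.tobytes()
        path = Path(path)
        ds.save_as(str(path), enforce_file_format=True)
        return path


def load_volume(path: str | Path, kind: str = "HU") -> ImageVolume:
    """Load a volume from NIfTI (.nii/.nii.gz), RTDOSE (.dcm) or a DICOM dir."""
    path = Path(path)
    if path.is_dir():
        return ImageVolume.from_dicom_ct_series(path)
    if path.suffix == ".dcm":
        return ImageVolume.from_dicom_rtdose(path)
    return ImageVolume.from_nifti(path, kind=kind)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid map between world frames.

    ``y = R @ (x - center) + center + translation`` with
    ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (angles in degrees) applied about
    ``center``, the fixed volume's world center.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of the map."""
        rx, ry, rz = self.rotation_deg
        R = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points, shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        if self.rotation_deg == (0.0, 0.0, 0.0):  # pure translation fast path
            return p + np.asarray(self.translation)
        m = self.matrix
        return p @ m[:3, :3].T + m[:3, 3]

    def inverse(self) -> "RigidTransform":
        rx, ry, rz = self.rotation_deg
        R = Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True)
        Rinv = R.inv()
        rz2, ry2, rx2 = Rinv.as_euler("ZYX", degrees=True)
        t2 = -Rinv.as_matrix() @ np.asarray(self.translation)
        return RigidTransform(tuple(t2), (rx2, ry2, rz2), self.center)

    def compose(self, other: "RigidTransform") -> np.ndarray:
        """Matrix of x -> other(self(x))."""
        return other.matrix @ self.matrix

    def shifted(self, delta: tuple[float, float, float]) -> "RigidTransform":
        """Same transform with ``delta`` (mm) added to the translation."""
        t = tuple(np.asarray(self.translation) + np.asarray(delta, dtype=float))
        return replace(self, translation=t)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(4), atol=1e-12)

    def to_dict(self) -> dict:
        return {
            "translation_mm": list(self.translation),
            "rotation_deg": list(self.rotation_deg),
            "center_mm": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["translation_mm"]),
            tuple(d["rotation_deg"]),
            tuple(d["center_mm"]),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))
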