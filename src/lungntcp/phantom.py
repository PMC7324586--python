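"""Synthetic thoracic CT phantom with an SBRT-like dose block.

The phantom provides ground truth for every pipeline stage without any
patient data: a planning chest CT (air / body / two lung ellipsoids
plus Gaussian HU noise), a 1 mm isotropic dose block with a steep,
monotone radial falloff spanning the 0-60 Gy range, a follow-up CT
whose lung HU has increased by a chosen sigmoid function of local dose,
and a known rigid mis-alignment between the two scans.

Default conditions: a 97^3-voxel, 1 mm grid (so the full pipeline runs
in seconds and the lung-centred isocenter lands exactly on a voxel
center, avoiding systematic half-voxel ties in nearest-neighbour dose
lookups; anisotropic 0.94 x 0.94 x 3 mm clinical-style spacing is
available), Dmax = 60 Gy with half-value radius 18 mm, lung at -800 HU
with 20 HU noise, a maximal HU increase of 200, a Lyman-type true
response at (D50, gamma50) = (35.29, 1.35), and a (+4, -2, +3) mm
translational mis-alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import models as m
from .curves import DoseResponseCurve
from .exceptions import ConfigurationError
from .volume import ImageVolume, RigidTransform

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_dose_block",
    "generate_ct_pair",
    "generate_binned_curve",
    "write_phantom",
]

_LN2 = np.log(2.0)


@dataclass
class PhantomConfig:
    """Everything that defines a synthetic study, with a single seed."""

    shape: tuple[int, int, int] = (97, 97, 97)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # HU compartments
    air_hu: float = -1000.0
    body_hu: float = 40.0
    lung_hu: float = -800.0
    hu_noise_sd: float = 20.0
    # anatomy (world mm, origin at 0): body ellipsoid and two lungs
    body_semiaxes: tuple[float, float, float] = (44.0, 40.0, 45.0)
    lung_semiaxes: tuple[float, float, float] = (18.0, 22.0, 32.0)
    lung_offset_mm: float = 22.0  # lung centers at volume center +/- this in x
    # dose block
    isocenter_mm: tuple[float, float, float] | None = None  # default: right lung center
    dose_block_size_mm: float = 50.0
    dmax_gy: float = 60.0
    r50_mm: float = 18.0
    falloff_exponent: float = 2.0
    # response
    true_model: str = "lyman"
    true_d50: float = 35.29
    true_gamma50: float = 1.35
    delta_hu_max: float = 200.0
    # mis-alignment of the follow-up scan (follow-up -> planning world map)
    misalignment: RigidTransform = field(
        default_factory=lambda: RigidTransform(translation=(4.0, -2.0, 3.0))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dmax_gy <= 0 or self.r50_mm <= 0:
            raise ConfigurationError("dmax_gy and r50_mm must be > 0")
        if self.hu_noise_sd < 0:
            raise ConfigurationError("hu_noise_sd must be >= 0")
        m.parse_model_id(self.true_model)

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)

    @property
    def isocenter(self) -> np.ndarray:
        if self.isocenter_mm is not None:
            return np.asarray(self.isocenter_mm, dtype=float)
        c = self.center_mm.copy()
        c[0] -= self.lung_offset_mm  # right lung (LPS: -x is patient right)
        return c

    @property
    def true_params(self) -> m.NTCPParams:
        return m.NTCPParams(self.true_d50, self.true_gamma50)


@dataclass
class PhantomTruth:
    """Ground truth of one generated phantom; JSON round-trippable."""

    model: str
    d50: float
    gamma50: float
    delta_hu_max: float
    misalignment: RigidTransform
    air_hu: float
    body_hu: float
    lung_hu: float
    dmax_gy: float
    r50_mm: float
    isocenter_mm: tuple[float, float, float]
    seed: int

    def to_json(self, path: str | Path) -> Path:
        d = asdict(self)
        d["misalignment"] = self.misalignment.to_dict()
        path = Path(path)
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        d["misalignment"] = RigidTransform.from_dict(d["misalignment"])
        d["isocenter_mm"] = tuple(d["isocenter_mm"])
        return cls(**d)


def _ellipsoid(axes: list[np.ndarray], center, semiaxes) -> np.ndarray:
    """Boolean ellipsoid mask from per-axis world coordinates (broadcast)."""
    sq = (
        (((axes[0] - center[0]) / semiaxes[0]) ** 2)[:, None, None]
        + (((axes[1] - center[1]) / semiaxes[1]) ** 2)[None, :, None]
        + (((axes[2] - center[2]) / semiaxes[2]) ** 2)[None, None, :]
    )
    return sq <= 1.0


def _radius_sq(axes: list[np.ndarray], center) -> np.ndarray:
    return (
        ((axes[0] - center[0]) ** 2)[:, None, None]
        + ((axes[1] - center[1]) ** 2)[None, :, None]
        + ((axes[2] - center[2]) ** 2)[None, None, :]
    )


def _lung_centers(config: PhantomConfig) -> list[np.ndarray]:
    c = config.center_mm
    return [
        c + np.array([-config.lung_offset_mm, 0.0, 0.0]),
        c + np.array([+config.lung_offset_mm, 0.0, 0.0]),
    ]


def lung_mask_truth(config: PhantomConfig) -> np.ndarray:
    """Analytic (noise-free) lung compartment mask of the phantom."""
    axes = ImageVolume(
        np.zeros(config.shape), config.spacing
    ).axis_world_coords()
    mask = np.zeros(config.shape, dtype=bool)
    for center in _lung_centers(config):
        mask |= _ellipsoid(axes, center, config.lung_semiaxes)
    return mask


def generate_dose_block(config: PhantomConfig) -> ImageVolume:
    """SBRT-like dose block on a 1 mm grid centered at the isocenter.

    Dose falls off radially as ``Dmax * exp(-ln2 * (r/r50)**q)`` -- a
    generalized-Gaussian surrogate for a sharply conformal SBRT dose
    distribution (it is not a beam-geometry simulation; only the steep
    monotone 0-Dmax gradient matters downstream).
    """
    size = config.dose_block_size_mm
    n = int(round(size))  # 1 x 1 x 1 mm grid
    if n % 2 == 0:  # odd count puts a voxel center exactly on the isocenter
        n += 1
    iso = config.isocenter
    origin = iso - (n - 1) / 2.0
    vol_extent_lo = np.zeros(3)
    vol_extent_hi = (np.asarray(config.shape) - 1) * np.asarray(config.spacing)
    if np.any(origin < vol_extent_lo - 1e-9) or np.any(
        origin + n - 1 > vol_extent_hi + 1e-9
    ):
        raise ConfigurationError(
            f"dose block ({size} mm at isocenter {tuple(iso)}) extends outside "
            f"the CT volume"
        )
    dose_vol = ImageVolume(
        np.zeros((n, n, n)), (1.0, 1.0, 1.0), tuple(origin), kind="Gy"
    )
    r = np.sqrt(_radius_sq(dose_vol.axis_world_coords(), iso))
    dose_vol.data = config.dmax_gy * np.exp(
        -_LN2 * (r / config.r50_mm) ** config.falloff_exponent
    )
    return dose_vol


def generate_ct_pair(
    config: PhantomConfig,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, PhantomTruth]:
    """Planning CT, mis-aligned follow-up CT, dose block, and ground truth.

    The follow-up scan is built in the planning frame as planning +
    ``delta_hu_max * P_true(dose)`` inside the lung compartment (with
    independent noise), then resampled under the configured
    mis-alignment, so that registering follow-up to planning should
    recover ``config.misalignment``.
    """
    rng = np.random.default_rng(config.seed)
    vol = ImageVolume(np.zeros(config.shape), config.spacing, kind="HU")
    axes = vol.axis_world_coords()

    body = _ellipsoid(axes, config.center_mm, config.body_semiaxes)
    lung = lung_mask_truth(config)
    planning_clean = np.full(config.shape, config.air_hu)
    planning_clean[body] = config.body_hu
    planning_clean[lung] = config.lung_hu

    iso = config.isocenter
    if not lung[tuple(np.round(vol.world_to_index(iso)).astype(int))]:
        raise ConfigurationError(f"isocenter {tuple(iso)} is not inside a lung")

    dose_vol = generate_dose_block(config)

    # Dose at each CT voxel (analytic form, so no resampling error here).
    r = np.sqrt(_radius_sq(axes, iso))
    dose_in_ct = config.dmax_gy * np.exp(
        -_LN2 * (r / config.r50_mm) ** config.falloff_exponent
    )

    response = m.evaluate(config.true_model, config.true_params, dose_in_ct)
    followup_clean = planning_clean.copy()
    followup_clean[lung] += config.delta_hu_max * response[lung]

    planning = vol.with_data(
        planning_clean
        + (rng.normal(0.0, config.hu_noise_sd, config.shape) if config.hu_noise_sd else 0.0)
    )
    followup_aligned = (
        followup_clean
        + (rng.normal(0.0, config.hu_noise_sd, config.shape) if config.hu_noise_sd else 0.0)
    )

    # Resample under the mis-alignment: the observed follow-up at x equals
    # the aligned volume at T(x), T mapping follow-up -> planning coords.
    T = config.misalignment
    if T.is_identity:
        followup_data = followup_aligned
    else:
        world = vol.voxel_world_points()
        idx = vol.world_to_index(T.apply(world))
        followup_data = ndimage.map_coordinates(
            followup_aligned,
            np.moveaxis(idx, -1, 0),
            order=1,
            mode="constant",
            cval=config.air_hu,
        ).reshape(config.shape)
    followup = vol.with_data(followup_data)

    truth = PhantomTruth(
        model=m.parse_model_id(config.true_model),
        d50=config.true_d50,
        gamma50=config.true_gamma50,
        delta_hu_max=config.delta_hu_max,
        misalignment=T,
        air_hu=config.air_hu,
        body_hu=config.body_hu,
        lung_hu=config.lung_hu,
        dmax_gy=config.dmax_gy,
        r50_mm=config.r50_mm,
        isocenter_mm=tuple(iso),
        seed=config.seed,
    )
    return planning, followup, dose_vol, truth


def generate_binned_curve(
    model: str,
    params: m.NTCPParams,
    bin_edges,
    noise_sd: float = 0.0,
    seed: int | None = None,
    patient_id: str = "synthetic",
) -> DoseResponseCurve:
    """Pre-binned dose-response curve straight from a model (no imaging).

    Responses are ``P(bin midpoint) + N(0, noise_sd)``; the curve is
    emitted un-normalized (the probabilities already live on the 0-1
    scale).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    mids = 0.5 * (edges[:-1] + edges[1:])
    resp = np.asarray(m.evaluate(model, params, mids), dtype=float)
    if noise_sd:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, resp.size)
    return DoseResponseCurve(
        bin_edges=edges,
        response=resp,
        pixel_count=np.ones(mids.size, dtype=int),
        normalized=False,
        patient_id=patient_id,
    )


def write_phantom(
    config: PhantomConfig, outdir: str | Path, rtdose_dicom: bool = False
) -> dict[str, Path]:
    """Generate a phantom and write volumes (NIfTI), truth (JSON) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planning, followup, dose, truth = generate_ct_pair(config)
    paths = {
        "planning": planning.to_nifti(outdir / "planning.nii.gz"),
        "followup": followup.to_nifti(outdir / "followup.nii.gz"),
        "dose": dose.to_nifti(outdir / "dose.nii.gz"),
        "truth": truth.to_json(outdir / "truth.json"),
        "misalignment": truth.misalignment.to_json(outdir / "misalignment.json"),
    }
    if rtdose_dicom:
        paths["rtdose"] = dose.to_dicom_rtdose(outdir / "rtdose.dcm")
    return paths
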