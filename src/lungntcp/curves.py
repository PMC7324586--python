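"""Pixel-wise HU change, dose binning, per-patient normalization, pooling.

The analysis reduces a registered CT pair plus a dose grid to a
:class:`DoseResponseCurve`: within the lung mask and the dose block,
each pixel's HU change is binned by its local dose into 6-Gy-wide bins
spanning 0-60 Gy, the mean change per bin is normalized to the largest
bin (typically the 54-60 Gy bin), and patient curves are pooled by
per-bin averaging into a cumulative curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyCurveError,
    EmptyOverlapError,
    IncompatibleCurvesError,
    NoResponseError,
)
from .imaging import sample_at
from .volume import ImageVolume, RigidTransform

__all__ = [
    "DEFAULT_BIN_EDGES",
    "DoseResponseCurve",
    "compute_hu_change",
    "bin_curve",
    "normalize_curve",
    "pool_curves",
]

#: 6-Gy-wide bins over 0-60 Gy.
DEFAULT_BIN_EDGES = tuple(float(x) for x in range(0, 66, 6))


@dataclass
class DoseResponseCurve:
    """Binned dose-response data: representative dose vs mean HU change."""

    bin_edges: np.ndarray
    response: np.ndarray
    pixel_count: np.ndarray
    normalized: bool = False
    patient_id: str = ""
    member_mean_dose: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.pixel_count = np.asarray(self.pixel_count, dtype=int)
        nbins = len(self.bin_edges) - 1
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.response) != nbins or len(self.pixel_count) != nbins:
            raise ValueError("response/pixel_count length must be len(bin_edges)-1")
        if np.any(self.pixel_count < 0):
            raise ValueError("pixel counts must be >= 0")

    @property
    def bin_dose(self) -> np.ndarray:
        """Representative dose per bin: the bin midpoint (Gy)."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.pixel_count > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "bin_lo_gy": self.bin_edges[:-1],
                "bin_hi_gy": self.bin_edges[1:],
                "bin_dose_gy": self.bin_dose,
                "response": self.response,
                "pixel_count": self.pixel_count,
                "normalized": self.normalized,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseCurve":
        df = pd.read_csv(path)
        edges = np.append(df["bin_lo_gy"].to_numpy(), df["bin_hi_gy"].iloc[-1])
        return cls(
            bin_edges=edges,
            response=df["response"].to_numpy(),
            pixel_count=df["pixel_count"].to_numpy(),
            normalized=bool(df["normalized"].iloc[0]),
            patient_id=str(df["patient_id"].iloc[0]) if len(df) else "",
        )


def compute_hu_change(
    followup: ImageVolume,
    planning: ImageVolume,
    registration: RigidTransform,
    mode: str = "pixelwise",
    baseline_mask: np.ndarray | None = None,
) -> ImageVolume:
    """HU change of the follow-up CT relative to planning, on the follow-up grid.

    ``mode='pixelwise'`` (default): for each follow-up voxel at world
    position x, subtract the planning CT trilinearly sampled at the
    registered position T(x).  ``mode='block_mean'``: subtract a single
    scalar baseline, the mean registered planning HU over
    ``baseline_mask`` (normally lung with valid dose).
    """
    if followup.kind != "HU" or planning.kind != "HU":
        raise ValueError("compute_hu_change expects two CT (HU) volumes")
    world = followup.voxel_world_points()
    planning_hu = sample_at(planning, registration.apply(world)).reshape(
        followup.shape
    )
    if not np.isfinite(planning_hu).any():
        raise EmptyOverlapError("registration maps all voxels outside planning CT")
    if mode == "pixelwise":
        delta = followup.data.astype(float) - planning_hu
    elif mode == "block_mean":
        sel = (
            np.isfinite(planning_hu)
            if baseline_mask is None
            else baseline_mask & np.isfinite(planning_hu)
        )
        if not sel.any():
            raise EmptyOverlapError("no voxels available for the block-mean baseline")
        delta = followup.data.astype(float) - planning_hu[sel].mean()
        delta[~np.isfinite(planning_hu)] = np.nan
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return followup.with_data(delta, kind="HU")


def bin_curve(
    delta: ImageVolume,
    dose: ImageVolume,
    mask: ImageVolume,
    bin_edges=DEFAULT_BIN_EDGES,
    clamp_high: bool = True,
    patient_id: str = "",
) -> DoseResponseCurve:
    """Bin masked pixel HU changes by local dose.

    Membership uses half-open intervals [lo, hi); doses at or above the
    top edge are clamped into the top bin by default (``clamp_high=False``
    excludes them).  Sentinel (NaN) doses and NaN deltas are dropped.
    """
    if not (delta.same_geometry(dose) and delta.same_geometry(mask)):
        raise ValueError("delta, dose and mask must share geometry")
    edges = np.asarray(bin_edges, dtype=float)
    m = mask.data.astype(bool)
    d = dose.data
    v = delta.data
    valid = m & np.isfinite(d) & np.isfinite(v)
    dv, vv = d[valid], v[valid]
    if clamp_high:
        sel = (dv >= edges[0])
        dv_b = np.minimum(dv, np.nextafter(edges[-1], -np.inf))
    else:
        sel = (dv >= edges[0]) & (dv < edges[-1])
        dv_b = dv
    dv_b, vv = dv_b[sel], vv[sel]
    if dv_b.size == 0:
        raise EmptyCurveError("no masked pixels with valid dose fall in the bins")
    which = np.digitize(dv_b, edges) - 1  # in [0, nbins-1] after clamping
    nbins = len(edges) - 1
    counts = np.bincount(which, minlength=nbins)
    sums = np.bincount(which, weights=vv, minlength=nbins)
    dose_sums = np.bincount(which, weights=dv_b, minlength=nbins)
    with np.errstate(invalid="ignore"):
        response = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        member_mean = np.where(counts > 0, dose_sums / np.maximum(counts, 1), np.nan)
    return DoseResponseCurve(
        bin_edges=edges,
        response=response,
        pixel_count=counts,
        normalized=False,
        patient_id=patient_id,
        member_mean_dose=member_mean,
    )


def normalize_curve(curve: DoseResponseCurve) -> DoseResponseCurve:
    """Scale responses so the largest bin equals 1 (idempotent)."""
    resp = np.where(curve.nonempty, curve.response, np.nan)
    peak = np.nanmax(resp) if np.isfinite(resp).any() else np.nan
    if not np.isfinite(peak) or peak <= 0:
        raise NoResponseError(
            "maximum bin response is not positive; no detectable change to scale by"
        )
    return replace(curve, response=curve.response / peak, normalized=True)


def pool_curves(curves: list[DoseResponseCurve]) -> DoseResponseCurve:
    """Average patient-normalized curves bin-by-bin into a cumulative curve.

    Each bin averages the curves that have pixels in it; the pooled curve
    is renormalized so its own maximum bin equals 1.
    """
    if not curves:
        raise IncompatibleCurvesError("need at least one curve")
    edges = curves[0].bin_edges
    for c in curves[1:]:
        if not np.array_equal(c.bin_edges, edges):
            raise IncompatibleCurvesError("curves have mismatched bin edges")
    for c in curves:
        if not c.normalized:
            raise ValueError("pool_curves requires normalized curves")
    resp = np.stack([c.response for c in curves])
    have = np.stack([c.nonempty for c in curves])
    counts = have.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(
            counts > 0,
            np.where(have, resp, 0.0).sum(axis=0) / np.maximum(counts, 1),
            np.nan,
        )
    pooled = DoseResponseCurve(
        bin_edges=edges,
        response=mean,
        pixel_count=counts,
        normalized=False,
        patient_id="pooled",
    )
    return normalize_curve(pooled)
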