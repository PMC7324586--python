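"""Lung segmentation, rigid NCC registration, and dose-grid resampling.

The registration convention used throughout: ``register_rigid(fixed,
moving)`` returns the :class:`~lungntcp.volume.RigidTransform` ``T``
mapping fixed-frame world coordinates to moving-frame world
coordinates, i.e. the transform under which ``moving`` sampled at
``T(x)`` best matches ``fixed(x)``.  In the analysis pipeline the
follow-up CT is the fixed image and the planning CT the moving one, so
``T`` carries follow-up coordinates into planning space -- the map
needed both to difference HU values and to pull the planned dose grid
onto the follow-up image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .exceptions import EmptyOverlapError, RegistrationError, SegmentationError
from .volume import ImageVolume, RigidTransform

__all__ = ["segment_lungs", "register_rigid", "map_dose_to_followup", "sample_at"]


def sample_at(
    volume: ImageVolume, world_points: np.ndarray, order: int = 1
) -> np.ndarray:
    """Interpolate a volume at world positions (trilinear by default).

    Points outside the grid return NaN.
    """
    idx = volume.world_to_index(world_points)  # (..., 3)
    coords = np.moveaxis(idx, -1, 0)
    values = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float),
        coords,
        order=order,
        mode="constant",
        cval=np.nan,
    )
    return values


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_lungs(
    ct: ImageVolume,
    hu_threshold: float = -400.0,
    min_component_volume_cm3: float = 50.0,
    closing_radius_mm: float = 3.0,
) -> ImageVolume:
    """Threshold-and-morphology lung segmentation of a chest CT.

    Voxels below ``hu_threshold`` are candidate air/lung; connected
    components touching the in-plane (x/y) volume boundary are discarded
    as external air; components smaller than ``min_component_volume_cm3``
    are dropped; the survivors are closed with a ball of
    ``closing_radius_mm`` and holes are filled slice-by-slice so dense
    structures (vessels, nodules) inside the lung border stay included.
    """
    if ct.kind != "HU":
        raise ValueError("segment_lungs expects a CT (HU) volume")
    binary = ct.data < hu_threshold
    labels, n = ndimage.label(binary)
    if n == 0:
        raise SegmentationError("no voxels below threshold")

    # External air: any component present on an in-plane boundary face.
    edge_labels = np.unique(
        np.concatenate(
            [
                labels[0, :, :].ravel(),
                labels[-1, :, :].ravel(),
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
            ]
        )
    )
    edge_labels = edge_labels[edge_labels > 0]
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    sizes_mm3 = sizes * ct.voxel_volume_mm3
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[edge_labels] = False
    keep[1:] &= sizes_mm3 >= min_component_volume_cm3 * 1000.0
    mask = keep[labels]
    if not mask.any():
        raise SegmentationError(
            "lung segmentation empty after boundary/size filtering",
            component_sizes_mm3=sorted(sizes_mm3.tolist(), reverse=True),
        )

    # Anisotropic ellipsoid footprint approximating a ball of the given
    # physical radius.
    radii = np.maximum(
        np.round(closing_radius_mm / np.asarray(ct.spacing)).astype(int), 0
    )
    if radii.max() > 0:
        grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
        footprint = (
            sum(
                (g / max(r, 1)) ** 2
                for g, r in zip(grids, radii)
            )
            <= 1.0
        )
        mask = ndimage.binary_closing(mask, structure=footprint)
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return ImageVolume(mask, ct.spacing, ct.origin, kind="mask")


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """Coarse-to-fine NCC search settings."""

    levels: tuple[int, ...] = (4, 2, 1)
    coarse_range_mm: float = 20.0
    translation_only: bool = False
    min_overlap_voxels: int = 500
    xatol_mm: float = 0.05
    fatol: float = 1e-7


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _ncc_at(
    fixed_values: np.ndarray,
    fixed_points: np.ndarray,
    moving: ImageVolume,
    transform: RigidTransform,
    min_overlap: int,
) -> float:
    sampled = sample_at(moving, transform.apply(fixed_points))
    valid = np.isfinite(sampled)
    if valid.sum() < min_overlap:
        return -np.inf
    return _ncc(fixed_values[valid], sampled[valid])


def _level_points(fixed: ImageVolume, level: int) -> tuple[np.ndarray, np.ndarray]:
    """Stride-subsampled fixed voxel values and world coordinates."""
    sl = (slice(None, None, level),) * 3
    values = fixed.data[sl].astype(float).ravel()
    axes = [
        fixed.origin[a] + np.arange(0, fixed.shape[a], level) * fixed.spacing[a]
        for a in range(3)
    ]
    shape = tuple(len(a) for a in axes)
    grid = np.empty(shape + (3,))
    grid[..., 0] = axes[0][:, None, None]
    grid[..., 1] = axes[1][None, :, None]
    grid[..., 2] = axes[2][None, None, :]
    return values, grid.reshape(-1, 3)


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig | None = None,
) -> tuple[RigidTransform, float]:
    """Rigid-body registration maximizing normalized cross-correlation.

    Coarse-to-fine: an exhaustive translation grid (+/- ``coarse_range_mm``)
    at the coarsest subsampling level seeds a Nelder-Mead refinement of
    the 6 (or, with ``translation_only``, 3) rigid parameters at each
    successively finer level.  Returns the transform (fixed -> moving
    world coordinates) and the achieved NCC at full resolution.
    """
    cfg = config or RegistrationConfig()
    center = tuple(fixed.center_world)
    min_ov = cfg.min_overlap_voxels

    def make_transform(params: np.ndarray) -> RigidTransform:
        if cfg.translation_only:
            return RigidTransform(tuple(params[:3]), (0.0, 0.0, 0.0), center)
        return RigidTransform(tuple(params[:3]), tuple(params[3:6]), center)

    nparams = 3 if cfg.translation_only else 6
    best = np.zeros(nparams)

    levels = tuple(cfg.levels)
    # Coarse exhaustive translation search at the first level.  On
    # congruent grids integer-voxel shifts reduce to array slicing.
    level0 = levels[0]
    min_ov_level = max(min_ov // level0**3, 8)
    best_ncc = -np.inf
    congruent = (
        np.allclose(fixed.spacing, moving.spacing)
        and np.allclose(fixed.origin, moving.origin)
        and fixed.shape == moving.shape
    )
    if congruent:
        f_ds = fixed.data[::level0, ::level0, ::level0].astype(float)
        m_ds = moving.data[::level0, ::level0, ::level0].astype(float)
        spac = np.asarray(fixed.spacing) * level0
        kmax = np.floor(cfg.coarse_range_mm / spac).astype(int)
        for kx in range(-kmax[0], kmax[0] + 1):
            for ky in range(-kmax[1], kmax[1] + 1):
                for kz in range(-kmax[2], kmax[2] + 1):
                    sl_f, sl_m = [], []
                    for k, n in zip((kx, ky, kz), f_ds.shape):
                        sl_f.append(slice(max(0, -k), n - max(0, k)))
                        sl_m.append(slice(max(0, k), n - max(0, -k)))
                    a = f_ds[tuple(sl_f)]
                    if a.size < min_ov_level:
                        continue
                    v = _ncc(a.ravel(), m_ds[tuple(sl_m)].ravel())
                    if v > best_ncc:
                        cand = np.zeros(nparams)
                        cand[:3] = np.array([kx, ky, kz]) * spac
                        best_ncc, best = v, cand
    else:
        values, points = _level_points(fixed, level0)
        step = float(min(fixed.spacing)) * level0
        offsets = np.arange(
            -cfg.coarse_range_mm, cfg.coarse_range_mm + step / 2, step
        )
        for tx in offsets:
            for ty in offsets:
                for tz in offsets:
                    cand = np.zeros(nparams)
                    cand[:3] = (tx, ty, tz)
                    v = _ncc_at(
                        values, points, moving, make_transform(cand), min_ov_level
                    )
                    if v > best_ncc:
                        best_ncc, best = v, cand
    if not np.isfinite(best_ncc):
        raise RegistrationError(
            f"no translation within +/-{cfg.coarse_range_mm} mm has at least "
            f"{min_ov_level} overlapping voxels"
        )

    # Simplex refinement at every level, coarsest to finest.  Tolerances
    # and the initial simplex step scale with the level, so the finest
    # level only polishes the coarser optimum.
    for level in levels:
        values, points = _level_points(fixed, level)
        min_ov_level = max(min_ov // level**3, 8)

        def objective(p: np.ndarray) -> float:
            v = _ncc_at(values, points, moving, make_transform(p), min_ov_level)
            return -v if np.isfinite(v) else 1.0

        step = np.full(nparams, 0.5 * level * float(min(fixed.spacing)))
        if nparams == 6:
            step[3:] = 0.25 * level  # degrees
        simplex = np.vstack([best, best + np.diag(step)])
        res = optimize.minimize(
            objective,
            best,
            method="Nelder-Mead",
            options={
                "xatol": cfg.xatol_mm * level,
                "fatol": cfg.fatol * level,
                "maxiter": 80 * nparams,
                "initial_simplex": simplex,
            },
        )
        if -res.fun >= _ncc_at(
            values, points, moving, make_transform(best), min_ov_level
        ):
            best = res.x

    # Guarantee: never worse than the identity transform at full resolution.
    values, points = _level_points(fixed, 1)
    final = make_transform(best)
    ncc_final = _ncc_at(values, points, moving, final, min_ov)
    identity = RigidTransform(center=center)
    ncc_id = _ncc_at(values, points, moving, identity, min_ov)
    if ncc_id > ncc_final:
        return identity, ncc_id
    if not np.isfinite(ncc_final):
        raise RegistrationError("registration overlap below the voxel-count floor")
    return final, ncc_final


# ---------------------------------------------------------------------------
# Dose resampling
# ---------------------------------------------------------------------------

def map_dose_to_followup(
    dose: ImageVolume,
    registration: RigidTransform,
    followup_geometry: ImageVolume,
    interpolation: str = "nearest",
) -> ImageVolume:
    """Pull the planning-frame dose grid onto the follow-up voxel grid.

    Each follow-up voxel center is mapped into planning coordinates by
    ``registration`` and assigned the nearest dose-grid sample (the
    default) or a trilinear interpolant.  Voxels landing outside the
    dose block get NaN and are excluded downstream.
    """
    if dose.kind != "Gy":
        raise ValueError("expected a dose (Gy) volume")
    planning_pts = registration.apply(followup_geometry.voxel_world_points())
    if interpolation == "nearest":
        idx = np.rint(
            (planning_pts - np.asarray(dose.origin)) / np.asarray(dose.spacing)
        ).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(dose.shape)), axis=1)
        out = np.full(idx.shape[0], np.nan)
        ii = idx[inside]
        out[inside] = dose.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    elif interpolation == "trilinear":
        out = sample_at(dose, planning_pts, order=1)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if not np.isfinite(out).any():
        raise EmptyOverlapError("no follow-up voxel maps inside the dose block")
    return ImageVolume(
        out.reshape(followup_geometry.shape),
        followup_geometry.spacing,
        followup_geometry.origin,
        kind="Gy",
    )
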