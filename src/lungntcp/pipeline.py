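"""End-to-end orchestration: segment -> register -> map dose -> bin -> fit.

:func:`run_analysis` wires the stages in study order and returns every
intermediate artifact; the CLI and the robustness experiment are thin
layers over it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import models as m
from .curves import (
    DEFAULT_BIN_EDGES,
    DoseResponseCurve,
    bin_curve,
    compute_hu_change,
    normalize_curve,
)
from .fitting import ComparisonReport, compare_models
from .imaging import (
    RegistrationConfig,
    map_dose_to_followup,
    register_rigid,
    segment_lungs,
)
from .volume import ImageVolume, RigidTransform

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "curve_from_transform"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Stage parameters for one planning/follow-up/dose analysis."""

    hu_threshold: float = -400.0
    min_component_volume_cm3: float = 50.0
    closing_radius_mm: float = 3.0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    bin_edges: tuple = DEFAULT_BIN_EDGES
    clamp_high: bool = True
    baseline_mode: str = "pixelwise"
    models: tuple = m.MODEL_IDS
    patient_id: str = "patient"


@dataclass
class AnalysisResult:
    """All artifacts of one end-to-end run."""

    mask: ImageVolume
    transform: RigidTransform
    ncc: float
    mapped_dose: ImageVolume
    delta: ImageVolume
    curve: DoseResponseCurve
    normalized_curve: DoseResponseCurve
    report: ComparisonReport
    timings_s: dict


def curve_from_transform(
    planning: ImageVolume,
    followup: ImageVolume,
    dose: ImageVolume,
    transform: RigidTransform,
    mask: ImageVolume,
    config: AnalysisConfig,
) -> DoseResponseCurve:
    """Dose mapping -> HU change -> binning -> normalization for one transform.

    The post-registration tail of the pipeline, reused by the
    registration-error robustness experiment.
    """
    mapped = map_dose_to_followup(dose, transform, followup)
    delta = compute_hu_change(
        followup,
        planning,
        transform,
        mode=config.baseline_mode,
        baseline_mask=mask.data.astype(bool) & np.isfinite(mapped.data),
    )
    curve = bin_curve(
        delta,
        mapped,
        mask,
        bin_edges=config.bin_edges,
        clamp_high=config.clamp_high,
        patient_id=config.patient_id,
    )
    return normalize_curve(curve)


def run_analysis(
    planning: ImageVolume,
    followup: ImageVolume,
    dose: ImageVolume,
    config: AnalysisConfig | None = None,
    transform: RigidTransform | None = None,
) -> AnalysisResult:
    """Run the full study pipeline on one scan pair.

    ``transform`` (follow-up -> planning world coordinates) skips the
    registration stage when supplied.
    """
    cfg = config or AnalysisConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    mask = segment_lungs(
        followup,
        hu_threshold=cfg.hu_threshold,
        min_component_volume_cm3=cfg.min_component_volume_cm3,
        closing_radius_mm=cfg.closing_radius_mm,
    )
    timings["segment"] = time.perf_counter() - t0
    log.info("segmented lungs: %d voxels", int(mask.data.sum()))

    t0 = time.perf_counter()
    if transform is None:
        transform, ncc = register_rigid(followup, planning, cfg.registration)
        log.info("registration NCC %.4f, transform %s", ncc, transform.to_dict())
    else:
        ncc = float("nan")
    timings["register"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mapped = map_dose_to_followup(dose, transform, followup)
    delta = compute_hu_change(
        followup,
        planning,
        transform,
        mode=cfg.baseline_mode,
        baseline_mask=mask.data.astype(bool) & np.isfinite(mapped.data),
    )
    curve = bin_curve(
        delta,
        mapped,
        mask,
        bin_edges=cfg.bin_edges,
        clamp_high=cfg.clamp_high,
        patient_id=cfg.patient_id,
    )
    normalized = normalize_curve(curve)
    timings["dose_response"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = compare_models(normalized, model_ids=cfg.models)
    timings["fit"] = time.perf_counter() - t0
    for name, dt in timings.items():
        log.info("stage %s: %.2f s", name, dt)

    return AnalysisResult(
        mask=mask,
        transform=transform,
        ncc=ncc,
        mapped_dose=mapped,
        delta=delta,
        curve=curve,
        normalized_curve=normalized,
        report=report,
        timings_s=timings,
    )
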