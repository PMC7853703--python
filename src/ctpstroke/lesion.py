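"""Core / penumbra classification, artifact removal and volumetry.

Hypoperfused tissue is identified by the relative-MTT rule (MTT above 145 %
of the contralateral healthy reference) and split into irreversibly
infarcted core (CBV below 2.0 ml/100g) and salvageable penumbra (CBV at or
above the cutoff).  The contralateral reference is the median MTT of the
hemisphere opposite the lesion.  Artifact removal always clips to the brain
mask and deletes connected components smaller than a minimum volume; for
noisy acquisitions an optional morphological repair (closing plus enclosed
hole filling) cleans speckle misses inside the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ctpstroke.perfusion import PerfusionMaps

__all__ = [
    "ThresholdConfig",
    "LesionSegmentation",
    "VolumeReport",
    "contralateral_reference",
    "classify_voxels",
    "remove_artifacts",
    "compute_volumes",
    "segment_lesion",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Segmentation thresholds and artifact-removal settings.

    ``mtt_relative`` multiplies the contralateral reference MTT (1.45 is the
    classical relative threshold); ``cbv_absolute`` is in ml/100g.  A voxel
    with CBV exactly at the cutoff is assigned to penumbra (documented
    tie-break: the published rule uses two strict inequalities and leaves
    the boundary open).  ``closing_iterations``/``fill_holes`` enable the
    morphological repair used for noisy data; both default off so the pure
    threshold rule is what the defaults compute.
    """

    mtt_relative: float = 1.45
    cbv_absolute: float = 2.0
    min_component_ml: float = 0.5
    closing_iterations: int = 0
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if self.mtt_relative <= 1.0:
            raise ValueError("relative MTT threshold must exceed 1")
        if self.cbv_absolute <= 0:
            raise ValueError("CBV threshold must be positive")


@dataclass
class LesionSegmentation:
    """Disjoint core and penumbra masks plus the reference MTT used."""

    core: np.ndarray
    penumbra: np.ndarray
    reference_mtt: float


@dataclass(frozen=True)
class VolumeReport:
    """Lesion volumes in ml; mismatch = penumbra / total (1.0 if total = 0)."""

    total_ml: float
    core_ml: float
    penumbra_ml: float
    mismatch: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "total_ml": self.total_ml,
            "core_ml": self.core_ml,
            "penumbra_ml": self.penumbra_ml,
            "mismatch": self.mismatch,
            "degenerate": self.degenerate,
        }


def contralateral_reference(
    mtt: np.ndarray,
    brain_mask: np.ndarray,
    midline_index: int,
    lesion_side: str,
    valid: np.ndarray | None = None,
) -> float:
    """Median MTT over valid brain voxels of the hemisphere opposite the lesion."""
    if lesion_side not in ("left", "right"):
        raise ValueError("lesion side must be 'left' or 'right'")
    idx = np.arange(mtt.shape[0])[:, None, None]
    contra = idx < midline_index if lesion_side == "right" else idx >= midline_index
    sel = np.broadcast_to(contra, mtt.shape) & np.asarray(brain_mask, dtype=bool)
    if valid is not None:
        sel = sel & np.asarray(valid, dtype=bool)
    if not sel.any():
        raise ValueError("contralateral hemisphere contains no valid brain voxels")
    return float(np.median(np.asarray(mtt, dtype=float)[sel]))


def classify_voxels(
    maps: PerfusionMaps,
    reference_mtt: float,
    config: ThresholdConfig = ThresholdConfig(),
    brain_mask: np.ndarray | None = None,
) -> LesionSegmentation:
    """Threshold rule: hypoperfused if MTT > mtt_relative * reference;
    core if additionally CBV < cbv_absolute, else penumbra.

    Invalid voxels are excluded from both masks; the masks are disjoint by
    construction.
    """
    if reference_mtt <= 0:
        raise ValueError("reference MTT must be positive")
    hypo = maps.valid & (maps.mtt > config.mtt_relative * reference_mtt)
    if brain_mask is not None:
        hypo = hypo & np.asarray(brain_mask, dtype=bool)
    core = hypo & (maps.cbv < config.cbv_absolute)
    penumbra = hypo & ~core
    return LesionSegmentation(core=core, penumbra=penumbra, reference_mtt=reference_mtt)


def _size_filter(mask: np.ndarray, min_ml: float, voxel_ml: float) -> np.ndarray:
    if min_ml <= 0 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes * voxel_ml >= min_ml])
    return keep[labels]


def remove_artifacts(
    segmentation: LesionSegmentation,
    spacing_mm,
    config: ThresholdConfig = ThresholdConfig(),
    brain_mask: np.ndarray | None = None,
    cbv: np.ndarray | None = None,
) -> LesionSegmentation:
    """Clean the union mask and re-split into core and penumbra.

    Steps: clip to the brain mask; delete 26-connected components of the
    union smaller than ``min_component_ml``; optionally close and fill
    enclosed holes (slice-wise then volumetrically).  When a CBV map is
    supplied the repaired union is re-split by the CBV rule, so voxels
    recovered by the repair land in the correct compartment; otherwise
    voxels keep their incoming class and repaired additions join the
    penumbra.
    """
    voxel_ml = float(np.prod(spacing_mm)) / 1000.0
    union = segmentation.core | segmentation.penumbra
    if brain_mask is not None:
        union = union & np.asarray(brain_mask, dtype=bool)
    union = _size_filter(union, config.min_component_ml, voxel_ml)
    if config.closing_iterations > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        union = ndimage.binary_closing(
            union, structure=structure, iterations=config.closing_iterations
        )
    if config.fill_holes:
        filled = union.copy()
        for z in range(filled.shape[2]):
            filled[:, :, z] = ndimage.binary_fill_holes(filled[:, :, z])
        union = ndimage.binary_fill_holes(filled)
    if brain_mask is not None:
        union = union & np.asarray(brain_mask, dtype=bool)
    if cbv is not None:
        core = union & (np.asarray(cbv, dtype=float) < config.cbv_absolute)
    else:
        core = union & segmentation.core
    penumbra = union & ~core
    return LesionSegmentation(
        core=core, penumbra=penumbra, reference_mtt=segmentation.reference_mtt
    )


def compute_volumes(segmentation: LesionSegmentation, spacing_mm) -> VolumeReport:
    """Integrate mask volumes (voxel count x voxel volume, in ml)."""
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    core_ml = float(segmentation.core.sum()) * voxel_ml
    pen_ml = float(segmentation.penumbra.sum()) * voxel_ml
    total = core_ml + pen_ml
    if total > 0:
        mismatch = pen_ml / total
        degenerate = False
    else:
        mismatch = 1.0
        degenerate = True
    return VolumeReport(
        total_ml=total,
        core_ml=core_ml,
        penumbra_ml=pen_ml,
        mismatch=mismatch,
        degenerate=degenerate,
    )


def segment_lesion(
    maps: PerfusionMaps,
    brain_mask: np.ndarray,
    midline_index: int,
    lesion_side: str,
    spacing_mm,
    config: ThresholdConfig = ThresholdConfig(),
) -> tuple[LesionSegmentation, VolumeReport]:
    """Reference -> classification -> artifact removal -> volumes."""
    ref = contralateral_reference(maps.mtt, brain_mask, midline_index, lesion_side, maps.valid)
    seg = classify_voxels(maps, ref, config, brain_mask)
    seg = remove_artifacts(seg, spacing_mm, config, brain_mask, cbv=maps.cbv)
    return seg, compute_volumes(seg, spacing_mm)


def repair_config(config: ThresholdConfig) -> ThresholdConfig:
    """Copy of a threshold config with morphological repair enabled."""
    from dataclasses import replace

    return replace(config, closing_iterations=max(config.closing_iterations, 1), fill_holes=True)
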