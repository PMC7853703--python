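"""Final-infarct segmentation on follow-up non-enhanced CT.

A semi-automatic seeded region-growing segmentation: breadth-first growth
from one or more seed voxels, accepting a neighbour when its intensity lies
within a tolerance of the running mean of the region accepted so far.  The
manual-outlining step of the clinical workflow is replaced by an optional
morphological closing and a guard on the maximum region size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RegionGrowConfig", "segment_infarct", "infarct_volume"]

_NEIGHBOURS_6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
_NEIGHBOURS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


@dataclass(frozen=True)
class RegionGrowConfig:
    """Growth criterion and guards.

    tolerance_hu:
        A neighbour is accepted when |HU - running mean of the region| is at
        most this value (adaptive similarity criterion).
    connectivity:
        6 (faces) or 26 (faces, edges, corners); growth and the final
        connectivity guarantee use the same neighbourhood.
    max_fraction:
        Growth stops (and the result is flagged) once the region exceeds
        this fraction of the brain mask - the guard against flood-fill on
        near-uniform images.
    closing_radius:
        Radius (voxels) of a binary closing applied to the grown mask; 0
        disables it.
    """

    tolerance_hu: float = 8.0
    connectivity: int = 6
    max_fraction: float = 0.5
    closing_radius: int = 1

    def __post_init__(self) -> None:
        if self.tolerance_hu < 0:
            raise ValueError("tolerance must be non-negative")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if not (0 < self.max_fraction <= 1):
            raise ValueError("max fraction must lie in (0, 1]")


def segment_infarct(
    ct: np.ndarray,
    seeds,
    brain_mask: np.ndarray | None = None,
    config: RegionGrowConfig = RegionGrowConfig(),
) -> tuple[np.ndarray, bool]:
    """Grow the infarct mask from seed voxels; returns ``(mask, flagged)``.

    Growth is deterministic: FIFO breadth-first order with a fixed neighbour
    ordering.  ``flagged`` is True when growth was stopped by the maximum
    region-size guard.  Seeds outside the volume (or outside the brain mask)
    raise.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.ndim != 3:
        raise ValueError("expected a 3-D CT volume")
    if brain_mask is None:
        brain_mask = np.ones(ct.shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)

    seeds = [tuple(int(c) for c in s) for s in np.atleast_2d(np.asarray(seeds, dtype=int))]
    if not seeds:
        raise ValueError("at least one seed is required")
    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, ct.shape)):
            raise ValueError(f"seed {s} outside the volume")
        if not brain_mask[s]:
            raise ValueError(f"seed {s} outside the brain mask")

    neighbours = _NEIGHBOURS_6 if config.connectivity == 6 else _NEIGHBOURS_26
    max_voxels = max(int(config.max_fraction * brain_mask.sum()), 1)

    mask = np.zeros(ct.shape, dtype=bool)
    queue: deque = deque()
    running_sum = 0.0
    count = 0
    for s in seeds:
        if not mask[s]:
            mask[s] = True
            queue.append(s)
            running_sum += ct[s]
            count += 1

    flagged = False
    while queue:
        if count >= max_voxels:
            flagged = True
            break
        x, y, z = queue.popleft()
        mean = running_sum / count
        for dx, dy, dz in neighbours:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < ct.shape[0] and 0 <= ny < ct.shape[1] and 0 <= nz < ct.shape[2]):
                continue
            if mask[nx, ny, nz] or not brain_mask[nx, ny, nz]:
                continue
            if abs(ct[nx, ny, nz] - mean) <= config.tolerance_hu:
                mask[nx, ny, nz] = True
                queue.append((nx, ny, nz))
                running_sum += ct[nx, ny, nz]
                count += 1

    if config.closing_radius > 0 and mask.any():
        structure = ndimage.generate_binary_structure(3, 1)
        closed = ndimage.binary_closing(
            mask, structure=structure, iterations=config.closing_radius
        )
        mask = closed & brain_mask

    return mask, flagged


def infarct_volume(mask: np.ndarray, spacing_mm) -> float:
    """Mask volume in ml (voxel count times voxel volume)."""
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    return float(np.asarray(mask, dtype=bool).sum()) * float(np.prod(spacing)) / 1000.0
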