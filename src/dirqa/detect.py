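"""Hotspot detection and plausibility classification of a vortex map.

Regions where the curl magnitude exceeds a threshold are labelled as
connected components (6- or 26-connectivity) and quantified by size, peak
intensity, and intensity-weighted physical centroid.  The global maximum
is classified against configurable plausibility bands: clinically valid
solutions typically show curl magnitudes between 0 and 5 while
non-physical solutions reach 5–10 and beyond; values above 3 flag regions
the registration struggled with, giving a three-way verdict

    plausible   : max <  borderline_min (default 3.0)
    borderline  : borderline_min <= max < valid_max (default 5.0)
    nonphysical : max >= valid_max

The banded verdict is deliberately global; whether a hotspot matters
clinically also depends on *where* it sits, so ``structure_report`` gives
per-structure peaks and distances for the reviewing physicist — hotspots
far from the target and critical organs may be acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .curl import VortexMap, VortexStats
from .errors import GridError
from .grids import Grid

__all__ = [
    "VortexRegion",
    "Bands",
    "PlausibilityVerdict",
    "StructureFinding",
    "detect_regions",
    "classify",
    "structure_report",
]

DEFAULT_THRESHOLD = 5.0
DEFAULT_CONNECTIVITY = 26
DEFAULT_MIN_REGION_SIZE = 3


@dataclass(frozen=True)
class VortexRegion:
    """One connected suprathreshold component of a vortex map."""

    label: int
    voxel_count: int
    volume_mm3: float
    peak_value: float
    peak_index: tuple[int, int, int]
    centroid_mm: tuple[float, float, float]
    # voxel indices of the component, kept for mask-intersection queries
    indices: np.ndarray = dc_field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class Bands:
    """Plausibility thresholds on the global vortex-map maximum."""

    valid_max: float = 5.0
    borderline_min: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.borderline_min < self.valid_max):
            raise ValueError(
                "bands must satisfy 0 < borderline_min < valid_max, got "
                f"borderline_min={self.borderline_min}, valid_max={self.valid_max}"
            )


@dataclass(frozen=True)
class StructureFinding:
    """Hotspot findings relative to one named structure mask."""

    structure: str
    peak_inside: float
    distance_mm: float  # nearest region centroid to the mask; inf if no regions
    flagged: bool  # true when any detected region intersects the mask


@dataclass(frozen=True)
class PlausibilityVerdict:
    """Banded classification of one registration solution."""

    category: str  # plausible | borderline | nonphysical
    max_value: float
    n_regions: int
    per_structure: tuple[StructureFinding, ...] = ()


def _structuring_element(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def detect_regions(
    vmap: VortexMap,
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_region_size: int = DEFAULT_MIN_REGION_SIZE,
) -> list[VortexRegion]:
    """Label connected components of ``{map > threshold}``.

    Components smaller than ``min_region_size`` voxels are discarded.
    Labels are assigned in scan order; the returned list is sorted by peak
    value descending, ties broken by ascending label.  Empty list when
    nothing is suprathreshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if min_region_size < 1:
        raise ValueError(f"min_region_size must be >= 1, got {min_region_size}")
    values = vmap.values
    above = values > threshold
    labels, n_labels = ndimage.label(above, structure=_structuring_element(connectivity))
    if n_labels == 0:
        return []

    grid = vmap.grid
    voxel_volume = grid.voxel_volume_mm3
    regions: list[VortexRegion] = []
    for lbl, slc in enumerate(ndimage.find_objects(labels), start=1):
        component = labels[slc] == lbl
        count = int(component.sum())
        if count < min_region_size:
            continue
        local = np.where(component, values[slc], -np.inf)
        peak_local = np.unravel_index(np.argmax(local), local.shape)
        offset = np.array([s.start for s in slc])
        peak_index = tuple(int(p) for p in (offset + np.array(peak_local)))
        coords = np.argwhere(component) + offset  # (n, 3)
        weights = values[tuple(coords.T)]
        centroid_idx = (coords * weights[:, None]).sum(axis=0) / weights.sum()
        centroid_mm = tuple(float(c) for c in grid.index_to_physical(centroid_idx))
        regions.append(
            VortexRegion(
                label=lbl,
                voxel_count=count,
                volume_mm3=count * voxel_volume,
                peak_value=float(values[peak_index]),
                peak_index=peak_index,
                centroid_mm=centroid_mm,
                indices=coords,
            )
        )
    regions.sort(key=lambda r: (-r.peak_value, r.label))
    return regions


def classify(
    stats: VortexStats,
    regions: list[VortexRegion] | None = None,
    bands: Bands = Bands(),
    per_structure: tuple[StructureFinding, ...] = (),
) -> PlausibilityVerdict:
    """Classify a solution from its vortex statistics.

    The category depends on the regions argument only through bookkeeping
    (region count in the verdict); the decision itself is a function of
    ``stats.max`` and the bands alone.
    """
    regions = regions or []
    if stats.max >= bands.valid_max:
        category = "nonphysical"
    elif stats.max >= bands.borderline_min:
        category = "borderline"
    else:
        category = "plausible"
    return PlausibilityVerdict(
        category=category,
        max_value=stats.max,
        n_regions=len(regions),
        per_structure=tuple(per_structure),
    )


def structure_report(
    vmap: VortexMap,
    regions: list[VortexRegion],
    structures: dict[str, np.ndarray],
) -> list[StructureFinding]:
    """Relate detected hotspots to named structure masks.

    For each structure: the peak map value inside the mask, the minimum
    centroid-to-mask distance over regions (0 when a region intersects the
    mask), and an intersection flag.  Distances in mm honour anisotropic
    spacing; with no regions the distance is reported infinite.
    """
    grid = vmap.grid
    findings: list[StructureFinding] = []
    for name, mask in structures.items():
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid.shape:
            raise GridError(
                f"structure {name!r} mask shape {mask.shape} does not match "
                f"map grid {grid.shape}"
            )
        peak_inside = float(vmap.values[mask].max()) if mask.any() else 0.0
        intersects = any(
            bool(mask[tuple(r.indices.T)].any()) for r in regions
        )
        if not regions:
            distance = float("inf")
        elif intersects:
            distance = 0.0
        else:
            # distance from every voxel to the nearest mask voxel, in mm
            dist_map = ndimage.distance_transform_edt(
                ~mask, sampling=grid.spacing
            )
            distance = float(
                min(
                    dist_map[_nearest_index(r.centroid_mm, grid)]
                    for r in regions
                )
            )
        findings.append(
            StructureFinding(
                structure=name,
                peak_inside=peak_inside,
                distance_mm=distance,
                flagged=intersects,
            )
        )
    return findings


def _nearest_index(point_mm: tuple[float, float, float], grid: Grid) -> tuple[int, ...]:
    rel = np.asarray(point_mm) - np.asarray(grid.origin)
    idx = (grid.direction.T @ rel) / np.asarray(grid.spacing)
    idx = np.clip(np.round(idx), 0, np.asarray(grid.shape) - 1)
    return tuple(int(i) for i in idx)
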