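"""Curl of a displacement field and the derived vortex-intensity map.

The rate of microscopic rotation of a displacement field u = (u, v, w) is

    curl u = (dw/dy - dv/dz,  du/dz - dw/dx,  dv/dx - du/dy)

evaluated here by finite differences on the physical grid: second-order
central differences at interior voxels, first-order one-sided differences
at the two boundary slabs of each axis, with step equal to the voxel
spacing in mm of that axis.  A displacement (mm) differentiated over
position (mm) makes the curl dimensionless.

A smooth, anatomically plausible deformation has near-zero curl inside
organs; spinning or tearing motions show up as hotspots of the curl
magnitude.  The *vortex map* is the voxelwise Euclidean norm of the curl
vector; being a norm it is invariant to rigid reorientation of the
patient axes, so the map does not depend on the grid's direction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError
from .grids import Grid, VectorField

__all__ = [
    "partial_derivative",
    "compute_curl",
    "vortex_map",
    "field_stats",
    "CurlField",
    "VortexMap",
    "VortexStats",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class CurlField:
    """Curl vector (cx, cy, cz) per voxel, components in the image axis frame."""

    grid: Grid
    cx: np.ndarray
    cy: np.ndarray
    cz: np.ndarray

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.cx**2 + self.cy**2 + self.cz**2)


@dataclass(frozen=True)
class VortexMap:
    """Non-negative scalar grid of curl magnitudes (dimensionless)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise GridError(
                f"map shape {vals.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise GridError("vortex map contains non-finite values")
        if np.any(vals < 0):
            raise GridError("vortex map contains negative values")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class VortexStats:
    """Summary statistics of a vortex map over an optional mask.

    ``max`` is the primary reported quantity (the global worst-case
    rotation intensity); ``p99`` is provided alongside because the maximum
    is a single-voxel statistic.
    """

    min: float
    max: float
    mean: float
    p99: float
    n_voxels: int


def partial_derivative(
    grid: np.ndarray, axis: str, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Differentiate a scalar grid along a physical axis.

    Central differences ``(f[i+1] - f[i-1]) / (2h)`` at interior voxels and
    one-sided first-order differences at the two boundary slabs, with ``h``
    the mm spacing of ``axis``.  Exact on fields affine in the coordinate;
    central part exact on quadratics.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {tuple(_AXES)}, got {axis!r}")
    ax = _AXES[axis]
    arr = np.asarray(grid, dtype=float)
    if arr.shape[ax] < 2:
        raise GridError(f"axis {axis!r} has fewer than 2 voxels")
    return np.gradient(arr, spacing[ax], axis=ax, edge_order=1)


def compute_curl(field: VectorField) -> CurlField:
    """Assemble the curl vector of a displacement field.

    Anisotropic spacing is honoured per axis; every axis needs at least
    two voxels.
    """
    sp = field.grid.spacing
    u, v, w = field.components
    cx = partial_derivative(w, "y", sp) - partial_derivative(v, "z", sp)
    cy = partial_derivative(u, "z", sp) - partial_derivative(w, "x", sp)
    cz = partial_derivative(v, "x", sp) - partial_derivative(u, "y", sp)
    return CurlField(field.grid, cx, cy, cz)


def vortex_map(field: VectorField) -> VortexMap:
    """Vortex-intensity map: Euclidean norm of the curl vector per voxel."""
    return VortexMap(field.grid, compute_curl(field).magnitude())


def field_stats(vmap: VortexMap, mask: np.ndarray | None = None) -> VortexStats:
    """Summarise a vortex map, optionally restricted to a binary mask.

    The 99th percentile uses linear interpolation between order statistics.
    """
    values = vmap.values
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != values.shape:
            raise GridError(
                f"mask shape {mask.shape} does not match map {values.shape}"
            )
        values = values[mask]
        if values.size == 0:
            raise GridError("mask selects no voxels")
    values = np.ravel(values)
    return VortexStats(
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        p99=float(np.percentile(values, 99.0)),
        n_voxels=int(values.size),
    )
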