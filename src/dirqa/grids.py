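"""Grid geometry and the in-memory containers for fields and volumes.

Everything downstream (curl computation, hotspot detection, synthetic
generators) operates on these containers.  Arrays are indexed ``[i, j, k]``
along the first, second and third physical axes; the physical position of a
voxel is ``origin + direction @ (index * spacing)`` with 0-based indices.
Displacements are stored in millimetres along the physical axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import GridError

__all__ = [
    "Grid",
    "VectorField",
    "ImageVolume",
    "GridCompatibility",
    "check_grids",
]

_ORTHO_TOL = 1e-6
_SPACING_TOL = 1e-6
_ORIGIN_TOL = 1e-3


@dataclass(frozen=True)
class Grid:
    """Regular 3D voxel lattice with physical metadata.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each physical axis, ``(nx, ny, nz)``.
    spacing : tuple of float
        Voxel size in mm per axis; strictly positive.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``.
    direction : ndarray, shape (3, 3)
        Orthonormal matrix whose columns are the physical directions of the
        grid axes.  Identity for axis-aligned volumes.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(
            self, "direction", np.array(self.direction, dtype=float).reshape(3, 3)
        )
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise GridError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.direction)):
            raise GridError("direction matrix contains non-finite entries")
        if not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=_ORTHO_TOL
        ):
            raise GridError("direction matrix is not orthonormal (tol 1e-6)")

    # -- geometry -----------------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map voxel indices (…, 3) to physical mm positions (…, 3)."""
        idx = np.asarray(index, dtype=float)
        scaled = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + scaled @ self.direction.T

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical x, y, z coordinates of every voxel centre (mm).

        Returns three ``shape``-sized arrays.  For identity direction these
        are separable; the general case goes through ``index_to_physical``.
        """
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1)
        pos = self.index_to_physical(idx)
        return pos[..., 0], pos[..., 1], pos[..., 2]

    def with_shape(self, shape: tuple[int, int, int]) -> "Grid":
        return replace(self, shape=tuple(shape))


def _check_array(name: str, arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.shape != shape:
        raise GridError(f"{name} has shape {out.shape}, expected {shape}")
    if not np.all(np.isfinite(out)):
        raise GridError(f"{name} contains non-finite values")
    return out


@dataclass(frozen=True)
class VectorField:
    """Displacement field u = (u, v, w) in mm on a :class:`Grid`.

    Components are stored planar (three separate scalar grids) regardless of
    the on-disk layout; ``u`` displaces along the first physical axis, ``v``
    along the second, ``w`` along the third.
    """

    grid: Grid
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        for name in ("u", "v", "w"):
            object.__setattr__(
                self, name, _check_array(name, getattr(self, name), self.grid.shape)
            )

    @property
    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.u, self.v, self.w

    def as_stack(self) -> np.ndarray:
        """Return an (nx, ny, nz, 3) view-stack of the components."""
        return np.stack([self.u, self.v, self.w], axis=-1)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.u**2 + self.v**2 + self.w**2)

    def __add__(self, other: "VectorField") -> "VectorField":
        _require_same_grid(self.grid, other.grid)
        return VectorField(
            self.grid, self.u + other.u, self.v + other.v, self.w + other.w
        )

    def __mul__(self, scalar: float) -> "VectorField":
        return VectorField(
            self.grid, self.u * scalar, self.v * scalar, self.w * scalar
        )

    __rmul__ = __mul__

    @classmethod
    def zeros(cls, grid: Grid) -> "VectorField":
        z = np.zeros(grid.shape)
        return cls(grid, z, z.copy(), z.copy())


@dataclass(frozen=True)
class ImageVolume:
    """Scalar volume (CT/CBCT-like intensities in HU, or any scalar map)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _check_array("values", self.values, self.grid.shape)
        )

    @classmethod
    def full(cls, grid: Grid, value: float) -> "ImageVolume":
        return cls(grid, np.full(grid.shape, float(value)))


@dataclass(frozen=True)
class GridCompatibility:
    """Per-attribute agreement between two grid headers."""

    same_shape: bool
    same_spacing: bool  # tolerance 1e-6 mm
    same_origin: bool  # tolerance 1e-3 mm

    @property
    def compatible(self) -> bool:
        return self.same_shape and self.same_spacing and self.same_origin


def check_grids(a: Grid, b: Grid) -> GridCompatibility:
    """Compare two grid headers attribute by attribute."""
    return GridCompatibility(
        same_shape=a.shape == b.shape,
        same_spacing=bool(
            np.allclose(a.spacing, b.spacing, rtol=0.0, atol=_SPACING_TOL)
        ),
        same_origin=bool(np.allclose(a.origin, b.origin, rtol=0.0, atol=_ORIGIN_TOL)),
    )


def _require_same_grid(a: Grid, b: Grid) -> None:
    compat = check_grids(a, b)
    if not compat.compatible:
        raise GridError(
            "grids are incompatible: "
            f"shape match={compat.same_shape}, spacing match={compat.same_spacing}, "
            f"origin match={compat.same_origin}"
        )


def require_compatible(a: Grid, b: Grid) -> None:
    """Raise :class:`GridError` unless the two headers match."""
    _require_same_grid(a, b)
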