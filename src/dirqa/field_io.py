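"""Read and write displacement fields and scalar volumes.

Supported dialects are MetaImage (``.mha``/``.mhd``), NRRD (``.nrrd``) and
NIfTI (``.nii``/``.nii.gz``), all through SimpleITK.  Vector data may be
stored either as a genuine 3-component (interleaved) vector image or as a
4D scalar stack with a length-3 component axis (the planar layout common
for NIfTI warps); both are detected from the header and normalised to the
planar in-memory representation of :class:`~dirqa.grids.VectorField`.

SimpleITK array order is (z, y, x); everything here transposes to the
package's (x, y, z) index convention at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError
from .grids import Grid, GridCompatibility, ImageVolume, VectorField, check_grids

__all__ = [
    "read_field",
    "write_field",
    "read_image",
    "write_scalar_map",
    "check_grids",
    "FORMATS",
]

FORMATS = ("metaimage", "nrrd", "nifti")

_EXTENSIONS = {
    "metaimage": (".mha", ".mhd"),
    "nrrd": (".nrrd",),
    "nifti": (".nii", ".nii.gz"),
}


def _resolve_format(path: str | os.PathLike, fmt: str) -> str:
    if fmt == "auto":
        name = str(path).lower()
        for candidate, exts in _EXTENSIONS.items():
            if any(name.endswith(e) for e in exts):
                return candidate
        raise FormatError(f"cannot infer format from file name: {path}")
    if fmt not in FORMATS:
        raise FormatError(
            f"unsupported format {fmt!r}; expected one of {FORMATS} or 'auto'"
        )
    return fmt


def _default_extension(fmt: str) -> str:
    return _EXTENSIONS[fmt][0]


def _read_sitk(path: str | os.PathLike) -> sitk.Image:
    if not Path(path).exists():
        raise FormatError(f"file not found: {path}")
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK message passthrough
        raise FormatError(f"could not read {path}: {exc}") from exc


def _grid_from_sitk(img: sitk.Image) -> Grid:
    size = img.GetSize()[:3]
    spacing = img.GetSpacing()[:3]
    origin = img.GetOrigin()[:3]
    d = np.array(img.GetDirection())
    if d.size == 16:  # 4D image: take the spatial 3x3 block
        d = d.reshape(4, 4)[:3, :3]
    else:
        d = d.reshape(3, 3)
    return Grid(shape=tuple(size), spacing=tuple(spacing), origin=tuple(origin),
                direction=d)


def read_field(path: str | os.PathLike, format: str = "auto") -> VectorField:
    """Read a 3-component 3D displacement field.

    The vector-component axis of the on-disk layout (interleaved vector
    pixels, or a trailing length-3 dimension of a 4D scalar image) is
    detected and normalised; components are returned ordered (x, y, z) in
    physical axes, values in mm.
    """
    _resolve_format(path, format)
    img = _read_sitk(path)
    dim = img.GetDimension()
    ncomp = img.GetNumberOfComponentsPerPixel()
    if dim == 3 and ncomp == 3:
        grid = _grid_from_sitk(img)
        arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
        comps = arr.transpose(2, 1, 0, 3)
        return VectorField(grid, comps[..., 0], comps[..., 1], comps[..., 2])
    if dim == 4 and ncomp == 1 and img.GetSize()[3] == 3:
        # planar layout: fourth dimension indexes the vector component
        grid = _grid_from_sitk(img)
        arr = sitk.GetArrayFromImage(img)  # (c, z, y, x)
        comps = arr.transpose(3, 2, 1, 0)
        return VectorField(grid, comps[..., 0], comps[..., 1], comps[..., 2])
    if dim == 3 and ncomp == 1:
        raise FormatError(f"{path} is not a vector field (scalar volume)")
    if ncomp not in (1, 3):
        raise FormatError(
            f"{path} is not a vector field (component count {ncomp}, expected 3)"
        )
    raise FormatError(f"{path} is not a 3D vector field (dimension {dim})")


def write_field(
    field: VectorField, path: str | os.PathLike, format: str = "auto"
) -> None:
    """Write a displacement field as a 3-component vector image."""
    _resolve_format(path, format)
    stack = field.as_stack().transpose(2, 1, 0, 3)  # (z, y, x, 3)
    img = sitk.GetImageFromArray(np.ascontiguousarray(stack), isVector=True)
    _apply_grid(img, field.grid)
    _write_sitk(img, path)


def read_image(path: str | os.PathLike, format: str = "auto") -> ImageVolume:
    """Read a scalar 3D volume (anatomy, mask, or vortex map)."""
    _resolve_format(path, format)
    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(f"{path} is not a scalar volume (vector pixels)")
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path} is not a scalar volume (dimension {img.GetDimension()})"
        )
    grid = _grid_from_sitk(img)
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(grid, arr)


def write_scalar_map(
    values: np.ndarray | ImageVolume,
    grid: Grid | None = None,
    path: str | os.PathLike = "",
    format: str = "auto",
    dtype: np.dtype | type | None = None,
) -> None:
    """Write a scalar grid (ImageVolume, VortexMap values, or mask) to disk.

    Accepts either an :class:`ImageVolume` or a raw array plus its grid.
    ``dtype`` optionally casts on write (e.g. ``np.uint8`` for masks).
    """
    if isinstance(values, ImageVolume):
        grid = values.grid
        arr = values.values
    else:
        if grid is None:
            raise FormatError("grid header required when writing a raw array")
        arr = np.asarray(values)
    if arr.shape != grid.shape:
        raise FormatError(f"array shape {arr.shape} does not match grid {grid.shape}")
    if dtype is not None:
        arr = arr.astype(dtype)
    _resolve_format(path, format)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    _apply_grid(img, grid)
    _write_sitk(img, path)


def _apply_grid(img: sitk.Image, grid: Grid) -> None:
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(tuple(grid.direction.ravel()))


def _write_sitk(img: sitk.Image, path: str | os.PathLike) -> None:
    parent = Path(path).resolve().parent
    if not parent.is_dir():
        raise FormatError(f"directory does not exist: {parent}")
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not write {path}: {exc}") from exc
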