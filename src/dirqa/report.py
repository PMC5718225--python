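"""QA report assembly and color-coded overlay rendering.

``build_report`` runs the full pipeline — vortex map, statistics, hotspot
detection, band classification, structure proximity — on files from disk
and assembles a versioned, JSON-serialisable report.  ``render_overlay``
paints the vortex map over grayscale anatomy slices, blue (low intensity)
through red (high), leaving sub-threshold background uncoloured.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402

from . import __version__  # noqa: E402
from .curl import VortexMap, VortexStats, field_stats, vortex_map  # noqa: E402
from .detect import (  # noqa: E402
    DEFAULT_CONNECTIVITY,
    DEFAULT_MIN_REGION_SIZE,
    DEFAULT_THRESHOLD,
    Bands,
    classify,
    detect_regions,
    structure_report,
)
from .errors import GridError  # noqa: E402
from .field_io import read_field, read_image  # noqa: E402
from .grids import Grid, ImageVolume, VectorField, check_grids  # noqa: E402

__all__ = ["QAReport", "build_report", "report_from_field", "render_overlay",
           "BLUE_RED_CMAP"]

SCHEMA_VERSION = 1

BLUE_RED_CMAP = LinearSegmentedColormap.from_list(
    "vortex", [(0.0, 0.0, 1.0), (0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (1.0, 0.0, 0.0)]
)

_AXIS_INDEX = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class QAReport:
    """Complete QA record for one registration solution."""

    schema_version: int
    tool_version: str
    inputs: dict  # file paths and voxel-buffer checksums
    grid: dict
    stats: dict
    bands: dict
    verdict: dict
    regions: list[dict]
    per_structure: list[dict]
    runtime_seconds: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for arr in arrays:
        h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return h.hexdigest()


def _grid_summary(grid: Grid) -> dict:
    return {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "direction": grid.direction.ravel().tolist(),
    }


def report_from_field(
    field: VectorField,
    structures: dict[str, np.ndarray] | None = None,
    bands: Bands = Bands(),
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_region_size: int = DEFAULT_MIN_REGION_SIZE,
    inputs: dict | None = None,
) -> tuple[QAReport, VortexMap]:
    """Assemble a QA report from an in-memory field.

    Returns the report together with the computed vortex map so callers
    can render overlays without recomputation.
    """
    start = time.perf_counter()
    vmap = vortex_map(field)
    stats = field_stats(vmap)
    regions = detect_regions(
        vmap,
        threshold=threshold,
        connectivity=connectivity,
        min_region_size=min_region_size,
    )
    findings = structure_report(vmap, regions, structures or {})
    verdict = classify(stats, regions, bands=bands, per_structure=tuple(findings))
    inputs = dict(inputs or {})
    inputs["field_checksum"] = _checksum(field.u, field.v, field.w)
    report = QAReport(
        schema_version=SCHEMA_VERSION,
        tool_version=__version__,
        inputs=inputs,
        grid=_grid_summary(field.grid),
        stats={
            "min": stats.min,
            "max": stats.max,
            "mean": stats.mean,
            "p99": stats.p99,
            "n_voxels": stats.n_voxels,
        },
        bands={"valid_max": bands.valid_max, "borderline_min": bands.borderline_min},
        verdict={
            "category": verdict.category,
            "max_value": verdict.max_value,
            "n_regions": verdict.n_regions,
        },
        regions=[
            {
                "label": r.label,
                "voxel_count": r.voxel_count,
                "volume_mm3": r.volume_mm3,
                "peak_value": r.peak_value,
                "peak_index": list(r.peak_index),
                "centroid_mm": list(r.centroid_mm),
            }
            for r in regions
        ],
        per_structure=[
            {
                "structure": f.structure,
                "peak_inside": f.peak_inside,
                "distance_mm": f.distance_mm if np.isfinite(f.distance_mm) else None,
                "flagged": f.flagged,
            }
            for f in findings
        ],
        runtime_seconds=time.perf_counter() - start,
    )
    return report, vmap


def build_report(
    field_path: str | Path,
    image_path: str | Path | None = None,
    mask_paths: dict[str, str | Path] | None = None,
    bands: Bands = Bands(),
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_region_size: int = DEFAULT_MIN_REGION_SIZE,
    field_units: str = "mm",
) -> tuple[QAReport, VortexMap, ImageVolume | None]:
    """Run the QA pipeline on files and assemble the report.

    ``field_units='voxels'`` converts a voxel-unit field to mm on load by
    multiplying each component by its axis spacing.  Masks must share the
    field's grid.
    """
    field = read_field(field_path)
    if field_units == "voxels":
        sp = field.grid.spacing
        field = VectorField(
            field.grid, field.u * sp[0], field.v * sp[1], field.w * sp[2]
        )
    elif field_units != "mm":
        raise ValueError(f"field_units must be 'mm' or 'voxels', got {field_units!r}")

    inputs: dict = {"field": str(field_path), "field_units": field_units}
    anatomy: ImageVolume | None = None
    if image_path is not None:
        anatomy = read_image(image_path)
        _require_match(field.grid, anatomy.grid, image_path)
        inputs["image"] = str(image_path)
        inputs["image_checksum"] = _checksum(anatomy.values)

    structures: dict[str, np.ndarray] = {}
    for name, mpath in (mask_paths or {}).items():
        vol = read_image(mpath)
        _require_match(field.grid, vol.grid, mpath)
        structures[name] = vol.values > 0
        inputs.setdefault("masks", {})[name] = str(mpath)

    report, vmap = report_from_field(
        field,
        structures=structures,
        bands=bands,
        threshold=threshold,
        connectivity=connectivity,
        min_region_size=min_region_size,
        inputs=inputs,
    )
    return report, vmap, anatomy


def _require_match(a: Grid, b: Grid, context: str | Path) -> None:
    compat = check_grids(a, b)
    if not compat.compatible:
        raise GridError(
            f"{context}: grid does not match the displacement field "
            f"(shape match={compat.same_shape}, spacing match={compat.same_spacing}, "
            f"origin match={compat.same_origin})"
        )


def render_overlay(
    image: ImageVolume,
    vmap: VortexMap,
    out_dir: str | Path,
    axis: str = "axial",
    slices: list[int] | None = None,
    display_threshold: float = 3.0,
    display_max: float | None = None,
    alpha: float = 0.6,
    window: tuple[float, float] | None = None,
    prefix: str = "overlay",
) -> list[Path]:
    """Render color-washed vortex overlays on anatomy slices to PNG.

    The anatomy is shown grayscale (optionally windowed); map values above
    ``display_threshold`` are colour-coded blue (low) to red (high) up to
    ``display_max`` (default: map maximum), with a numeric colourbar.  One
    PNG per requested slice; deterministic output for fixed inputs.
    """
    compat = check_grids(image.grid, vmap.grid)
    if not compat.compatible:
        raise GridError("anatomy and vortex map are on different grids")
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of {tuple(_AXIS_INDEX)}, got {axis!r}")
    ax_i = _AXIS_INDEX[axis]
    n_slices = image.grid.shape[ax_i]
    if slices is None:
        slices = [n_slices // 2]
    if display_max is None:
        display_max = float(vmap.values.max()) or 1.0
    vmin, vmax = window if window is not None else (
        float(image.values.min()),
        float(image.values.max()),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # display extent honours anisotropic spacing so slices are not distorted
    sp = image.grid.spacing
    plane_axes = [i for i in range(3) if i != ax_i]
    extent = (0, image.grid.shape[plane_axes[0]] * sp[plane_axes[0]],
              0, image.grid.shape[plane_axes[1]] * sp[plane_axes[1]])

    paths: list[Path] = []
    for idx in slices:
        if not (0 <= idx < n_slices):
            raise ValueError(
                f"slice {idx} out of range for axis {axis!r} (0..{n_slices - 1})"
            )
        anat = np.take(image.values, idx, axis=ax_i)
        vort = np.take(vmap.values, idx, axis=ax_i)
        masked = np.ma.masked_less_equal(vort, display_threshold)
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(anat.T, cmap="gray", vmin=vmin, vmax=vmax, origin="lower",
                  extent=extent, aspect="equal")
        im = ax.imshow(masked.T, cmap=BLUE_RED_CMAP, vmin=0.0, vmax=display_max,
                       origin="lower", alpha=alpha, extent=extent, aspect="equal")
        fig.colorbar(im, ax=ax, label="vortex intensity")
        ax.set_title(f"{axis} slice {idx}")
        ax.set_xlabel("mm")
        ax.set_ylabel("mm")
        path = out_dir / f"{prefix}_{axis}_{idx:04d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
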