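"""Synthetic phantoms, deformation fields, defect injectors, and a demons
registration fixture.

This module makes the whole QA loop exercisable without any external data:
it builds a rigid-body QA phantom (constant-HU cylinder and cube inserts on
an air background, 2.5 mm default slice thickness, modelled on commercial
body phantoms), deforms and corrupts it with the artifact types seen in
cone-beam CT (crosshair streaks, HU calibration offsets), and registers
image pairs with a classic intensity-driven demons scheme whose per-
iteration field smoothing can be switched off — the knob that separates
smooth, plausible solutions from jagged, vortex-ridden ones.

All stochastic generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .curl import VortexMap, vortex_map
from .detect import VortexRegion, detect_regions
from .errors import GridError
from .grids import Grid, ImageVolume, VectorField, require_compatible

__all__ = [
    "Insert",
    "PhantomSpec",
    "FieldSpec",
    "make_phantom",
    "analytic_field",
    "bspline_random_field",
    "inject_vortex",
    "inject_artifact",
    "warp_image",
    "invert_field",
    "demons_register",
    "translated_sphere_pair",
    "phantom_study",
    "PhantomStudyResult",
]

DEFAULT_SPACING = (1.0, 1.0, 2.5)
DEFAULT_BACKGROUND_HU = -1000.0


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Insert:
    """One constant-HU phantom insert.

    ``size_mm`` is (radius, height) for a cylinder (axis along z) and the
    edge length (scalar, or per-axis triple) for a cube.
    """

    name: str
    shape: str  # cylinder | cube
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, ...] | float
    hu: float

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "cube"):
            raise ValueError(f"insert shape must be cylinder or cube, got {self.shape!r}")
        if not np.isfinite(self.hu):
            raise ValueError("insert HU must be finite")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description: grid, background, inserts."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_hu: float = DEFAULT_BACKGROUND_HU
    inserts: tuple[Insert, ...] = ()

    @property
    def grid(self) -> Grid:
        return Grid(shape=self.shape, spacing=self.spacing, origin=self.origin)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        inserts = tuple(
            Insert(
                name=i["name"],
                shape=i["shape"],
                center_mm=tuple(i["center_mm"]),
                size_mm=tuple(i["size_mm"]) if isinstance(i["size_mm"], (list, tuple))
                else float(i["size_mm"]),
                hu=float(i["hu"]),
            )
            for i in data.get("inserts", ())
        )
        return cls(
            shape=tuple(data.get("shape", (64, 64, 64))),
            spacing=tuple(data.get("spacing", DEFAULT_SPACING)),
            origin=tuple(data.get("origin", (0.0, 0.0, 0.0))),
            background_hu=float(data.get("background_hu", DEFAULT_BACKGROUND_HU)),
            inserts=inserts,
        )

    @classmethod
    def from_json(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _insert_mask(insert: Insert, x: np.ndarray, y: np.ndarray, z: np.ndarray,
                 grid: Grid) -> np.ndarray:
    cx, cy, cz = insert.center_mm
    if insert.shape == "cylinder":
        radius, height = insert.size_mm  # type: ignore[misc]
        mask = ((x - cx) ** 2 + (y - cy) ** 2 <= radius**2) & (
            np.abs(z - cz) <= height / 2.0
        )
        lo = np.array([cx - radius, cy - radius, cz - height / 2.0])
        hi = np.array([cx + radius, cy + radius, cz + height / 2.0])
    else:
        size = insert.size_mm
        sx, sy, sz = (size, size, size) if np.isscalar(size) else size  # type: ignore[misc]
        mask = (
            (np.abs(x - cx) <= sx / 2.0)
            & (np.abs(y - cy) <= sy / 2.0)
            & (np.abs(z - cz) <= sz / 2.0)
        )
        lo = np.array([cx - sx / 2.0, cy - sy / 2.0, cz - sz / 2.0])
        hi = np.array([cx + sx / 2.0, cy + sy / 2.0, cz + sz / 2.0])
    extent_lo = np.asarray(grid.origin)
    extent_hi = extent_lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    if np.any(lo < extent_lo - 1e-9) or np.any(hi > extent_hi + 1e-9):
        raise GridError(f"insert {insert.name!r} extends outside the grid")
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, dict[str, np.ndarray]]:
    """Rasterise a phantom spec to a HU volume plus one binary mask per insert.

    A voxel belongs to an insert when its physical centre lies inside the
    insert's geometry; later inserts overwrite earlier ones.
    """
    grid = spec.grid
    x, y, z = grid.coordinate_arrays()
    values = np.full(grid.shape, spec.background_hu)
    masks: dict[str, np.ndarray] = {}
    for insert in spec.inserts:
        mask = _insert_mask(insert, x, y, z, grid)
        values[mask] = insert.hu
        masks[insert.name] = mask
    return ImageVolume(grid, values), masks


# ---------------------------------------------------------------------------
# analytic deformation fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Declarative deformation description.

    kind and the parameters it requires:

    - ``translation``: ``vector`` (3,) mm
    - ``rotation``: ``omega`` (3,) angular factor, ``center`` (3,) mm
    - ``expansion``: ``magnitude`` (dimensionless), ``radius`` mm,
      ``center`` mm — radial field m * (r - c) * max(0, 1 - |r - c| / R),
      compactly supported so the deformation is identity far away
    - ``gradient``: ``quadratic`` dict of coefficients of
      phi = xx*x^2 + yy*y^2 + zz*z^2 + xy*x*y + yz*y*z + xz*x*z
            + x*x + y*y + z*z; the field is the (curl-free) gradient of phi
    - ``bspline_random``: ``node_spacing_mm``, ``amplitude_mm``, ``seed``
    """

    kind: str
    params: dict = dc_field(default_factory=dict)

    _KINDS = ("translation", "rotation", "expansion", "gradient", "bspline_random")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}; expected {self._KINDS}")

    @classmethod
    def from_json(cls, path: str) -> "FieldSpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(kind=data["kind"], params=data.get("params", {}))


def analytic_field(spec: FieldSpec, grid: Grid) -> VectorField:
    """Evaluate a closed-form deformation field on a grid."""
    x, y, z = grid.coordinate_arrays()
    p = spec.params
    if spec.kind == "translation":
        vec = np.asarray(p["vector"], dtype=float)
        ones = np.ones(grid.shape)
        return VectorField(grid, vec[0] * ones, vec[1] * ones, vec[2] * ones)
    if spec.kind == "rotation":
        omega = np.asarray(p["omega"], dtype=float)
        cx, cy, cz = p.get("center", (0.0, 0.0, 0.0))
        rx, ry, rz = x - cx, y - cy, z - cz
        return VectorField(
            grid,
            omega[1] * rz - omega[2] * ry,
            omega[2] * rx - omega[0] * rz,
            omega[0] * ry - omega[1] * rx,
        )
    if spec.kind == "expansion":
        m = float(p["magnitude"])
        radius = float(p["radius"])
        cx, cy, cz = p["center"]
        rx, ry, rz = x - cx, y - cy, z - cz
        dist = np.sqrt(rx**2 + ry**2 + rz**2)
        falloff = m * np.maximum(0.0, 1.0 - dist / radius)
        return VectorField(grid, rx * falloff, ry * falloff, rz * falloff)
    if spec.kind == "gradient":
        q = {k: float(v) for k, v in p["quadratic"].items()}
        g = lambda k: q.get(k, 0.0)  # noqa: E731
        u = 2 * g("xx") * x + g("xy") * y + g("xz") * z + g("x")
        v = 2 * g("yy") * y + g("xy") * x + g("yz") * z + g("y")
        w = 2 * g("zz") * z + g("yz") * y + g("xz") * x + g("z")
        ones = np.ones(grid.shape)
        return VectorField(grid, u * ones, v * ones, w * ones)
    if spec.kind == "bspline_random":
        return bspline_random_field(
            grid, p["node_spacing_mm"], p["amplitude_mm"], p["seed"]
        )
    raise ValueError(f"unknown field kind {spec.kind!r}")


def bspline_random_field(
    grid: Grid, node_spacing_mm: float, amplitude_mm: float, seed: int
) -> VectorField:
    """Random smooth field from a coarse control-node lattice.

    Node displacements are drawn uniformly in [-amplitude, amplitude] per
    component from a seeded generator and interpolated to the voxel grid
    with cubic B-splines, emulating the parametric (B-spline) registration
    model where voxel displacement is interpolated from the nearest lattice
    nodes.  Wider node spacing means stronger regularisation: smoother
    fields, lower curl.
    """
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)
    if node_spacing_mm < 2 * spacing.max():
        raise GridError(
            f"node spacing {node_spacing_mm} mm is finer than 2 voxels "
            f"(max spacing {spacing.max()} mm)"
        )
    extent = (shape - 1) * spacing
    n_nodes = np.maximum(np.ceil(extent / node_spacing_mm).astype(int) + 1, 2)
    rng = np.random.default_rng(seed)
    nodes = rng.uniform(-amplitude_mm, amplitude_mm, size=(3, *n_nodes))
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.stack([ii, jj, kk]).astype(float)
    for ax in range(3):
        coords[ax] *= spacing[ax] / node_spacing_mm
    comps = [
        ndimage.map_coordinates(nodes[c], coords, order=3, mode="nearest")
        for c in range(3)
    ]
    return VectorField(grid, *comps)


def inject_vortex(
    field: VectorField,
    center_mm: Sequence[float],
    radius_mm: float,
    omega: Sequence[float],
) -> VectorField:
    """Add a compactly supported rotational defect to a field.

    The added displacement is omega x (r - c) weighted by the smooth bump
    (1 - t^2)^2 with t = |r - c| / radius, so it is 1 at the centre with a
    flat top (the curl there is exactly 2*omega) and vanishes with its
    derivative at the support boundary.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    grid = field.grid
    center = np.asarray(center_mm, dtype=float)
    extent_lo = np.asarray(grid.origin)
    extent_hi = extent_lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    if np.any(center < extent_lo) or np.any(center > extent_hi):
        raise GridError(f"vortex centre {tuple(center)} lies outside the grid")
    omega = np.asarray(omega, dtype=float)
    x, y, z = grid.coordinate_arrays()
    rx, ry, rz = x - center[0], y - center[1], z - center[2]
    t2 = (rx**2 + ry**2 + rz**2) / radius_mm**2
    bump = np.where(t2 < 1.0, (1.0 - np.minimum(t2, 1.0)) ** 2, 0.0)
    du = (omega[1] * rz - omega[2] * ry) * bump
    dv = (omega[2] * rx - omega[0] * rz) * bump
    dw = (omega[0] * ry - omega[1] * rx) * bump
    return VectorField(grid, field.u + du, field.v + dv, field.w + dw)


# ---------------------------------------------------------------------------
# image artifacts
# ---------------------------------------------------------------------------

def inject_artifact(image: ImageVolume, kind: str, params: dict) -> ImageVolume:
    """Corrupt a volume with a CBCT-style artifact.

    ``streak_crosshair``: on one axial slice, voxels within ``width``
    voxels of two orthogonal in-plane lines through ``center_index`` (arm
    length ``arm_length`` voxels) are set to ``hu``.

    ``hu_offset``: values inside ``mask`` are shifted by ``delta`` HU,
    emulating a calibration error.
    """
    values = image.values.copy()
    if kind == "streak_crosshair":
        ic, jc, kc = (int(c) for c in params["center_index"])
        arm = int(params["arm_length"])
        width = int(params.get("width", 1))
        hu = float(params["hu"])
        half = (width - 1) // 2
        nx, ny, _ = image.grid.shape
        i0, i1 = max(ic - arm, 0), min(ic + arm, nx - 1)
        j0, j1 = max(jc - arm, 0), min(jc + arm, ny - 1)
        values[i0 : i1 + 1, max(jc - half, 0) : jc + half + 1, kc] = hu
        values[max(ic - half, 0) : ic + half + 1, j0 : j1 + 1, kc] = hu
    elif kind == "hu_offset":
        mask = np.asarray(params["mask"]).astype(bool)
        if mask.shape != image.grid.shape:
            raise GridError("hu_offset mask shape does not match image grid")
        values[mask] += float(params["delta"])
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return ImageVolume(image.grid, values)


# ---------------------------------------------------------------------------
# warping and registration
# ---------------------------------------------------------------------------

def _physical_to_index_offsets(field: VectorField) -> np.ndarray:
    """Convert mm displacements to index-space offsets, (3, nx, ny, nz)."""
    grid = field.grid
    stack = field.as_stack()  # (nx, ny, nz, 3) physical mm
    index_disp = stack @ grid.direction  # rows: D^T @ u
    return np.moveaxis(index_disp / np.asarray(grid.spacing), -1, 0)


def warp_image(
    image: ImageVolume,
    field: VectorField,
    interpolation: str = "linear",
    background: float | None = None,
) -> ImageVolume:
    """Backward-warp a volume: output(x) = image(x + u(x)).

    Samples falling outside the volume take ``background`` (default: the
    image minimum, i.e. air for CT-like data).
    """
    require_compatible(image.grid, field.grid)
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"interpolation must be nearest or linear, got {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    if background is None:
        background = float(image.values.min())
    shape = image.grid.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = np.stack([ii, jj, kk]).astype(float) + _physical_to_index_offsets(field)
    warped = ndimage.map_coordinates(
        image.values, coords, order=order, mode="constant", cval=background
    )
    return ImageVolume(image.grid, warped)


def invert_field(field: VectorField, iterations: int = 20) -> VectorField:
    """Approximate inverse displacement by fixed-point iteration.

    Iterates v <- -u(x + v(x)); converges for moderate, smooth fields and
    serves as a ground-truth tool for round-trip warping checks.
    """
    grid = field.grid
    shape = grid.shape
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    base = np.stack([ii, jj, kk]).astype(float)
    inv = VectorField.zeros(grid)
    for _ in range(iterations):
        coords = base + _physical_to_index_offsets(inv)
        comps = [
            -ndimage.map_coordinates(c, coords, order=1, mode="nearest")
            for c in field.components
        ]
        inv = VectorField(grid, *comps)
    return inv


def demons_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    iterations: int = 50,
    smooth_sigma_mm: float | None = None,
) -> VectorField:
    """Classic intensity-driven (Thirion-style) demons registration.

    Each iteration evaluates the optical-flow force

        du(x) = (f(x) - m(x + u(x))) * grad f(x)
                / (|grad f(x)|^2 + (f(x) - m(x + u(x)))^2)

    (zero where the denominator falls below 1e-9), accumulates u <- u + du,
    and — when ``smooth_sigma_mm`` is given — Gaussian-smooths each
    component of u, which is the algorithm's regularisation.  Without
    smoothing the field tracks intensity noise and artifacts voxel by
    voxel and develops vortexes; the QA metric is designed to expose
    exactly that contrast.  Fully deterministic.
    """
    require_compatible(fixed.grid, moving.grid)
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    grid = fixed.grid
    spacing = np.asarray(grid.spacing)
    f = fixed.values
    grads = np.gradient(f, *spacing, edge_order=1)
    grad_sq = sum(g**2 for g in grads)
    u = VectorField.zeros(grid)
    sigma_vox = None
    if smooth_sigma_mm is not None:
        sigma_vox = smooth_sigma_mm / spacing
    for _ in range(iterations):
        warped = warp_image(moving, u, interpolation="linear")
        diff = f - warped.values
        denom = grad_sq + diff**2
        scale = np.where(denom >= 1e-9, diff / np.where(denom >= 1e-9, denom, 1.0), 0.0)
        comps = [u.components[c] + scale * grads[c] for c in range(3)]
        if sigma_vox is not None:
            comps = [ndimage.gaussian_filter(c, sigma=sigma_vox) for c in comps]
        u = VectorField(grid, *comps)
    return u


def translated_sphere_pair(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    radius_mm: float = 10.0,
    shift_mm: tuple[float, float, float] = (3.0, 0.0, 0.0),
    intensity: float = 1000.0,
    edge_sigma_mm: float = 2.0,
) -> tuple[ImageVolume, ImageVolume, np.ndarray]:
    """Fixed/moving pair: a soft-edged sphere, translated by a known offset.

    The sphere sits at the grid centre in the fixed volume and at
    ``centre + shift`` in the moving volume, so the ground-truth backward
    displacement is exactly ``shift`` inside the sphere.  Edges are
    Gaussian-softened (``edge_sigma_mm``) so intensity gradients — and
    hence registration forces — extend over a shell rather than a single
    voxel layer, as for a real soft-tissue boundary.  Returns the two
    volumes plus the fixed sphere's interior mask.
    """
    grid = Grid(shape=shape, spacing=spacing)
    x, y, z = grid.coordinate_arrays()
    center = (np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    sigma_vox = np.asarray(edge_sigma_mm) / np.asarray(spacing)

    def ball(cx: float, cy: float, cz: float) -> np.ndarray:
        hard = np.where(
            (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm**2,
            intensity,
            0.0,
        )
        return ndimage.gaussian_filter(hard, sigma=sigma_vox)

    fixed = ImageVolume(grid, ball(*center))
    moving = ImageVolume(grid, ball(*(center + np.asarray(shift_mm))))
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (
        z - center[2]
    ) ** 2 <= radius_mm**2
    return fixed, moving, inside


# ---------------------------------------------------------------------------
# phantom study protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomStudyResult:
    """Outputs of the scaled-down phantom QA protocol."""

    moving: ImageVolume
    fixed: ImageVolume
    masks: dict[str, np.ndarray]  # insert + dilated artifact masks
    field: VectorField
    vmap: VortexMap
    regions: list[VortexRegion]
    artifact_peaks: dict[str, float]  # peak map value inside each artifact mask
    clean_insert_peak: float


def phantom_study(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    iterations: int = 80,
    smooth_sigma_mm: float | None = None,
    detect_threshold: float = 5.0,
    dilation_voxels: int = 3,
) -> PhantomStudyResult:
    """Run the phantom QA protocol end to end.

    A phantom with cylinder/cube inserts is imaged twice: the moving volume
    with nominal insert sizes, the fixed volume with two inserts expanded
    (mimicking anatomical change) plus two CBCT-style defects — a crosshair
    streak and an HU-offset on one insert.  Demons registration of the pair
    is then scored with the vortex map.  Genuine anatomical change deforms
    smoothly; the intensity defects violate the registration's constancy
    assumption and concentrate rotational hotspots inside the artifact
    regions.  The default runs the demons without per-iteration field
    smoothing — the weakly regularised regime where such hotspots are
    expected to develop.
    """
    def spec(expand: float) -> PhantomSpec:
        return PhantomSpec(
            shape=shape,
            spacing=spacing,
            inserts=(
                Insert("expand_cyl", "cylinder", (20.0, 20.0, 45.0),
                       (8.0 + expand, 36.0), 0.0),
                Insert("expand_cube", "cube", (44.0, 44.0, 45.0),
                       12.0 + expand, 100.0),
                Insert("hu_insert", "cylinder", (20.0, 44.0, 115.0),
                       (9.0, 36.0), 50.0),
            ),
        )

    moving, masks = make_phantom(spec(expand=0.0))
    fixed, fixed_masks = make_phantom(spec(expand=2.0))

    streak_center = (44, 18, int(round(115.0 / spacing[2])))
    fixed = inject_artifact(
        fixed,
        "streak_crosshair",
        {"center_index": streak_center, "arm_length": 10, "width": 1, "hu": 500.0},
    )
    streak_mask = np.zeros(shape, dtype=bool)
    ic, jc, kc = streak_center
    streak_mask[ic - 10 : ic + 11, jc, kc] = True
    streak_mask[ic, jc - 10 : jc + 11, kc] = True

    fixed = inject_artifact(
        fixed, "hu_offset", {"mask": fixed_masks["hu_insert"], "delta": 300.0}
    )

    field = demons_register(
        fixed, moving, iterations=iterations, smooth_sigma_mm=smooth_sigma_mm
    )
    vmap = vortex_map(field)
    regions = detect_regions(vmap, threshold=detect_threshold, min_region_size=3)

    structure = ndimage.generate_binary_structure(3, 1)
    dilate = lambda m: ndimage.binary_dilation(  # noqa: E731
        m, structure=structure, iterations=dilation_voxels
    )
    artifact_masks = {
        "streak": dilate(streak_mask),
        "hu_offset": dilate(fixed_masks["hu_insert"]),
    }
    clean_mask = (
        dilate(fixed_masks["expand_cyl"]) | dilate(fixed_masks["expand_cube"])
    ) & ~(artifact_masks["streak"] | artifact_masks["hu_offset"])
    all_masks = dict(masks)
    all_masks.update({f"artifact_{k}": v for k, v in artifact_masks.items()})

    artifact_peaks = {
        name: float(vmap.values[m].max()) for name, m in artifact_masks.items()
    }
    return PhantomStudyResult(
        moving=moving,
        fixed=fixed,
        masks=all_masks,
        field=field,
        vmap=vmap,
        regions=regions,
        artifact_peaks=artifact_peaks,
        clean_insert_peak=float(vmap.values[clean_mask].max()),
    )
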