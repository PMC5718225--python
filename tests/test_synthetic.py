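import numpy as np
import pytest

from dirqa import Grid, ImageVolume, vortex_map
from dirqa.errors import GridError
from dirqa.synthetic import (
    FieldSpec,
    Insert,
    PhantomSpec,
    analytic_field,
    bspline_random_field,
    demons_register,
    inject_artifact,
    inject_vortex,
    invert_field,
    make_phantom,
    translated_sphere_pair,
    warp_image,
)

from oracles import naive_curl


class TestMakePhantom:
    def test_cylinder_volume_matches_analytic(self):
        spec = PhantomSpec(
            shape=(64, 64, 40),
            spacing=(1.0, 1.0, 2.5),
            inserts=(
                # centre offset off the slice grid so the flat faces do not
                # land exactly on voxel centres (the <= tie would add a slice)
                Insert("cyl", "cylinder", (32.0, 32.0, 51.25), (20.0, 40.0), 0.0),
            ),
        )
        _, masks = make_phantom(spec)
        analytic = np.pi * 20.0**2 * 40.0 / 2.5  # voxels (in-plane area x slices)
        assert masks["cyl"].sum() == pytest.approx(analytic, rel=0.03)

    def test_cube_count_matches_brute_force_inclusion(self):
        spec = PhantomSpec(
            shape=(24, 24, 24),
            spacing=(1.0, 1.0, 1.0),
            inserts=(Insert("cube", "cube", (12.0, 12.0, 12.0), 10.0, 100.0),),
        )
        vol, masks = make_phantom(spec)
        # brute force: voxel centres within half-side of the centre
        count = 0
        for i in range(24):
            for j in range(24):
                for k in range(24):
                    if max(abs(i - 12), abs(j - 12), abs(k - 12)) <= 5:
                        count += 1
        assert masks["cube"].sum() == count == 11**3
        assert vol.values[12, 12, 12] == 100.0

    def test_empty_spec_gives_uniform_background(self):
        vol, masks = make_phantom(PhantomSpec(shape=(8, 8, 8)))
        assert masks == {}
        assert (vol.values == -1000.0).all()

    def test_later_insert_overwrites_earlier(self):
        spec = PhantomSpec(
            shape=(16, 16, 16),
            spacing=(1.0, 1.0, 1.0),
            inserts=(
                Insert("a", "cube", (8.0, 8.0, 8.0), 8.0, 0.0),
                Insert("b", "cube", (8.0, 8.0, 8.0), 4.0, 500.0),
            ),
        )
        vol, _ = make_phantom(spec)
        assert vol.values[8, 8, 8] == 500.0
        assert vol.values[5, 8, 8] == 0.0

    def test_insert_outside_grid_rejected(self):
        spec = PhantomSpec(
            shape=(16, 16, 16),
            inserts=(Insert("far", "cube", (100.0, 8.0, 8.0), 4.0, 0.0),),
        )
        with pytest.raises(GridError, match="outside the grid"):
            make_phantom(spec)

    def test_spec_round_trips_through_json(self, tmp_path):
        spec = PhantomSpec(
            shape=(8, 8, 8),
            inserts=(Insert("c", "cylinder", (4.0, 4.0, 8.0), (2.0, 5.0), 50.0),),
        )
        path = tmp_path / "spec.json"
        path.write_text(
            """{"shape": [8, 8, 8], "inserts": [{"name": "c", "shape": "cylinder",
                "center_mm": [4, 4, 8], "size_mm": [2, 5], "hu": 50}]}"""
        )
        loaded = PhantomSpec.from_json(str(path))
        assert loaded.inserts[0] == spec.inserts[0]
        assert loaded.spacing == (1.0, 1.0, 2.5)


class TestAnalyticFields:
    def test_expansion_is_radial_and_compact(self):
        g = Grid(shape=(32, 32, 32))
        spec = FieldSpec(
            "expansion", {"magnitude": 0.5, "radius": 10.0, "center": (16, 16, 16)}
        )
        f = analytic_field(spec, g)
        # zero at centre, zero outside the support radius
        assert f.magnitude()[16, 16, 16] == 0.0
        assert f.magnitude()[0, 0, 0] == 0.0
        # at 4 mm from centre along x: u = m * 4 * (1 - 4/10)
        assert f.u[20, 16, 16] == pytest.approx(0.5 * 4.0 * 0.6)
        assert f.v[20, 16, 16] == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown field kind"):
            FieldSpec("spiral", {})


class TestBsplineRandomField:
    def test_seed_determinism(self):
        g = Grid(shape=(24, 24, 16), spacing=(1.0, 1.0, 2.5))
        a = bspline_random_field(g, 16.0, 2.0, seed=5)
        b = bspline_random_field(g, 16.0, 2.0, seed=5)
        for ca, cb in zip(a.components, b.components):
            np.testing.assert_array_equal(ca, cb)

    def test_zero_amplitude_gives_zero_field(self):
        g = Grid(shape=(16, 16, 16))
        f = bspline_random_field(g, 8.0, 0.0, seed=1)
        assert f.magnitude().max() == 0.0

    def test_wider_node_spacing_regularises(self):
        """Fewer control nodes (stronger regularisation) never raises the
        vortex-map maximum, paired over seeds."""
        g = Grid(shape=(32, 32, 32))
        for seed in range(10):
            fine = bspline_random_field(g, 8.0, 2.0, seed=seed)
            coarse = bspline_random_field(g, 20.0, 2.0, seed=seed)
            assert (
                vortex_map(coarse).values.max() <= vortex_map(fine).values.max()
            )

    def test_too_fine_lattice_rejected(self):
        g = Grid(shape=(16, 16, 16), spacing=(1.0, 1.0, 2.5))
        with pytest.raises(GridError, match="node spacing"):
            bspline_random_field(g, 3.0, 1.0, seed=0)


class TestInjectVortex:
    def test_peak_curl_and_compact_support(self):
        from dirqa import VectorField

        g = Grid(shape=(40, 40, 40))
        center = (20.0, 20.0, 20.0)
        f = inject_vortex(VectorField.zeros(g), center, 8.0, (0.0, 0.0, 2.0))
        cx, cy, cz = naive_curl(f.u, f.v, f.w, g.spacing)
        mag = np.sqrt(cx**2 + cy**2 + cz**2)
        assert mag[20, 20, 20] == pytest.approx(4.0, rel=0.10)  # 2|omega|
        # untouched outside radius + 2 voxels
        x, y, z = g.coordinate_arrays()
        outside = (x - 20) ** 2 + (y - 20) ** 2 + (z - 20) ** 2 > (8.0 + 2.0) ** 2
        assert np.abs(mag[outside]).max() <= 1e-12

    def test_zero_omega_is_identity(self, rotation_field):
        out = inject_vortex(rotation_field, (8.0, 8.0, 10.0), 5.0, (0, 0, 0))
        for a, b in zip(out.components, rotation_field.components):
            np.testing.assert_array_equal(a, b)

    def test_center_outside_grid_rejected(self, rotation_field):
        with pytest.raises(GridError, match="outside the grid"):
            inject_vortex(rotation_field, (999.0, 0.0, 0.0), 5.0, (0, 0, 1))

    def test_two_injections_detected_separately(self):
        from dirqa import VectorField, detect_regions

        g = Grid(shape=(48, 48, 24))
        c1, c2 = (12.0, 12.0, 12.0), (36.0, 36.0, 12.0)
        f = inject_vortex(VectorField.zeros(g), c1, 7.0, (0, 0, 4.0))
        f = inject_vortex(f, c2, 7.0, (0, 0, 3.5))
        regions = detect_regions(vortex_map(f), threshold=5.0)
        assert len(regions) == 2
        assert np.linalg.norm(np.array(regions[0].centroid_mm) - c1) < 2.0
        assert np.linalg.norm(np.array(regions[1].centroid_mm) - c2) < 2.0


class TestInjectArtifact:
    def test_hu_offset_shifts_mean_exactly(self):
        g = Grid(shape=(16, 16, 16))
        vol = ImageVolume.full(g, -1000.0)
        mask = np.zeros(g.shape, dtype=bool)
        mask[4:8, 4:8, 4:8] = True
        out = inject_artifact(vol, "hu_offset", {"mask": mask, "delta": 100.0})
        assert out.values[mask].mean() == pytest.approx(-900.0)
        assert out.values[~mask].mean() == pytest.approx(-1000.0)

    def test_zero_delta_is_identity(self):
        g = Grid(shape=(8, 8, 8))
        vol = ImageVolume.full(g, 42.0)
        mask = np.ones(g.shape, dtype=bool)
        out = inject_artifact(vol, "hu_offset", {"mask": mask, "delta": 0.0})
        np.testing.assert_array_equal(out.values, vol.values)

    def test_streak_modified_voxel_count_analytic(self):
        g = Grid(shape=(32, 32, 8))
        vol = ImageVolume.full(g, -1000.0)
        out = inject_artifact(
            vol,
            "streak_crosshair",
            {"center_index": (16, 16, 4), "arm_length": 6, "width": 1, "hu": 500.0},
        )
        modified = (out.values != -1000.0).sum()
        # two arms of 2L+1 voxels sharing the centre voxel
        assert modified == 2 * (2 * 6 + 1) - 1
        assert (out.values[10:23, 16, 4] == 500.0).all()

    def test_unknown_kind_rejected(self):
        g = Grid(shape=(4, 4, 4))
        with pytest.raises(ValueError, match="unknown artifact"):
            inject_artifact(ImageVolume.full(g, 0.0), "ring", {})


class TestWarpImage:
    def test_zero_field_is_identity(self):
        from dirqa import VectorField

        g = Grid(shape=(12, 12, 12))
        rng = np.random.default_rng(2)
        vol = ImageVolume(g, rng.normal(0, 100, g.shape))
        out = warp_image(vol, VectorField.zeros(g), interpolation="linear")
        np.testing.assert_allclose(out.values, vol.values, atol=1e-9)

    def test_integer_shift_nearest_is_exact(self):
        g = Grid(shape=(16, 16, 16), spacing=(1.0, 1.0, 2.5))
        rng = np.random.default_rng(4)
        vol = ImageVolume(g, rng.normal(0, 100, g.shape))
        # displacement of exactly 2 voxels along z = 5.0 mm
        f = analytic_field(FieldSpec("translation", {"vector": (0, 0, 5.0)}), g)
        out = warp_image(vol, f, interpolation="nearest", background=0.0)
        np.testing.assert_array_equal(out.values[:, :, :14], vol.values[:, :, 2:])
        assert (out.values[:, :, 14:] == 0.0).all()

    def test_warp_then_approximate_inverse_recovers_image(self):
        g = Grid(shape=(32, 32, 32))
        x, y, z = g.coordinate_arrays()
        # smooth test pattern with moderate dynamic range
        vol = ImageVolume(g, 500 * np.sin(x / 5) * np.cos(y / 6) + 500 * (z / 31))
        f = bspline_random_field(g, 12.0, 1.5, seed=3)
        inv = invert_field(f, iterations=20)
        round_trip = warp_image(warp_image(vol, f), inv)
        core = (slice(4, -4),) * 3
        err = np.abs(round_trip.values[core] - vol.values[core]).mean()
        dynamic_range = vol.values.max() - vol.values.min()
        assert err < 0.02 * dynamic_range

    def test_incompatible_grids_rejected(self):
        from dirqa import VectorField

        vol = ImageVolume.full(Grid(shape=(8, 8, 8)), 0.0)
        field = VectorField.zeros(Grid(shape=(8, 8, 9)))
        with pytest.raises(GridError, match="incompatible"):
            warp_image(vol, field)


class TestDemonsRegister:
    def test_identical_images_give_zero_field(self):
        g = Grid(shape=(16, 16, 16))
        rng = np.random.default_rng(6)
        vol = ImageVolume(g, rng.normal(0, 100, g.shape))
        u = demons_register(vol, vol, iterations=10)
        assert u.magnitude().max() < 1e-6

    def test_recovers_known_translation_inside_sphere(self):
        fixed, moving, inside = translated_sphere_pair(shift_mm=(3.0, 0.0, 0.0))
        u = demons_register(fixed, moving, iterations=100, smooth_sigma_mm=2.0)
        mean_ux = u.u[inside].mean()
        assert mean_ux == pytest.approx(3.0, rel=0.30)

    def test_smoothing_lowers_vortex_maximum(self):
        fixed, moving, _ = translated_sphere_pair(shift_mm=(0.0, 3.0, 0.0))
        smoothed = demons_register(fixed, moving, iterations=40, smooth_sigma_mm=2.0)
        rough = demons_register(fixed, moving, iterations=40, smooth_sigma_mm=None)
        assert vortex_map(smoothed).values.max() < vortex_map(rough).values.max()

    def test_invalid_iterations_rejected(self):
        g = Grid(shape=(8, 8, 8))
        vol = ImageVolume.full(g, 0.0)
        with pytest.raises(ValueError, match="iterations"):
            demons_register(vol, vol, iterations=0)
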