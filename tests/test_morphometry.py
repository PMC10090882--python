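"""Voxel volumes, isosurface areas, mesh volumes and convex hulls."""

import numpy as np
import pytest
import trimesh

from nasallom.morphometry import (
    DegenerateHullError,
    EmptyRegionError,
    LabelNotFoundError,
    LabeledVolume,
    NonWatertightMeshError,
    SurfaceMesh,
    convex_hull_volume,
    label_surface_area,
    label_volume,
    measure_specimen,
    mesh_volume,
)


def _volume_with(mask, spacing=(1.0, 1.0, 1.0), label=1, name="region"):
    grid = np.zeros(mask.shape, dtype=np.int16)
    grid[mask] = label
    return LabeledVolume(grid=grid, spacing=spacing, labels={"background": 0, name: label})


def _sphere_mask(shape, center, r, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape, dtype=float)
    w = [(idx[k] + 0.5) * spacing[k] for k in range(3)]
    return sum((w[k] - center[k]) ** 2 for k in range(3)) <= r * r


class TestLabelVolume:
    def test_block_volume(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        vol = _volume_with(mask)
        assert label_volume(vol, "region") == pytest.approx(1000.0)

    def test_empty_label_in_table_gives_zero(self):
        vol = _volume_with(np.zeros((5, 5, 5), dtype=bool))
        assert label_volume(vol, "region") == 0.0

    def test_unknown_label_raises(self):
        vol = _volume_with(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(LabelNotFoundError):
            label_volume(vol, "nope")

    def test_voxelized_sphere_within_one_percent(self):
        mask = _sphere_mask((64, 64, 64), (32, 32, 32), 20.0)
        vol = _volume_with(mask)
        assert label_volume(vol, "region") == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.01)

    def test_additivity_of_disjoint_labels(self):
        grid = np.zeros((20, 20, 20), dtype=np.int16)
        grid[2:5, 2:5, 2:5] = 1
        grid[10:15, 10:15, 10:15] = 2
        vol = LabeledVolume(grid=grid, labels={"background": 0, "a": 1, "b": 2})
        assert label_volume(vol, "a") + label_volume(vol, "b") == pytest.approx(
            float((grid > 0).sum())
        )

    def test_scale_equivariance(self):
        mask = _sphere_mask((32, 32, 32), (16, 16, 16), 10.0)
        v1 = label_volume(_volume_with(mask), "region")
        v2 = label_volume(_volume_with(mask, spacing=(2.0, 2.0, 2.0)), "region")
        assert v2 == pytest.approx(8 * v1)


class TestLabelSurfaceArea:
    def test_single_voxel_constant_is_octahedron(self):
        # method constant: isolevel crossings at face midpoints -> area sqrt(3)
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        vol = _volume_with(mask)
        assert label_surface_area(vol, "region") == pytest.approx(np.sqrt(3), rel=1e-5)

    def test_voxelized_sphere_within_three_percent(self):
        mask = _sphere_mask((64, 64, 64), (32, 32, 32), 20.0)
        vol = _volume_with(mask)
        assert label_surface_area(vol, "region") == pytest.approx(
            4 * np.pi * 20**2, rel=0.03
        )

    def test_disjoint_blocks_sum(self):
        a = np.zeros((30, 20, 20), dtype=bool)
        a[3:8, 5:10, 5:10] = True
        b = np.zeros((30, 20, 20), dtype=bool)
        b[18:23, 5:10, 5:10] = True
        area_a = label_surface_area(_volume_with(a), "region")
        area_b = label_surface_area(_volume_with(b), "region")
        area_ab = label_surface_area(_volume_with(a | b), "region")
        assert area_ab == pytest.approx(area_a + area_b, rel=1e-6)

    def test_area_scale_equivariance(self):
        mask = _sphere_mask((32, 32, 32), (16, 16, 16), 10.0)
        a1 = label_surface_area(_volume_with(mask), "region")
        a2 = label_surface_area(_volume_with(mask, spacing=(2.0, 2.0, 2.0)), "region")
        assert a2 == pytest.approx(4 * a1, rel=1e-6)

    def test_empty_label_raises(self):
        vol = _volume_with(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(EmptyRegionError):
            label_surface_area(vol, "region")


class TestMeshVolume:
    def test_unit_cube(self):
        box = trimesh.creation.box((1.0, 1.0, 1.0))
        mesh = SurfaceMesh(vertices=box.vertices, faces=box.faces)
        assert mesh_volume(mesh) == pytest.approx(1.0)

    def test_icosphere_near_analytic(self):
        ico = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        assert mesh_volume(ico) == pytest.approx(4 / 3 * np.pi, rel=0.005)

    def test_open_mesh_rejected(self):
        box = trimesh.creation.box((1.0, 1.0, 1.0))
        open_mesh = SurfaceMesh(vertices=box.vertices, faces=box.faces[:-2])
        with pytest.raises(NonWatertightMeshError):
            mesh_volume(open_mesh)

    def test_orientation_independent(self):
        box = trimesh.creation.box((2.0, 1.0, 1.0))
        flipped = trimesh.Trimesh(box.vertices, box.faces[:, ::-1], process=False)
        assert mesh_volume(flipped) == pytest.approx(2.0)


class TestConvexHullVolume:
    CUBE = np.array(
        [[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)]
    )

    def test_cube_corners(self):
        assert convex_hull_volume(self.CUBE) == pytest.approx(8.0)

    def test_interior_points_do_not_change_hull(self, rng):
        pts = np.vstack([self.CUBE, rng.uniform(0.2, 1.8, size=(100, 3))])
        assert convex_hull_volume(pts) == pytest.approx(8.0)

    def test_two_offset_cubes_vs_monte_carlo_oracle(self, rng):
        # unit cube at origin and another shifted 5 mm along x
        pts = np.vstack(
            [
                [[x, y, z] for x in (0, 1.0) for y in (0, 1.0) for z in (0, 1.0)],
                [[x + 5.0, y, z] for x in (0, 1.0) for y in (0, 1.0) for z in (0, 1.0)],
            ]
        )
        hull_vol = convex_hull_volume(pts)
        # rejection-sampling oracle inside the bounding box
        from scipy.spatial import Delaunay

        box_lo = np.array([0.0, 0.0, 0.0])
        box_hi = np.array([6.0, 1.0, 1.0])
        samples = rng.uniform(box_lo, box_hi, size=(1_000_000, 3))
        tri = Delaunay(pts)
        frac = (tri.find_simplex(samples) >= 0).mean()
        mc_vol = frac * np.prod(box_hi - box_lo)
        assert hull_vol == pytest.approx(mc_vol, rel=0.01)

    def test_coplanar_points_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateHullError):
            convex_hull_volume(flat)


class TestMeasureSpecimen:
    def test_phantom_measurements_match_analytic_truths(self, default_phantom):
        vol, _, truths = default_phantom
        meas = measure_specimen(vol)
        assert meas["nasal_vol_mm3"] == pytest.approx(truths["cavity_vol_mm3"], rel=0.01)
        assert meas["nasal_sa_mm2"] == pytest.approx(truths["cavity_sa_mm2"], rel=0.03)
        assert meas["skull_vol_mm3"] == pytest.approx(truths["skull_vol_mm3"], rel=0.02)
        assert meas["hull_vol_mm3"] == pytest.approx(truths["hull_vol_mm3"], rel=0.02)
        assert meas["resp_vol_mm3"] == pytest.approx(
            truths["main_airway_vol_mm3"], rel=0.01
        )

    def test_hull_contains_skull(self, default_phantom):
        vol, _, _ = default_phantom
        meas = measure_specimen(vol)
        assert meas["hull_vol_mm3"] >= meas["skull_vol_mm3"]

    def test_respiratory_subset_of_nasal(self, default_phantom):
        vol, _, _ = default_phantom
        meas = measure_specimen(vol)
        assert meas["resp_vol_mm3"] <= meas["nasal_vol_mm3"]

    def test_empty_olfactory_label_makes_nasal_equal_respiratory(self):
        from nasallom.phantom import PhantomSpec, generate_skull_phantom

        # split plane caudal of the cavity: olfactory partition empty
        spec = PhantomSpec(split_point=(40.0, 16.0, 16.0))
        vol, _, truths = generate_skull_phantom(spec)
        assert truths["olfactory_vol_mm3"] == 0.0
        meas = measure_specimen(vol)
        assert meas["nasal_vol_mm3"] == meas["resp_vol_mm3"]
        assert meas["nasal_sa_mm2"] == meas["resp_sa_mm2"]

    def test_missing_bone_label_raises(self):
        vol = _volume_with(np.ones((5, 5, 5), dtype=bool), name="main_airway")
        vol.labels["bone"] = 9
        with pytest.raises(EmptyRegionError):
            measure_specimen(vol)
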