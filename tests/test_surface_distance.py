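"""Iso-surface extraction, exact closest distances, labeling, summaries."""

import json

import numpy as np
import pytest

from voxelreg.surface_distance import (
    SurfaceError,
    SurfaceMesh,
    _TriangleIndex,
    band_index,
    closest_distances,
    closest_distances_bruteforce,
    distance_band_colors,
    export_distance_map,
    extract_surface,
    label_regions,
    summarize_regions,
)
from voxelreg.volume_io import BinaryMask, Volume


def sphere_volume(radius=10.0, n=64, spacing=0.5):
    """Signed radial field: iso-level 0 is a sphere of the given radius."""
    x = (np.arange(n) - n / 2 + 0.5) * spacing
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    origin = -(n / 2 - 0.5) * spacing * np.ones(3)
    return Volume(1000.0 * (radius - r), np.full(3, spacing), origin)


def plane_mesh(z, nx=6, ny=6, step=1.0):
    """A square triangulated patch in the plane Z = z, normal +z."""
    xs, ys = np.meshgrid(np.arange(nx) * step, np.arange(ny) * step, indexing="ij")
    verts = np.stack([xs.ravel(), ys.ravel(), np.full(nx * ny, float(z))], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            faces.append([a, a + ny, a + 1])
            faces.append([a + 1, a + ny, a + ny + 1])
    return SurfaceMesh(verts, np.array(faces))


class TestExtractSurface:
    def test_sphere_area_within_two_percent(self):
        mesh = extract_surface(sphere_volume(), iso_level=0.0)
        tri = mesh.vertices[mesh.faces]
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
        assert area == pytest.approx(4 * np.pi * 100, rel=0.02)

    def test_all_air_volume_raises(self):
        vol = Volume(np.full((8, 8, 8), -1000.0), (1, 1, 1))
        with pytest.raises(SurfaceError, match="iso-crossing"):
            extract_surface(vol)

    def test_spacing_scales_world_coordinates(self):
        vol1 = sphere_volume(radius=5.0, n=32, spacing=0.5)
        vol2 = Volume(vol1.data, vol1.spacing * 2, vol1.origin * 2)
        m1 = extract_surface(vol1, iso_level=0.0)
        m2 = extract_surface(vol2, iso_level=0.0)
        assert np.allclose(m2.vertices, 2 * m1.vertices, atol=1e-9)

    def test_outward_normals_on_sphere(self):
        mesh = extract_surface(sphere_volume(), iso_level=0.0)
        tri = mesh.vertices[mesh.faces]
        centers = tri.mean(axis=1)
        outward = centers / np.linalg.norm(centers, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", mesh.face_normals(), outward)
        assert np.mean(dots) > 0.99


class TestClosestDistances:
    def test_self_distance_is_zero(self):
        mesh = plane_mesh(0.0)
        out = closest_distances(plane_mesh(0.0), mesh)
        assert np.abs(out.absolute_distance_mm).max() <= 1e-12

    def test_parallel_planes_give_exact_separation_and_constant_sign(self):
        reference = plane_mesh(0.0)
        query = plane_mesh(0.5)
        # query only the interior vertices (edge vertices see the same planes)
        out = closest_distances(query, reference)
        assert np.abs(out.absolute_distance_mm - 0.5).max() <= 1e-9
        assert (np.sign(out.signed_distance_mm) == 1.0).all()  # above = in front

    def test_concentric_spheres_give_radial_gap(self):
        inner = extract_surface(sphere_volume(10.0), iso_level=0.0)
        outer = extract_surface(sphere_volume(10.5), iso_level=0.0)
        out = closest_distances(outer, inner)
        assert out.absolute_distance_mm.mean() == pytest.approx(0.5, abs=0.05)
        assert (out.signed_distance_mm > 0).all()  # outer lies outside inner
        back = closest_distances(inner, outer)
        assert (back.signed_distance_mm < 0).all()  # inner lies inside outer

    def test_accelerated_query_matches_bruteforce(self, rng):
        # random small reference meshes (<= 500 triangles) and random queries
        inner = extract_surface(sphere_volume(6.0, n=24, spacing=1.0), iso_level=0.0)
        ref = SurfaceMesh(inner.vertices, inner.faces[:500])
        pts = rng.uniform(-8, 8, (200, 3))
        index = _TriangleIndex(ref)
        fast, _, _ = index.query(pts)
        brute = closest_distances_bruteforce(pts, ref)
        assert np.abs(fast - brute).max() <= 1e-9

    def test_empty_mesh_rejected(self):
        mesh = plane_mesh(0.0)
        empty = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(SurfaceError):
            closest_distances(empty, mesh)


class TestLabelRegions:
    def _mask(self, shape, box):
        data = np.zeros(shape, bool)
        data[box] = True
        return BinaryMask(data, (1.0, 1.0, 1.0))

    def test_vertex_labeling_and_priority(self):
        shape = (10, 10, 10)
        fh = self._mask(shape, (slice(0, 5), slice(None), slice(None)))
        cb = self._mask(shape, (slice(3, 7), slice(None), slice(None)))
        mesh = SurfaceMesh(
            np.array([[1.0, 5.0, 5.0], [4.0, 5.0, 5.0], [9.0, 5.0, 5.0]]),
            np.array([[0, 1, 2]]),
        )
        label_regions(mesh, {"CB": cb, "FH": fh})
        assert mesh.region_labels[0] == "FH"  # only FH contains it
        assert mesh.region_labels[1] == "CB"  # overlap: CB wins by priority
        assert mesh.region_labels[2] == ""  # in no mask

    def test_counts_match_bruteforce_point_in_mask(self, coarse_pair):
        fixed, _moving, truth = coarse_pair
        mesh = extract_surface(fixed, iso_level=300.0)
        masks = truth.evaluation_masks()
        label_regions(mesh, masks)
        # brute-force recount with an independent (priority-aware) lookup
        from voxelreg.volume_io import world_to_voxel

        expected = {}
        assigned = np.full(mesh.n_vertices, "", dtype="<U4")
        for name in ("CB", "FH", "ZL", "ZR"):
            mask = masks[name]
            idx = np.rint(world_to_voxel(mask, mesh.vertices)).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(mask.data.shape)), axis=1)
            hit = np.zeros(mesh.n_vertices, bool)
            hit[ok] = mask.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            hit &= assigned == ""
            assigned[hit] = name
            expected[name] = int(hit.sum())
        for name, count in expected.items():
            assert (mesh.region_labels == name).sum() == count
        assert expected["ZL"] > 0  # phantom surfaces do reach the masks


class TestSummarize:
    def _mesh_with(self, labels, dists):
        n = len(labels)
        mesh = SurfaceMesh(np.zeros((n, 3)), np.empty((0, 3), dtype=int))
        mesh.region_labels = np.array(labels, dtype="<U4")
        mesh.absolute_distance_mm = np.array(dists, dtype=float)
        mesh.signed_distance_mm = mesh.absolute_distance_mm.copy()
        return mesh

    def test_constant_distance_gives_zero_sd(self):
        s = summarize_regions(self._mesh_with(["CB"] * 5, [0.3] * 5))
        row = s.region("CB")
        assert row["mean"] == pytest.approx(0.30)
        assert row["sd"] == pytest.approx(0.0)

    def test_two_point_hand_computation(self):
        s = summarize_regions(self._mesh_with(["FH", "FH"], [0.1, 0.3]))
        row = s.region("FH")
        assert row["mean"] == pytest.approx(0.2)
        assert row["sd"] == pytest.approx(0.14142135623730953)
        assert row["se"] == pytest.approx(row["sd"] / np.sqrt(2))

    def test_empty_region_absent_not_zero(self):
        s = summarize_regions(self._mesh_with(["CB", "CB", ""], [0.1, 0.2, 9.9]))
        assert s.regions == ["CB"]
        with pytest.raises(KeyError):
            s.region("ZL")


class TestDistanceMapExport:
    def test_band_boundaries_are_half_open_multiples(self):
        k = band_index(np.array([-0.5, -0.01, 0.0, 0.49, 0.5, 0.6, 1.0]), 0.5)
        assert list(k) == [-1, -1, 0, 0, 1, 1, 2]

    def test_zero_distance_is_single_neutral_band(self):
        colors = distance_band_colors(np.zeros(4), 0.5)
        assert (colors == colors[0]).all()

    def test_plus_0p6_gets_second_positive_band_color(self):
        c = distance_band_colors(np.array([0.1, 0.6]), 0.5)
        assert not (c[0] == c[1]).all()
        assert (c[1] == distance_band_colors(np.array([0.75]), 0.5)[0]).all()

    def test_export_writes_colored_ply_and_legend(self, tmp_path):
        import trimesh

        mesh = plane_mesh(0.0)
        mesh.signed_distance_mm = np.linspace(-1.2, 1.2, mesh.n_vertices)
        mesh.absolute_distance_mm = np.abs(mesh.signed_distance_mm)
        out = tmp_path / "map.ply"
        export_distance_map(mesh, out, band_width_mm=0.5)
        back = trimesh.load(str(out), process=False)
        assert len(back.vertices) == mesh.n_vertices
        assert back.visual.vertex_colors.shape[0] == mesh.n_vertices
        legend = json.loads((tmp_path / "map.ply.legend.json").read_text())
        assert legend["band_width_mm"] == 0.5
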