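"""Cleaning, volume/area measurement, unit conversion, export round-trips."""
import numpy as np
import pytest
import trimesh as _trimesh

from bracketvol.exceptions import (
    BadDimension,
    NotCloseable,
    NotWatertight,
    UnsupportedFormat,
)
from bracketvol.mesh_ops import (
    CleanConfig,
    TriMesh,
    UnitScale,
    clean_mesh,
    export_mesh,
    load_mesh,
    mesh_area,
    mesh_volume,
    to_si,
)

from conftest import cube_mesh


@pytest.fixture
def clean_cube():
    v, f = cube_mesh()
    return clean_mesh(TriMesh(v, f))


@pytest.fixture
def icosphere():
    tm = _trimesh.creation.icosphere(subdivisions=5, radius=10.0)  # ~20k faces
    return clean_mesh(TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces)))


class TestCleanMesh:
    def test_duplicated_corner_vertices_merged(self):
        v, f = cube_mesh()
        # duplicate all 8 corners; remap half the faces to the duplicates
        v2 = np.vstack([v, v + 1e-6])
        f2 = f.copy()
        f2[6:] += 8
        mesh = clean_mesh(TriMesh(v2, f2), CleanConfig(merge_tol_px=1e-4))
        assert mesh.n_vertices == 8
        assert mesh.watertight
        assert mesh_volume(mesh) == pytest.approx(1.0, abs=1e-9)

    def test_already_clean_mesh_counts_preserved(self, icosphere):
        again = clean_mesh(icosphere)
        assert again.n_vertices == icosphere.n_vertices
        assert again.n_faces == icosphere.n_faces

    def test_open_surface_raises_not_closeable(self):
        v, f = cube_mesh()
        with pytest.raises(NotCloseable):
            clean_mesh(TriMesh(v, f[:-2]))  # remove the z=1 cap

    def test_duplicate_faces_removed(self):
        v, f = cube_mesh()
        mesh = clean_mesh(TriMesh(v, np.vstack([f, f[:3]])))
        assert mesh.n_faces == 12


class TestMeasurement:
    def test_unit_cube_volume_exact(self, clean_cube):
        assert mesh_volume(clean_cube) == pytest.approx(1.0, abs=1e-12)

    def test_unit_cube_area_exact(self, clean_cube):
        assert mesh_area(clean_cube) == pytest.approx(6.0, abs=1e-12)

    def test_icosphere_against_closed_forms(self, icosphere):
        r = 10.0
        assert mesh_volume(icosphere) == pytest.approx(
            4 / 3 * np.pi * r ** 3, rel=0.001)
        assert mesh_area(icosphere) == pytest.approx(
            4 * np.pi * r ** 2, rel=0.001)

    def test_agrees_with_independent_trimesh_measure(self, icosphere):
        tm = _trimesh.Trimesh(icosphere.vertices, icosphere.faces,
                              process=False)
        assert mesh_volume(icosphere) == pytest.approx(abs(tm.volume),
                                                       rel=1e-9)
        assert mesh_area(icosphere) == pytest.approx(tm.area, rel=1e-9)

    def test_winding_reversed_same_magnitude(self, clean_cube):
        flipped = TriMesh(clean_cube.vertices,
                          clean_cube.faces[:, ::-1], watertight=True)
        assert mesh_volume(flipped) == pytest.approx(
            mesh_volume(clean_cube), abs=1e-12)

    def test_volume_requires_watertight_flag(self):
        v, f = cube_mesh()
        with pytest.raises(NotWatertight):
            mesh_volume(TriMesh(v, f))

    def test_degenerate_triangle_zero_area(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        assert mesh_area(TriMesh(v, np.array([[0, 1, 2]]))) == 0.0

    def test_rigid_motion_invariance(self, icosphere):
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("xyz", [31, -17, 113], degrees=True)
        moved = TriMesh(rot.apply(icosphere.vertices) + [5, -3, 11],
                        icosphere.faces, watertight=True)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(icosphere),
                                                   rel=1e-9)
        assert mesh_area(moved) == pytest.approx(mesh_area(icosphere),
                                                 rel=1e-9)

    def test_subdivision_invariance(self, clean_cube):
        tm = _trimesh.Trimesh(clean_cube.vertices, clean_cube.faces,
                              process=False).subdivide()
        sub = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                      watertight=True)
        assert mesh_volume(sub) == pytest.approx(1.0, rel=1e-9)
        assert mesh_area(sub) == pytest.approx(6.0, rel=1e-9)


class TestUnits:
    def test_px3_to_m3(self):
        scale = UnitScale(body_axis_m=3.0, body_axis_px=3000)
        assert scale.m_per_px == pytest.approx(1e-3)
        assert to_si(1.0, scale, 3) == pytest.approx(1e-9)
        assert to_si(1e6, scale, 2) == pytest.approx(1.0)

    def test_bad_dimension(self):
        scale = UnitScale(body_axis_m=1.0, body_axis_px=100)
        with pytest.raises(BadDimension):
            to_si(1.0, scale, 4)


class TestExport:
    @pytest.mark.parametrize("ext", ["ply", "obj", "stl"])
    def test_round_trip_preserves_geometry(self, tmp_path, clean_cube, ext):
        p = export_mesh(clean_cube, tmp_path / f"cube.{ext}")
        back = load_mesh(p)
        back.watertight = True
        assert mesh_volume(back) == pytest.approx(1.0, rel=1e-6)
        assert mesh_area(back) == pytest.approx(6.0, rel=1e-6)
        assert back.n_vertices == clean_cube.n_vertices
        assert back.n_faces == clean_cube.n_faces

    def test_unknown_extension_rejected(self, tmp_path, clean_cube):
        with pytest.raises(UnsupportedFormat):
            export_mesh(clean_cube, tmp_path / "cube.vtk")
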