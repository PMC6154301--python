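"""Shape and transit metrics against independent geometric oracles."""

import math
import types

import numpy as np
import pytest
import trimesh

from cellpass import (
    RoughChannel,
    in_channel_mean_speed,
    mesh_surface_area,
    mesh_volume,
    penetration_time,
    polygon_area,
    polygon_centroid,
    speed_series,
)
from cellpass.exceptions import GeometryError
from cellpass.measurements import mesh_volume_centroid, _mesh_volume_axis

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])

# a closed box mesh from trimesh serves as an independent mesh source
BOX = trimesh.creation.box(extents=(1.0, 1.0, 1.0))


def make_traj(times, membrane, centroids=None, events=None, channel=None):
    membrane = np.asarray(membrane, dtype=float)
    if centroids is None:
        centroids = membrane.mean(axis=1)
    return types.SimpleNamespace(times=np.asarray(times, dtype=float),
                                 membrane=membrane,
                                 centroids=np.asarray(centroids, dtype=float),
                                 events=events or {}, channel=channel)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(UNIT_SQUARE) == 1.0

    def test_regular_30gon_closed_form(self):
        ang = 2 * math.pi * np.arange(30) / 30
        poly = 12.5 * np.column_stack([np.cos(ang), np.sin(ang)])
        assert polygon_area(poly) == pytest.approx(15 * 12.5**2 * math.sin(2 * math.pi / 30),
                                                   rel=1e-12)

    def test_orientation_invariant(self):
        assert polygon_area(UNIT_SQUARE[::-1]) == 1.0

    def test_rejects_degenerate(self):
        with pytest.raises(GeometryError):
            polygon_area(UNIT_SQUARE[:2])

    def test_ngon_area_converges_quadratically_to_circle(self):
        # pi R^2 - A_N = O(1/N^2)
        R = 12.5
        errs = []
        for N in (30, 60, 120):
            ang = 2 * math.pi * np.arange(N) / N
            poly = R * np.column_stack([np.cos(ang), np.sin(ang)])
            errs.append(math.pi * R**2 - polygon_area(poly))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.02)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.02)


class TestPolygonCentroid:
    def test_unit_square(self):
        assert np.allclose(polygon_centroid(UNIT_SQUARE), [0.5, 0.5])

    def test_translation_equivariance(self):
        shift = np.array([3.7, -1.2])
        assert np.allclose(polygon_centroid(UNIT_SQUARE + shift),
                           polygon_centroid(UNIT_SQUARE) + shift)

    def test_lshape_against_rejection_sampling(self):
        # L-shaped hexagon; oracle: uniform rejection sampling inside it
        poly = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 3], [0, 3]], dtype=float)
        from matplotlib.path import Path

        rng = np.random.default_rng(42)
        pts = rng.uniform([0, 0], [2, 3], size=(400_000, 2))
        inside = Path(poly).contains_points(pts)
        mc = pts[inside].mean(axis=0)
        assert np.allclose(polygon_centroid(poly), mc, atol=5e-3)

    def test_zero_area_falls_back_to_vertex_mean(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning):
            c = polygon_centroid(line)
        assert np.allclose(c, [1.0, 0.0])


class TestMeshVolume:
    def test_unit_cube(self):
        assert mesh_volume(BOX.vertices, BOX.faces) == pytest.approx(1.0, rel=1e-12)

    def test_icosphere_against_trimesh_oracle(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        v = mesh_volume(sph.vertices, sph.faces)
        assert v == pytest.approx(4 / 3 * math.pi * 1000.0, rel=0.01)
        assert v == pytest.approx(sph.volume, rel=1e-10)

    def test_orientation_flip_changes_sign(self):
        flipped = BOX.faces[:, ::-1]
        assert mesh_volume(BOX.vertices, flipped, check=False) == pytest.approx(-1.0)

    def test_divergence_theorem_axis_consistency(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=7.0)
        vols = [_mesh_volume_axis(np.asarray(sph.vertices), np.asarray(sph.faces), k)
                for k in range(3)]
        assert abs(vols[0] - vols[1]) / abs(vols[0]) < 1e-10
        assert abs(vols[0] - vols[2]) / abs(vols[0]) < 1e-10

    def test_open_mesh_warns(self):
        open_faces = BOX.faces[:-2]
        with pytest.warns(UserWarning):
            mesh_volume(BOX.vertices, open_faces)

    def test_volume_centroid(self):
        shifted = BOX.vertices + np.array([2.0, -1.0, 0.5])
        assert np.allclose(mesh_volume_centroid(shifted, BOX.faces),
                           [2.0, -1.0, 0.5], atol=1e-12)


class TestMeshSurfaceArea:
    def test_unit_cube(self):
        assert mesh_surface_area(BOX.vertices, BOX.faces) == pytest.approx(6.0)

    def test_icosphere(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        assert mesh_surface_area(sph.vertices, sph.faces) == pytest.approx(
            4 * math.pi * 100.0, rel=0.01)

    def test_degenerate_triangle_contributes_zero(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        assert mesh_surface_area(verts, np.array([[0, 1, 2]])) == 0.0


class TestPenetrationTime:
    channel = RoughChannel(y0=5.0, epsilon=0.0, omega=0.0, x_entry=0.0, length=60.0)

    def synthetic(self):
        # point-like cell translating at 200 um/h: enters x=0 at t=0.10 and
        # clears x=60 at t=0.40 -> tau = 0.30 by construction
        times = np.round(np.arange(0.0, 0.5001, 0.01), 6)
        frames = []
        for t in times:
            xc = -20.0 + 200.0 * t
            frames.append([[xc, 0.0], [xc, 1.0], [xc - 0.001, 0.5]])
        return make_traj(times, frames, channel=self.channel)

    def test_constructed_tau(self):
        tau = penetration_time(self.synthetic(), self.channel)
        assert tau == pytest.approx(0.30, abs=0.011)

    def test_never_reaching_cell_returns_none(self):
        times = [0.0, 0.1]
        frames = [[[-30.0, 0.0], [-10.0, 0.0], [-20.0, 1.0]]] * 2
        assert penetration_time(make_traj(times, frames), self.channel) is None

    def test_event_log_takes_precedence(self):
        traj = self.synthetic()
        traj.events = {"channel_entry": 0.1, "channel_exit": 0.4}
        assert penetration_time(traj, self.channel) == pytest.approx(0.30)


class TestSpeedSeries:
    def test_stationary_cell_zero(self):
        frames = [UNIT_SQUARE, UNIT_SQUARE, UNIT_SQUARE]
        t, v = speed_series(make_traj([0.0, 0.1, 0.2], frames))
        assert np.allclose(v, 0.0)

    def test_uniform_translation(self):
        vel = np.array([120.0, -50.0])
        times = np.linspace(0, 0.2, 9)
        frames = [UNIT_SQUARE + vel * t for t in times]
        t, v = speed_series(make_traj(times, frames))
        assert np.allclose(v, np.linalg.norm(vel), rtol=1e-9)

    def test_in_channel_mean_restricts_to_channel(self):
        chan = RoughChannel(y0=5.0, epsilon=0.0, omega=0.0, length=60.0)
        times = np.linspace(0.0, 1.0, 101)
        # 100 um/h before entry, 200 inside (x in [0,60]), then stationary
        xs = []
        x = -10.0
        for k in range(101):
            xs.append(x)
            x += (200.0 if 0 <= x < 60 else (100.0 if x < 0 else 0.0)) * 0.01
        frames = [UNIT_SQUARE - 0.5 + np.array([xx, 0.0]) for xx in xs]
        traj = make_traj(times, frames)
        assert in_channel_mean_speed(traj, chan) == pytest.approx(200.0, rel=0.02)
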