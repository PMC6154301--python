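"""Shape and transit metrics.

2D cell shapes are simple polygons traced by the ordered membrane (or
nucleus) nodes; 3D shapes are closed triangulated surfaces.  Areas use the
shoelace rule written as a boundary integral of ``x n_x``; volumes use the
divergence theorem over the triangulation, taking the x-component of the
(un-normalised) triangle cross products.  Transit metrics (penetration
time, centroid speed) operate on recorded trajectories.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "polygon_area",
    "polygon_centroid",
    "mesh_volume",
    "mesh_surface_area",
    "mesh_volume_centroid",
    "penetration_time",
    "speed_series",
    "in_channel_mean_speed",
]


def _centroid_fast(v: np.ndarray) -> np.ndarray:
    """Area-weighted polygon centroid without validation (hot path)."""
    from ._kernels import polygon_centroid_xy

    return np.array(polygon_centroid_xy(v))


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned shoelace area of an ordered vertex ring (μm²).

    The signed shoelace value is wrapped in an absolute value so that the
    node orientation never flips downstream metrics.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or len(v) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(abs(0.5 * np.sum((xn + x) * (yn - y))))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon.

    Falls back (with a warning) to the vertex mean when the signed area
    vanishes, e.g. for collinear rings.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or len(v) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-14 * max(1.0, np.abs(v).max() ** 2):
        warnings.warn("zero-area polygon; returning vertex mean", stacklevel=2)
        return v.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _triangle_cross(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = vertices[faces[:, 0]]
    return np.cross(vertices[faces[:, 1]] - a, vertices[faces[:, 2]] - a)


def _mesh_volume_axis(vertices, faces, axis: int) -> float:
    cr = _triangle_cross(vertices, faces)
    coord_sum = vertices[faces, axis].sum(axis=1)
    return float(np.sum(cr[:, axis] * coord_sum) / 6.0)


def mesh_volume(vertices: np.ndarray, faces: np.ndarray, check: bool = True) -> float:
    """Signed volume of a triangulated surface via the divergence theorem.

    Uses the x-projection ``V = sum |Δ_j| n_x / 6 * sum_m x_m``; a closed,
    consistently oriented mesh gives the same value through the y- and
    z-projections, and a disagreement beyond 1% triggers an open-mesh
    warning.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    vx = _mesh_volume_axis(vertices, faces, 0)
    if check:
        vy = _mesh_volume_axis(vertices, faces, 1)
        vz = _mesh_volume_axis(vertices, faces, 2)
        scale = max(abs(vx), abs(vy), abs(vz), 1e-300)
        if max(abs(vx - vy), abs(vx - vz)) / scale > 0.01:
            warnings.warn(
                "divergence-theorem volumes disagree by > 1%: "
                f"x={vx:.6g} y={vy:.6g} z={vz:.6g}; mesh may be open "
                "or inconsistently oriented",
                stacklevel=2,
            )
    return vx


def mesh_surface_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Total triangle area, ``1/2 sum ||cross||`` (μm²)."""
    cr = _triangle_cross(np.asarray(vertices, float), np.asarray(faces, int))
    return float(0.5 * np.sum(np.linalg.norm(cr, axis=1)))


def mesh_volume_centroid(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Volume centroid of a closed mesh (signed tetrahedra from the origin)."""
    vertices = np.asarray(vertices, dtype=float)
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    vols = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    vtot = vols.sum()
    if abs(vtot) < 1e-12:
        warnings.warn("zero-volume mesh; returning vertex mean", stacklevel=2)
        return vertices.mean(axis=0)
    cent = (vols[:, None] * (a + b + c) / 4.0).sum(axis=0) / vtot
    return cent


# -- transit metrics ------------------------------------------------------


def penetration_time(traj, channel) -> float | None:
    """Transit (penetration) time τ through a channel, in hours.

    Entry is the first frame at which *any* membrane node has
    ``x > x_entry``; exit the first frame at which *all* membrane nodes
    have ``x > x_entry + length``.  Returns ``None`` for incomplete
    transits.  If the trajectory's event log already contains exact
    entry/exit times (recorded online at full step resolution) those are
    preferred over the possibly subsampled frames.
    """
    events = getattr(traj, "events", None) or {}
    if "channel_entry" in events and "channel_exit" in events:
        return float(events["channel_exit"] - events["channel_entry"])
    x0 = channel.x_entry
    x1 = channel.x_entry + channel.length
    xs = np.asarray(traj.membrane)[:, :, 0]
    entered = np.nonzero(xs.max(axis=1) > x0)[0]
    exited = np.nonzero(xs.min(axis=1) > x1)[0]
    if len(entered) == 0 or len(exited) == 0:
        return None
    return float(traj.times[exited[0]] - traj.times[entered[0]])


def speed_series(traj) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference centroid speed trace (μm/h).

    Returns ``(t_mid, speed)`` where ``speed[k]`` is the displacement of
    the membrane polygon centroid between frames k and k+1 divided by the
    frame spacing, and ``t_mid`` the midpoints of the frame times.
    """
    cents = np.asarray(traj.centroids, dtype=float)
    times = np.asarray(traj.times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two frames for a speed trace")
    dt = np.diff(times)
    disp = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    return 0.5 * (times[:-1] + times[1:]), disp / dt


def in_channel_mean_speed(traj, channel) -> float:
    """Mean centroid speed over frames whose centroid lies in the channel."""
    t_mid, v = speed_series(traj)
    cents = np.asarray(traj.centroids, dtype=float)
    xmid = 0.5 * (cents[:-1, 0] + cents[1:, 0])
    x0, x1 = channel.x_entry, channel.x_entry + channel.length
    mask = (xmid >= x0) & (xmid < x1)
    if not mask.any():
        raise ValueError("trajectory never places the centroid inside the channel")
    return float(v[mask].mean())
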