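"""Cell/nucleus state, initial meshing, equilibrium offsets and polarity.

The cell is a ring (2D) or spherical lattice (3D) of membrane nodes, each
tethered to a corresponding node on the nucleus surface; nucleus nodes are
in turn tethered to the nucleus centre.  The tether rest vectors -- the
*equilibrium offsets* ``xhat`` (membrane node minus nucleus node at t=0)
and ``xhat_n`` (nucleus node minus centre at t=0) -- encode the rest shape,
so relaxing toward them restores the initial circle/sphere after a
deformation.  A rigid rotation fitted to the current membrane configuration
is applied to the offsets each step, giving the cell a persistent polarity:
it recovers its shape *and* its orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .exceptions import ParameterError
from .measurements import _centroid_fast, mesh_volume_centroid, polygon_centroid

__all__ = [
    "CellParams",
    "CellState",
    "init_cell_2d",
    "init_cell_3d",
    "fit_rotation_2d",
    "fit_rotation_3d",
    "rotation_matrix_2d",
    "rotation_matrix_3d",
]


@dataclass
class CellParams:
    """Cell geometry and rate constants (2D defaults).

    R, R_n : cell / nucleus radius, μm (3D defaults are 10 and 8)
    N      : membrane node count (longitudes in 3D)
    M      : latitude count, 3D only
    alpha, alpha_n : cell / nucleus deformation relaxation rates, 1/h
    beta   : mobility response to the signal gradient, 1/h
    eta    : random-walk amplitude, μm/sqrt(h)
    """

    R: float = 12.5
    R_n: float = 5.0
    N: int = 30
    M: int = 30
    alpha: float = 250.0
    alpha_n: float = 2500.0
    beta: float = 60.0
    eta: float = 5.0

    def __post_init__(self) -> None:
        if not (self.R > self.R_n > 0):
            raise ParameterError(
                f"need R > R_n > 0, got R={self.R}, R_n={self.R_n}"
            )
        if self.N < 3:
            raise ParameterError(f"need N >= 3 membrane nodes, got {self.N}")
        for name in ("alpha", "alpha_n", "beta", "eta"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def with_overrides(self, **kw) -> "CellParams":
        return replace(self, **kw)


def defaults_3d(**kw) -> CellParams:
    """Table of 3D defaults: R = 10 μm, R_n = 8 μm, 30 latitude circles."""
    base = dict(R=10.0, R_n=8.0, N=30, M=30)
    base.update(kw)
    return CellParams(**base)


@dataclass
class CellState:
    """Node positions, equilibrium offsets and fitted orientation.

    ``x`` and ``x_n`` are the membrane and nucleus node arrays (n, dim),
    paired index-by-index.  ``faces`` triangulates the node lattice in 3D
    (shared by membrane and nucleus).  ``phi`` is the fitted orientation:
    a scalar in 2D, the (phi_x, phi_y, phi_z) triple in 3D.
    """

    params: CellParams
    x: np.ndarray
    x_n: np.ndarray
    xhat: np.ndarray
    xhat_n: np.ndarray
    x_c: np.ndarray
    x_ref: np.ndarray
    phi: float | tuple = 0.0
    faces: np.ndarray | None = field(default=None, repr=False)

    @property
    def dim(self) -> int:
        return self.x.shape[1]

    def membrane_centroid(self) -> np.ndarray:
        if self.dim == 2:
            return _centroid_fast(self.x)
        return self.x.mean(axis=0)

    def nucleus_center(self) -> np.ndarray:
        """Area (2D) or volume (3D) centroid of the nucleus shape."""
        if self.dim == 2:
            return _centroid_fast(self.x_n)
        return mesh_volume_centroid(self.x_n, self.faces)

    def copy(self) -> "CellState":
        return CellState(
            params=self.params,
            x=self.x.copy(),
            x_n=self.x_n.copy(),
            xhat=self.xhat.copy(),
            xhat_n=self.xhat_n.copy(),
            x_c=self.x_c.copy(),
            x_ref=self.x_ref.copy(),
            phi=self.phi,
            faces=self.faces,
        )


def init_cell_2d(params: CellParams, center=(0.0, 0.0)) -> CellState:
    """Circular cell with node i at angle 2π(i-1)/N on both rings.

    At t=0 the offset identities x_i = x_n_i + xhat_i and
    x_n_i = x_c + xhat_n_i hold exactly, so the initial state is an exact
    equilibrium of the noise-free dynamics.
    """
    center = np.asarray(center, dtype=float)
    ang = 2.0 * math.pi * np.arange(params.N) / params.N
    ring = np.column_stack([np.cos(ang), np.sin(ang)])
    x = center + params.R * ring
    x_n = center + params.R_n * ring
    return CellState(
        params=params,
        x=x,
        x_n=x_n,
        xhat=x - x_n,
        xhat_n=x_n - center,
        x_c=center.copy(),
        x_ref=x - center,
        phi=0.0,
    )


def _sphere_lattice(R: float, N: int, M: int, center: np.ndarray) -> np.ndarray:
    """Spherical node lattice: poles plus M-1 latitude rings of N nodes.

    The raw lattice formula places N coincident nodes on the north pole
    (the j=1 latitude collapses since sin 0 = 0) and none on the south
    pole; duplicates are merged into a single pole node and the south pole
    is added so the triangulated surface closes.
    """
    pts = [center + np.array([0.0, 0.0, R])]
    for j in range(2, M + 1):
        th = math.pi * (j - 1) / M
        for i in range(1, N + 1):
            ph = 2.0 * math.pi * (i - 1) / N
            pts.append(
                center
                + R
                * np.array(
                    [math.cos(ph) * math.sin(th), math.sin(ph) * math.sin(th), math.cos(th)]
                )
            )
    pts.append(center + np.array([0.0, 0.0, -R]))
    return np.array(pts)


def _sphere_faces(N: int, M: int) -> np.ndarray:
    """Consistently outward-oriented triangulation of the lattice."""
    faces = []
    ring = lambda j: 1 + (j - 2) * N  # first index of latitude ring j (j=2..M)
    # north cap
    for i in range(N):
        faces.append([0, ring(2) + i, ring(2) + (i + 1) % N])
    # quad strips
    for j in range(2, M):
        a, b = ring(j), ring(j + 1)
        for i in range(N):
            i2 = (i + 1) % N
            faces.append([a + i, b + i, b + i2])
            faces.append([a + i, b + i2, a + i2])
    # south cap
    south = 1 + (M - 1) * N
    a = ring(M)
    for i in range(N):
        faces.append([south, a + (i + 1) % N, a + i])
    return np.array(faces, dtype=int)


def init_cell_3d(params: CellParams, center=(0.0, 0.0, 0.0)) -> CellState:
    """Spherical cell: matching membrane (radius R) and nucleus (R_n) lattices."""
    if params.M < 3:
        raise ParameterError(f"need M >= 3 latitudes, got {params.M}")
    center = np.asarray(center, dtype=float)
    x = _sphere_lattice(params.R, params.N, params.M, center)
    x_n = _sphere_lattice(params.R_n, params.N, params.M, center)
    faces = _sphere_faces(params.N, params.M)
    return CellState(
        params=params,
        x=x,
        x_n=x_n,
        xhat=x - x_n,
        xhat_n=x_n - center,
        x_c=center.copy(),
        x_ref=x - center,
        phi=(0.0, 0.0, 0.0),
        faces=faces,
    )


# -- rotation (polarity) fitting ------------------------------------------


def rotation_matrix_2d(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


def rotation_matrix_3d(phi_x: float, phi_y: float, phi_z: float) -> np.ndarray:
    """Composition B = Bx(phi_x) · By(phi_y) · Bz(phi_z).

    By follows the sign convention of the model definition (its (1,3)
    entry is -sin), i.e. it equals the conventional y-rotation through
    -phi_y.
    """
    cx, sx = math.cos(phi_x), math.sin(phi_x)
    cy, sy = math.cos(phi_y), math.sin(phi_y)
    cz, sz = math.cos(phi_z), math.sin(phi_z)
    Bx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    By = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    Bz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Bx @ By @ Bz


def fit_rotation_2d(state: CellState) -> float:
    """Best-fit rigid rotation of the reference shape onto the current one.

    Minimises sum ||B(phi) xref_i - d_i||^2 where d_i are the current
    membrane nodes about their centroid; the argmin is the closed form
    phi = atan2(sum xref x d, sum xref . d), reduced to [0, 2π).
    """
    from ._kernels import polygon_centroid_xy, rotation_angle_2d

    cx, cy = polygon_centroid_xy(state.x)
    s, c = rotation_angle_2d(state.x, state.x_ref, cx, cy)
    if s == 0.0 and c == 0.0:
        warnings.warn("all membrane nodes coincident; rotation set to 0", stacklevel=2)
        return 0.0
    phi = math.atan2(s, c) % (2.0 * math.pi)
    # a roundoff-negative atan2 must not alias to just below 2*pi
    return 0.0 if 2.0 * math.pi - phi < 1e-12 else phi


def fit_rotation_3d(state: CellState) -> tuple[float, float, float]:
    """Orthogonal-Procrustes best proper rotation, as Bx·By·Bz angles.

    The optimal rotation mapping the centred reference lattice onto the
    current membrane nodes is found by Kabsch/SVD; the Euler angles are
    then extracted in the model's Bx(phi_x)·By(phi_y)·Bz(phi_z) factor
    order (note the flipped sign of phi_y versus the conventional
    y-rotation).
    """
    d = state.x - state.x.mean(axis=0)
    ref = state.x_ref
    H = ref.T @ d
    if np.linalg.matrix_rank(H, tol=1e-9 * max(1.0, np.abs(H).max())) < 2:
        warnings.warn("degenerate node configuration; identity rotation", stacklevel=2)
        return (0.0, 0.0, 0.0)
    rot, _ = _Rotation.align_vectors(d, ref)
    a, b, c = rot.as_euler("XYZ")
    return (float(a), float(-b), float(c))


def fit_rotation(state: CellState):
    return fit_rotation_2d(state) if state.dim == 2 else fit_rotation_3d(state)


def offset_rotation(state: CellState) -> np.ndarray:
    """Rotation matrix B(phi) for the state's currently fitted angles."""
    if state.dim == 2:
        return rotation_matrix_2d(state.phi)
    return rotation_matrix_3d(*state.phi)
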