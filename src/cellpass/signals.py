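"""Chemoattractant fields built from free-space Green's functions.

A point source secreting a chemokine at rate ``gamma_s`` into an unbounded
medium with diffusivity ``D`` produces a quasi-steady concentration field.
In 2D this is the logarithmic fundamental solution of the Poisson equation,

    c(x) = -gamma_s / (2 pi D) * ln ||x - x_S||,

and fields of several sources superpose.  The drift entering the equations
of motion is not the analytic gradient of ``c`` but the linear-implicit
(IMEX) form used by the time integrator: the direction is evaluated at the
*new* node position while the squared distance in the denominator is frozen
at the *old* one,

    grad c = gamma_s (x_S - x_new) / (pi D ||x_S - x_old||^2)      (2D).

Note the ``pi D`` denominator: it is a factor 2 larger than the analytic
gradient of the logarithmic solution.  The drift is phenomenological (the
mobility ``beta`` absorbs constant factors) and the ``pi D`` form is the
one the integrator is defined with; a regression test pins this choice.

In 3D two flavours are supported: the ``"paper"`` form ``c = gamma_s /
(4 pi D r^2)`` (with IMEX gradient ``gamma_s (x_S - x_new) / (2 pi D
r_old^4)``) and the standard ``"physical"`` fundamental solution
``c = gamma_s / (4 pi D r)`` (gradient ``gamma_s (x_S - x_new) /
(4 pi D r_old^3)``).

The 2D concentration is negative for ``r > 1`` μm; that is accepted, since
only the gradient enters the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib.path import Path as _MplPath

from .exceptions import GeometryError, SingularEvaluationError

__all__ = [
    "ChemokineSource",
    "SignalField",
    "concentration",
    "imex_gradient",
    "consume_sources",
]

#: tolerance used to count a point as "on" the cell boundary when testing
#: whether a source has been engulfed (boundary points count as inside)
_BOUNDARY_RADIUS = 1e-9


@dataclass
class ChemokineSource:
    """A point source of chemoattractant.

    Parameters
    ----------
    position : array-like of shape (2,) or (3,)
        Source location in μm.
    rate : float
        Secretion rate ``gamma_s`` in mol/(h·μm³); must be non-negative.
    active : bool
        Inactive sources contribute zero to field and gradient.  Once a
        source has been consumed by a cell the flag is cleared permanently.
    t_on, t_off : float or None
        Optional activity window in hours.
    """

    position: np.ndarray
    rate: float
    active: bool = True
    t_on: float | None = None
    t_off: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.rate < 0:
            raise ValueError(f"secretion rate must be >= 0, got {self.rate}")

    def is_active(self, t: float = 0.0) -> bool:
        if not self.active:
            return False
        if self.t_on is not None and t < self.t_on:
            return False
        if self.t_off is not None and t >= self.t_off:
            return False
        return True


@dataclass
class SignalField:
    """Superposition of point-source chemokine fields.

    ``form`` selects the 3D flavour: ``"paper"`` uses the inverse-square
    concentration, ``"physical"`` the standard ``1/(4 pi D r)`` fundamental
    solution.  The 2D expressions are independent of ``form``.
    """

    sources: list[ChemokineSource] = field(default_factory=list)
    D: float = 3600.0  # μm²/h
    dim: int = 2
    form: str = "paper"

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusivity must be > 0, got {self.D}")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.form not in ("paper", "physical"):
            raise ValueError("form must be 'paper' or 'physical'")

    # -- public evaluation ------------------------------------------------

    def concentration(self, x, t: float = 0.0) -> float | np.ndarray:
        """Field value at position(s) ``x`` (superposed over active sources)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        pts = np.atleast_2d(x)
        out = np.zeros(len(pts))
        for src in self.sources:
            if not src.is_active(t):
                continue
            r = np.linalg.norm(pts - src.position, axis=1)
            if np.any(r == 0.0):
                raise SingularEvaluationError(
                    "concentration evaluated at a source position"
                )
            if self.dim == 2:
                out += -src.rate / (2.0 * math.pi * self.D) * np.log(r)
            elif self.form == "paper":
                out += src.rate / (4.0 * math.pi * self.D * r**2)
            else:
                out += src.rate / (4.0 * math.pi * self.D * r)
        return out[0] if single else out

    def imex_coefficients(self, x_old, t: float = 0.0):
        """Linear-implicit gradient split at old positions ``x_old``.

        Returns ``(s, S)`` with ``s`` of shape (n,) and ``S`` of shape
        (n, dim) such that the IMEX gradient at the (yet unknown) new
        positions is ``S - s[:, None] * x_new``.  This is what the
        implicit membrane update needs.
        """
        pts = np.atleast_2d(np.asarray(x_old, dtype=float))
        s = np.zeros(len(pts))
        S = np.zeros_like(pts)
        if self.dim == 2:
            active = [sr for sr in self.sources if sr.is_active(t)]
            if active:
                from ._kernels import imex_coeffs_2d

                src_xy = np.array([sr.position for sr in active])
                rates = np.array([sr.rate for sr in active])
                ok = imex_coeffs_2d(pts, src_xy, rates, self.D, s, S)
                if not ok:
                    raise SingularEvaluationError(
                        "gradient denominator evaluated at a source position"
                    )
            return s, S
        for src in self.sources:
            if not src.is_active(t):
                continue
            d = pts - src.position
            r2 = np.einsum("ij,ij->i", d, d)
            if np.any(r2 == 0.0):
                raise SingularEvaluationError(
                    "gradient denominator evaluated at a source position"
                )
            if self.dim == 2:
                k = src.rate / (math.pi * self.D * r2)
            elif self.form == "paper":
                k = src.rate / (2.0 * math.pi * self.D * r2**2)
            else:
                k = src.rate / (4.0 * math.pi * self.D * r2**1.5)
            s += k
            S += k[:, None] * src.position
        return s, S

    def imex_gradient(self, x_new, x_old, t: float = 0.0) -> np.ndarray:
        """IMEX chemotactic drift direction, new numerator over old denominator."""
        x_new = np.asarray(x_new, dtype=float)
        single = x_new.ndim == 1
        new = np.atleast_2d(x_new)
        s, S = self.imex_coefficients(x_old, t)
        g = S - s[:, None] * new
        return g[0] if single else g


# -- module-level operation wrappers --------------------------------------


def concentration(field: SignalField, x, t: float = 0.0):
    return field.concentration(x, t)


def imex_gradient(field: SignalField, x_new, x_old, t: float = 0.0):
    return field.imex_gradient(x_new, x_old, t)


def _point_in_polygon(point: np.ndarray, ring: np.ndarray) -> bool:
    """Even-odd containment with boundary points counting as inside."""
    path = _MplPath(ring, closed=False)
    return bool(path.contains_point(point, radius=_BOUNDARY_RADIUS)) or bool(
        path.contains_point(point, radius=-_BOUNDARY_RADIUS)
    )


def point_in_mesh(point: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> bool:
    """Ray-crossing parity test for a closed triangulated surface (3D)."""
    point = np.asarray(point, dtype=float)
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    # Moller-Trumbore against a fixed ray direction; irrational-ish
    # components keep the ray away from edges/vertices of lattice meshes.
    d = np.array([0.577350269189626, 0.211324865405187, 0.788675134594813])
    h = np.cross(d, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    s = point - v0
    u = np.where(ok, np.einsum("ij,ij->i", s, h) / np.where(ok, a, 1.0), -1.0)
    q = np.cross(s, e1)
    v = np.where(ok, np.dot(q, d) / np.where(ok, a, 1.0), -1.0)
    t = np.where(ok, np.einsum("ij,ij->i", e2, q) / np.where(ok, a, 1.0), -1.0)
    hits = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
    return bool(np.count_nonzero(hits) % 2 == 1)


def consume_sources(
    field: SignalField,
    cell_boundary: Sequence | np.ndarray,
    faces: np.ndarray | None = None,
    t: float = 0.0,
) -> SignalField:
    """Permanently deactivate sources engulfed by the cell.

    ``cell_boundary`` is an ordered ring of membrane vertices in 2D, or the
    membrane vertex array in 3D together with a ``faces`` triangulation.
    A source exactly on the boundary counts as inside.  Returns ``field``
    (sources are mutated in place; deactivation is permanent).
    """
    boundary = np.asarray(cell_boundary, dtype=float)
    if boundary.ndim != 2 or len(boundary) < 3:
        raise GeometryError("cell boundary must be a closed ring of >= 3 vertices")
    if boundary.shape[1] == 3 and faces is None:
        raise GeometryError("3D consumption test requires a surface triangulation")
    for src in field.sources:
        if not src.is_active(t):
            continue
        if boundary.shape[1] == 2:
            inside = _point_in_polygon(src.position, boundary)
        else:
            inside = point_in_mesh(src.position, boundary, faces)
        if inside:
            src.active = False
    return field
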