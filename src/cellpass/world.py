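"""Rigid obstacles, rough channels, contact detection and projection.

Obstacles are perfectly rigid and immobile.  Contact handling follows the
no-penetration rule of the model: when a node on the obstacle boundary
attempts to move into it, the normal component of its displacement is
removed, so the node slides tangentially ("the obstacle slows down the
migration").  Because pure point-membership almost never triggers in
floating point, membership is operationalised with a tolerance plus a
swept-segment crossing test, and any residual interior point after the
tangential projection is clamped back to the nearest boundary point --
this prevents slow tunnelling at finite time steps.

The rough channel of the transmigration scenarios has walls

    y = ±(y0 + ε sin(ω x)),    x in [x_entry, x_entry + L],

realised as two rigid slabs of finite thickness with vertical end faces;
nodes beyond the channel x-extent are unconstrained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "Obstacle",
    "DiscObstacle",
    "HalfPlaneWall",
    "RoughSlabWall",
    "World",
    "RoughChannel",
    "channel_wall",
    "wall_normal",
    "project_displacement",
    "detect_contact",
    "cell_cell_contact",
]


class Obstacle:
    """Implicit rigid body: signed distance (positive outside) + outward normal."""

    kind = "obstacle"

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def normal(self, pts: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.signed_distance(np.atleast_2d(pts)) < 0

    def coarse_reject(self, pts: np.ndarray, margin: float) -> bool:
        """Cheap conservative test: True only if no point can be in contact."""
        return False

    def bounds(self):
        """Static axis-aligned bounding box ``(lo, hi)``, or None if unbounded."""
        return None


@dataclass
class DiscObstacle(Obstacle):
    """Disc (2D) or sphere (3D)."""

    center: np.ndarray
    radius: float
    kind = "disc"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise GeometryError("disc radius must be positive")

    def signed_distance(self, pts):
        d = np.atleast_2d(pts) - self.center
        return np.linalg.norm(d, axis=1) - self.radius

    def normal(self, pts):
        d = np.atleast_2d(pts) - self.center
        r = np.linalg.norm(d, axis=1)
        r = np.where(r == 0.0, 1.0, r)
        return d / r[:, None]

    def bounds(self):
        return (self.center - self.radius, self.center + self.radius)


@dataclass
class HalfPlaneWall(Obstacle):
    """Half-space obstacle; ``outward`` points away from the solid."""

    point: np.ndarray
    outward: np.ndarray
    kind = "halfplane-wall"

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.outward = np.asarray(self.outward, dtype=float)
        self.outward = self.outward / np.linalg.norm(self.outward)

    def signed_distance(self, pts):
        return (np.atleast_2d(pts) - self.point) @ self.outward

    def normal(self, pts):
        return np.broadcast_to(self.outward, np.atleast_2d(pts).shape).copy()


@dataclass
class RoughSlabWall(Obstacle):
    """One wall of a rough channel: a rigid slab bounded by a sinusoid.

    In the side-normalised frame yhat = side*y the solid occupies
    ``g(x) <= yhat <= g(x) + thickness`` for ``x in [x0, x1]`` with
    ``g(x) = y0 + eps sin(omega x)``.  ``side=+1`` is the upper wall.
    Signed distances to the sinusoidal faces are measured vertically
    (the wall slope never exceeds eps*omega ~ 1 in the scenarios, so this
    underestimates true clearance by at most sqrt(2)); end faces and
    corners are handled exactly.

    With ``end_faces=False`` the slab models an open-ended thin sheet:
    only the two sinusoidal faces carry contact and the sheet edges at
    ``x0``/``x1`` do not.  A micron-scale sheet edge cannot realistically
    pin a cell, and a capped edge creates a concave pocket at the channel
    mouth where a node would jam permanently under the projection rule.
    """

    x0: float
    x1: float
    y0: float
    eps: float
    omega: float
    side: int = 1
    thickness: float = 10.0
    end_faces: bool = True
    kind = "channel-wall"

    def __post_init__(self) -> None:
        if self.y0 <= self.eps or self.eps < 0 or self.omega < 0:
            raise GeometryError("need y0 > eps >= 0 and omega >= 0")
        if self.x1 <= self.x0:
            raise GeometryError("need x1 > x0")
        if self.side not in (-1, 1):
            raise GeometryError("side must be +1 (upper) or -1 (lower)")

    def _g(self, x):
        return self.y0 + self.eps * np.sin(self.omega * x)

    def _gp(self, x):
        return self.eps * self.omega * np.cos(self.omega * x)

    def coarse_reject(self, pts: np.ndarray, margin: float) -> bool:
        """True when every point is safely clear of the slab's bounding box."""
        x, yh = self._local(pts)
        near = (x > self.x0 - margin) & (x < self.x1 + margin) & \
               (yh > self.y0 - self.eps - margin)
        return not near.any()

    def bounds(self):
        lo_y = self.y0 - self.eps
        hi_y = self.y0 + self.eps + self.thickness
        if self.side == 1:
            return (np.array([self.x0, lo_y]), np.array([self.x1, hi_y]))
        return (np.array([self.x0, -hi_y]), np.array([self.x1, -lo_y]))

    def _local(self, pts):
        pts = np.atleast_2d(pts)
        return pts[:, 0], self.side * pts[:, 1]

    def signed_distance(self, pts):
        x, yh = self._local(pts)
        if not self.end_faces:
            # open-ended sheet: vertical distance to the nearer sinusoidal
            # face inside the x-extent, no contact beyond it
            g = self._g(x)
            v = np.minimum(yh - g, g + self.thickness - yh)
            return np.where((x >= self.x0) & (x <= self.x1), -v, np.inf)
        g = self._g(np.clip(x, self.x0, self.x1))
        in_x = (x >= self.x0) & (x <= self.x1)
        # inside depth (negative sd): min of vertical and end-face depths
        depth = np.minimum.reduce([yh - g, g + self.thickness - yh,
                                   x - self.x0, self.x1 - x])
        # outside, x within extent: vertical gap to nearer sinusoidal face
        sd_mid = np.where(yh < g, g - yh, yh - (g + self.thickness))
        # outside the x-extent: distance to end face / corner
        dx_out = np.maximum(self.x0 - x, x - self.x1)
        below = g - yh          # >0 when on the channel side of the face span
        above = yh - (g + self.thickness)
        dy_out = np.maximum.reduce([below, above, np.zeros_like(yh)])
        sd_end = np.hypot(dx_out, dy_out)
        return np.where(depth >= 0, -depth, np.where(in_x, sd_mid, sd_end))

    def normal(self, pts):
        """Outward unit normal at the nearest boundary feature."""
        x, yh = self._local(pts)
        xc = np.clip(x, self.x0, self.x1)
        g = self._g(xc)
        gp = self._gp(xc)
        norm_fac = np.sqrt(1.0 + gp**2)
        d_bot = np.abs(yh - g)
        d_top = np.abs(g + self.thickness - yh)
        # bottom (channel-facing) face outward normal: local (gp, -1)/|.|
        top_nearer = d_top < d_bot
        sgn = np.where(top_nearer, 1.0, -1.0)
        n = np.column_stack([-sgn * gp / norm_fac, sgn / norm_fac])

        if self.end_faces:
            d_l = np.abs(x - self.x0)
            d_r = np.abs(self.x1 - x)
            in_x = (x >= self.x0) & (x <= self.x1)
            depth = np.minimum.reduce([yh - g, g + self.thickness - yh,
                                       x - self.x0, self.x1 - x])
            inside = depth >= 0
            stack = np.column_stack([d_bot, d_top, d_l, d_r])
            feat = np.argmin(stack, axis=1)
            # outside the x-extent the end face wins regardless of depth
            feat = np.where(x < self.x0, 2, feat)
            feat = np.where(x > self.x1, 3, feat)
            mid_out = ~inside & in_x
            feat = np.where(mid_out & (yh < g), 0, feat)
            feat = np.where(mid_out & (yh >= g + self.thickness), 1, feat)
            n[feat == 2] = [-1.0, 0.0]
            n[feat == 3] = [1.0, 0.0]
            # corner blending for points beyond the extent and clear of the
            # face span: point from the corner to the node
            for mask, xe in ((x < self.x0, self.x0), (x > self.x1, self.x1)):
                if not mask.any():
                    continue
                ge = self._g(xe)
                lo = mask & (yh < ge)
                hi = mask & (yh > ge + self.thickness)
                for m, ye in ((lo, ge), (hi, ge + self.thickness)):
                    if m.any():
                        v = np.column_stack([x[m] - xe, yh[m] - ye])
                        L = np.linalg.norm(v, axis=1)
                        L = np.where(L == 0, 1.0, L)
                        n[m] = v / L[:, None]
        # convert local yhat-frame normal back to world y
        n[:, 1] *= self.side
        return n


@dataclass
class RoughSheetPair(Obstacle):
    """Both walls of a rough channel as one fused open-ended sheet pair.

    Geometrically identical to two mirror-image ``RoughSlabWall`` sheets
    with ``end_faces=False``; fusing them halves the contact-resolution
    work in the transit simulations, where the wall pair is tested against
    every node twice per step.
    """

    x0: float
    x1: float
    y0: float
    eps: float
    omega: float
    thickness: float = 1.0
    kind = "channel-wall"

    def __post_init__(self) -> None:
        if self.y0 <= self.eps or self.eps < 0 or self.omega < 0:
            raise GeometryError("need y0 > eps >= 0 and omega >= 0")
        if self.x1 <= self.x0:
            raise GeometryError("need x1 > x0")

    def _g(self, x):
        return self.y0 + self.eps * np.sin(self.omega * x)

    def signed_distance(self, pts):
        x = pts[:, 0]
        ya = np.abs(pts[:, 1])
        g = self._g(x)
        v = np.minimum(ya - g, g + self.thickness - ya)
        return np.where((x >= self.x0) & (x <= self.x1), -v, np.inf)

    def normal(self, pts):
        x = pts[:, 0]
        y = pts[:, 1]
        ya = np.abs(y)
        g = self._g(x)
        gp = self.eps * self.omega * np.cos(self.omega * x)
        fac = np.sqrt(1.0 + gp * gp)
        # nearer face: inner (channel-facing) or outer
        inner = (ya - g) <= (g + self.thickness - ya)
        sgn = np.where(inner, -1.0, 1.0)
        side = np.sign(y)
        side[side == 0] = 1.0
        return np.column_stack([-sgn * gp / fac, side * sgn / fac])

    def bounds(self):
        return (np.array([self.x0, -np.inf]),
                np.array([self.x1, np.inf]))

    def resolve_into(self, pts, dX, contact, tol, margin) -> None:
        """Kernel-backed projection + clamp (see World.resolve)."""
        from ._kernels import sheetpair_resolve

        sheetpair_resolve(pts, dX, contact, self.x0, self.x1, self.y0,
                          self.eps, self.omega, self.thickness, tol, margin)


@dataclass
class FunnelWall(Obstacle):
    """Converging wedge guide leading into a channel mouth.

    In the side-normalised frame the solid occupies ``yh >= g(x)`` for
    ``x in [x0, x1]``, with ``g`` linear from ``y_wide`` at ``x0`` down to
    ``y_mouth`` at ``x1``.  A pair of these flares a channel entry so that
    a cell wider than the channel engages the constriction by sliding
    along a converging surface instead of stalling against a flat end
    face (sliding on a converging wall has a forward tangential component,
    so the spring tension built up by the advancing cell body drives the
    outer nodes toward the mouth).
    """

    x0: float
    x1: float
    y_wide: float
    y_mouth: float
    side: int = 1
    kind = "funnel-wall"

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y_wide <= self.y_mouth or self.y_mouth <= 0:
            raise GeometryError("funnel needs x1 > x0 and y_wide > y_mouth > 0")
        if self.side not in (-1, 1):
            raise GeometryError("side must be +1 (upper) or -1 (lower)")
        self._slope = (self.y_mouth - self.y_wide) / (self.x1 - self.x0)

    def _local(self, pts):
        pts = np.atleast_2d(pts)
        return pts[:, 0], self.side * pts[:, 1]

    def _g(self, x):
        return self.y_wide + self._slope * (np.clip(x, self.x0, self.x1) - self.x0)

    def coarse_reject(self, pts, margin):
        x, yh = self._local(pts)
        near = (x > self.x0 - margin) & (x < self.x1 + margin) & \
            (yh > self.y_mouth - margin)
        return not near.any()

    def bounds(self):
        big = 1e9
        if self.side == 1:
            return (np.array([self.x0, self.y_mouth]), np.array([self.x1, big]))
        return (np.array([self.x0, -big]), np.array([self.x1, -self.y_mouth]))

    def signed_distance(self, pts):
        x, yh = self._local(pts)
        g = self._g(x)
        in_x = (x >= self.x0) & (x <= self.x1)
        depth = np.minimum.reduce([yh - g, x - self.x0, self.x1 - x])
        sd_mid = g - yh
        dx_out = np.maximum(self.x0 - x, x - self.x1)
        dy_out = np.maximum(g - yh, 0.0)
        sd_end = np.hypot(dx_out, dy_out)
        return np.where(depth >= 0, -depth, np.where(in_x, sd_mid, sd_end))

    def normal(self, pts):
        x, yh = self._local(pts)
        g = self._g(x)
        norm_fac = math.sqrt(1.0 + self._slope**2)
        n = np.tile([self._slope / norm_fac, -1.0 / norm_fac], (len(x), 1))
        depth = np.minimum.reduce([yh - g, x - self.x0, self.x1 - x])
        # end faces only matter when they are the nearest interior feature
        left = (depth >= 0) & (x - self.x0 < np.minimum(yh - g, self.x1 - x))
        right = (depth >= 0) & (self.x1 - x < np.minimum(yh - g, x - self.x0))
        n[left] = [-1.0, 0.0]
        n[right] = [1.0, 0.0]
        for mask, xe in ((x < self.x0, self.x0), (x > self.x1, self.x1)):
            m = mask & (yh < self._g(np.full_like(yh, xe)))
            if m.any():
                ge = float(self._g(np.array([xe]))[0])
                v = np.column_stack([x[m] - xe, yh[m] - ge])
                L = np.linalg.norm(v, axis=1)
                L[L == 0] = 1.0
                n[m] = v / L[:, None]
            m2 = mask & ~ (yh < self._g(np.full_like(yh, xe)))
            if m2.any():
                n[m2] = [-1.0 if xe == self.x0 else 1.0, 0.0]
        n[:, 1] *= self.side
        return n


class World:
    """A collection of rigid obstacles with shared contact resolution."""

    def __init__(self, obstacles=(), tol: float = 1e-2):
        self.obstacles = list(obstacles)
        self.tol = float(tol)

    def signed_distance(self, pts) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if not self.obstacles:
            return np.full(len(pts), np.inf)
        return np.minimum.reduce([ob.signed_distance(pts) for ob in self.obstacles])

    def max_penetration(self, pts) -> float:
        """Largest interior depth of any point in any obstacle (0 if none)."""
        sd = self.signed_distance(pts)
        return float(max(0.0, -sd.min(initial=np.inf))) if len(sd) else 0.0

    def resolve(self, pts: np.ndarray, dX: np.ndarray, tol: float | None = None):
        """Project and clamp a proposed displacement field.

        For every node within ``tol`` of an obstacle boundary and moving
        inward, the normal component of its displacement is removed; any
        node still interior after the move is clamped to the nearest
        boundary point.  Returns ``(dX_resolved, contact_mask)``.
        """
        tol = self.tol if tol is None else tol
        dX = dX.copy()
        contact = np.zeros(len(pts), dtype=bool)
        step_max = float(np.abs(dX).max(initial=0.0))
        margin = tol + 1.5 * step_max  # inf-norm bound on the step length
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        for ob in self.obstacles:
            bb = ob.bounds()
            if bb is not None and (np.any(hi + margin < bb[0])
                                   or np.any(lo - margin > bb[1])):
                continue
            if hasattr(ob, "resolve_into"):
                ob.resolve_into(pts, dX, contact, tol, margin)
                continue
            sd_old = ob.signed_distance(pts)
            if sd_old.min() > margin:
                continue
            near = sd_old <= tol
            if near.any():
                n_old = ob.normal(pts[near])
                comp = np.einsum("ij,ij->i", dX[near], n_old)
                inward = comp < 0.0
                if inward.any():
                    sub = np.flatnonzero(near)[inward]
                    dX[sub] -= comp[inward, None] * n_old[inward]
                    contact[sub] = True
            # only nodes that started within reach of the boundary can
            # cross it during this step
            cand = np.flatnonzero(sd_old <= margin)
            new = pts[cand] + dX[cand]
            sd_new = ob.signed_distance(new)
            pen = sd_new < 0.0
            if pen.any():
                sub = cand[pen]
                n_new = ob.normal(new[pen])
                dX[sub] -= sd_new[pen][:, None] * n_new
                contact[sub] = True
        return dX, contact


# -- elementary operations -------------------------------------------------


def project_displacement(dx: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Remove the component of ``dx`` along the unit normal ``n``."""
    dx = np.asarray(dx, dtype=float)
    n = np.asarray(n, dtype=float)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("non-unit normal passed to project_displacement; normalising",
                      stacklevel=2)
        n = n / norm
    return dx - np.dot(dx, n) * n


def detect_contact(x, proposed_dx, world: World, tol: float = 1e-2):
    """Single-point contact query.

    Returns the outward normal of the contacted obstacle boundary, or
    ``None``.  Contact means: within ``tol`` of a boundary while moving
    inward, or the step ``x -> x+dx`` crosses into the obstacle.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.asarray(x, dtype=float)[None, :]
    dx = np.asarray(proposed_dx, dtype=float)[None, :]
    for ob in world.obstacles:
        sd = float(ob.signed_distance(x)[0])
        n = ob.normal(x)[0]
        if sd <= tol and float(dx[0] @ n) < 0.0:
            return n
        if float(ob.signed_distance(x + dx)[0]) < 0.0:
            return n
    return None


# -- rough channel ---------------------------------------------------------


@dataclass
class RoughChannel:
    """Trigonometric rough channel: walls at y = ±(y0 + eps sin(omega x))."""

    y0: float = 5.0
    epsilon: float = 1.0
    omega: float = 0.5
    x_entry: float = 0.0
    length: float = 60.0

    def __post_init__(self) -> None:
        if not (self.y0 > self.epsilon >= 0):
            raise GeometryError("need y0 > epsilon >= 0 (walls must not cross the axis)")
        if self.omega < 0:
            raise GeometryError("omega must be >= 0")

    def to_obstacles(self, thickness: float = 10.0,
                     end_faces: bool = True) -> list[RoughSlabWall]:
        common = dict(x0=self.x_entry, x1=self.x_entry + self.length,
                      y0=self.y0, eps=self.epsilon, omega=self.omega,
                      thickness=thickness, end_faces=end_faces)
        return [RoughSlabWall(side=1, **common), RoughSlabWall(side=-1, **common)]


def channel_wall(spec: RoughChannel, x, side: str):
    """Wall ordinate: +(y0 + eps sin(omega x)) for 'upper', mirrored for 'lower'."""
    y = spec.y0 + spec.epsilon * np.sin(spec.omega * np.asarray(x, dtype=float))
    return y if side == "upper" else -y


def wall_normal(spec: RoughChannel, x, side: str) -> np.ndarray:
    """Inward-facing (channel-side) unit normal of a wall at abscissa x."""
    gp = spec.epsilon * spec.omega * math.cos(spec.omega * float(x))
    v = np.array([gp, -1.0]) if side == "upper" else np.array([-gp, 1.0])
    return v / np.linalg.norm(v)


# -- cell-cell contact -----------------------------------------------------


def _segment_normals(poly: np.ndarray) -> np.ndarray:
    """Outward unit normals of a simple polygon's edges (any orientation)."""
    e = np.roll(poly, -1, axis=0) - poly
    n = np.column_stack([e[:, 1], -e[:, 0]])
    # signed area > 0 (CCW) makes (dy, -dx) outward; flip otherwise
    area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1])
    if area2 < 0:
        n = -n
    L = np.linalg.norm(n, axis=1)
    L[L == 0] = 1.0
    return n / L[:, None]


def _nearest_edge(points: np.ndarray, poly: np.ndarray):
    """Distance to and index of the nearest polygon edge for each point."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a                                   # (m, 2)
    ee = np.einsum("ij,ij->i", e, e)
    ee[ee == 0] = 1.0
    w = points[:, None, :] - a[None, :, :]      # (n, m, 2)
    tpar = np.clip(np.einsum("nmj,mj->nm", w, e) / ee, 0.0, 1.0)
    proj = a[None] + tpar[..., None] * e[None]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    idx = np.argmin(d, axis=1)
    return d[np.arange(len(points)), idx], idx


def cell_cell_contact(cells, tol: float = 1e-2):
    """Per-node contact normals between cell membrane polygons (2D).

    For each ordered pair (A, B) of distinct cells, every membrane node of
    A that lies inside or within ``tol`` of B's membrane polygon is
    assigned the outward normal of B's nearest boundary segment; the usual
    tangential-projection rule can then be applied to that node's
    displacement.  Returns a list (one entry per cell) of
    ``(mask, normals)`` pairs.
    """
    from matplotlib.path import Path as _Path

    if len(cells) < 2:
        return [(np.zeros(len(c.x), dtype=bool), np.zeros_like(c.x)) for c in cells]
    out = []
    for ia, A in enumerate(cells):
        mask = np.zeros(len(A.x), dtype=bool)
        normals = np.zeros_like(A.x)
        for ib, B in enumerate(cells):
            if ib == ia:
                continue
            poly = B.x
            d, idx = _nearest_edge(A.x, poly)
            inside = _Path(poly).contains_points(A.x, radius=1e-9)
            near = inside | (d <= tol)
            if near.any():
                en = _segment_normals(poly)
                mask |= near
                normals[near] = en[idx[near]]
        out.append((mask, normals))
    return out
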