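"""Numba kernels for the per-step hot path of the channel simulations.

Each kernel mirrors a (tested) vectorised implementation elsewhere in the
package; equivalence is pinned by tests.  If numba is unavailable the
plain-Python definitions below still work, just slowly.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def polygon_centroid_xy(v):
    """Area-weighted centroid of an ordered vertex ring (2D)."""
    n = v.shape[0]
    a = 0.0
    cx = 0.0
    cy = 0.0
    for i in range(n):
        j = i + 1
        if j == n:
            j = 0
        cr = v[i, 0] * v[j, 1] - v[j, 0] * v[i, 1]
        a += cr
        cx += (v[i, 0] + v[j, 0]) * cr
        cy += (v[i, 1] + v[j, 1]) * cr
    if abs(a) < 1e-12:
        sx = 0.0
        sy = 0.0
        for i in range(n):
            sx += v[i, 0]
            sy += v[i, 1]
        return sx / n, sy / n
    return cx / (3.0 * a), cy / (3.0 * a)


@njit(cache=True)
def rotation_angle_2d(x, ref, cx, cy):
    """Closed-form best-fit rotation of ``ref`` onto ``x`` about (cx, cy)."""
    s = 0.0
    c = 0.0
    for i in range(x.shape[0]):
        dx = x[i, 0] - cx
        dy = x[i, 1] - cy
        s += ref[i, 0] * dy - ref[i, 1] * dx
        c += ref[i, 0] * dx + ref[i, 1] * dy
    return s, c


@njit(cache=True)
def imex_coeffs_2d(pts, src_xy, rates, D, s_out, S_out):
    """Accumulate the linear-implicit gradient split for 2D point sources."""
    n = pts.shape[0]
    m = src_xy.shape[0]
    for i in range(n):
        s_out[i] = 0.0
        S_out[i, 0] = 0.0
        S_out[i, 1] = 0.0
    ok = True
    for j in range(m):
        sx = src_xy[j, 0]
        sy = src_xy[j, 1]
        coef = rates[j] / (math.pi * D)
        for i in range(n):
            dx = pts[i, 0] - sx
            dy = pts[i, 1] - sy
            r2 = dx * dx + dy * dy
            if r2 == 0.0:
                ok = False
            else:
                k = coef / r2
                s_out[i] += k
                S_out[i, 0] += k * sx
                S_out[i, 1] += k * sy
    return ok


@njit(cache=True)
def sheetpair_resolve(pts, dX, contact, x0, x1, y0, eps, om, T, tol, margin):
    """Contact projection + crossing clamp against a fused wall pair.

    Mirrors ``World.resolve`` specialised to a single ``RoughSheetPair``:
    (1) nodes within ``tol`` of a face moving inward lose their normal
    displacement component; (2) nodes whose step ends inside the sheet are
    pushed back to the nearest face along its normal.  Mutates ``dX`` and
    ``contact`` in place.
    """
    for i in range(pts.shape[0]):
        x = pts[i, 0]
        y = pts[i, 1]
        ya = abs(y)
        side = 1.0 if y >= 0.0 else -1.0
        g = 0.0
        if x0 <= x <= x1:
            g = y0 + eps * math.sin(om * x)
            a = ya - g
            b = g + T - ya
            sd = -(a if a < b else b)
        else:
            sd = np.inf
        if sd > margin:
            continue
        # outward unit normal at the nearer face
        gp = eps * om * math.cos(om * x)
        fac = math.sqrt(1.0 + gp * gp)
        inner = (ya - g) <= (g + T - ya)
        sgn = -1.0 if inner else 1.0
        nx = -sgn * gp / fac
        ny = side * sgn / fac
        if sd <= tol:
            comp = dX[i, 0] * nx + dX[i, 1] * ny
            if comp < 0.0:
                dX[i, 0] -= comp * nx
                dX[i, 1] -= comp * ny
                contact[i] = True
        # crossing clamp at the proposed new position
        xn = x + dX[i, 0]
        yn = y + dX[i, 1]
        yan = abs(yn)
        if x0 <= xn <= x1:
            gn = y0 + eps * math.sin(om * xn)
            an = yan - gn
            bn = gn + T - yan
            sdn = -(an if an < bn else bn)
            if sdn < 0.0:
                gpn = eps * om * math.cos(om * xn)
                facn = math.sqrt(1.0 + gpn * gpn)
                inn = an <= bn
                sgnn = -1.0 if inn else 1.0
                siden = 1.0 if yn >= 0.0 else -1.0
                nxn = -sgnn * gpn / facn
                nyn = siden * sgnn / facn
                dX[i, 0] -= sdn * nxn
                dX[i, 1] -= sdn * nyn
                contact[i] = True
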