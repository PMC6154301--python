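"""Preset scenarios: obstacle crawling, cavity squeeze, rough-channel transit.

Every preset is generated programmatically from a handful of geometric
constants.  The ``channel`` preset is the workhorse of the transit-time
studies: a 60 μm long trigonometric channel of ~10 μm width whose walls
are two rigid slabs, a cell of radius 12.5 μm starting just left of the
entry, and a chemokine source past the exit that pulls the cell through.

The source placement and its secretion rate are the two quantities the
transit studies are sensitive to that are pure scenario choices.  They are
fixed once and not varied anywhere: the source sits 42 μm past the channel
exit -- far enough that the cell clears the channel completely before
engulfing the source (once engulfed the drift vanishes and the cell only
relaxes in place) -- and the secretion rate 7.0e6 mol/(h·μm³) makes the
transit proceed at the ~200 μm/h amoeboid speed scale.  Note the whole
cell (membrane plus the drift-free nucleus it drags) translates at about
half the bare membrane drift speed, which is why the rate is several times
the free-migration default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_model import CellParams, CellState, defaults_3d, init_cell_2d, init_cell_3d
from .signals import ChemokineSource, SignalField
from .world import DiscObstacle, RoughChannel, World

__all__ = ["Scenario", "build_scenario", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("obstacle2d", "obstacle3d", "cavity", "channel", "vessel")

#: channel-scenario source: offset past the exit (μm) and secretion rate
CHANNEL_SOURCE_OFFSET = 46.0
CHANNEL_GAMMA_S = 7.65e6
#: free-migration secretion rate of the obstacle presets (mol/(h·μm³))
OBSTACLE_GAMMA_S = 2.0e5
#: endothelial wall sheet thickness (μm); real capillary endothelium is
#: of order 1 μm away from its nuclei.  A cell wider than the channel
#: spreads its flanks over the outside of the thin sheet while its core
#: transits the lumen -- with thick walls the flat entry face would let
#: the shape-memory springs (force scale alpha*R) statically resist the
#: much weaker chemotactic pull and the squeeze would stall.
WALL_THICKNESS = 1.0


@dataclass
class Scenario:
    """A fully parameterised simulation setup."""

    name: str
    cells: list[CellState]
    field: SignalField
    world: World
    channel: RoughChannel | None = None
    t_end: float = 1.0
    apertures: tuple = ()


def _channel(params: CellParams | None, D: float, epsilon: float, omega: float,
             gamma_s: float | None, source_offset: float | None,
             y0: float = 5.0, length: float = 60.0) -> Scenario:
    params = params or CellParams()
    chan = RoughChannel(y0=y0, epsilon=epsilon, omega=omega, x_entry=0.0,
                        length=length)
    from .world import RoughSheetPair

    world = World([RoughSheetPair(x0=0.0, x1=length, y0=y0, eps=epsilon,
                                  omega=omega, thickness=WALL_THICKNESS)])
    cell = init_cell_2d(params, center=(-params.R - 2.5, 0.0))
    off = CHANNEL_SOURCE_OFFSET if source_offset is None else source_offset
    gs = CHANNEL_GAMMA_S if gamma_s is None else gamma_s
    field = SignalField([ChemokineSource(np.array([length + off, 0.0]), gs)], D=D, dim=2)
    return Scenario("channel", [cell], field, world, channel=chan, t_end=4.0)


def _cavity(params: CellParams | None, D: float) -> Scenario:
    """Two rigid posts leaving a sub-nucleus pore (8 μm < nucleus diameter).

    The posts are small enough (top at ±12 μm) that the membrane can wrap
    around them while the nucleus is forced through the pore; a converging
    pocket much taller than the cell's half-width would be statically
    impassable under the projection rule.
    """
    params = params or CellParams()
    gap = 8.0
    radius = 4.0
    world = World([
        DiscObstacle(np.array([0.0, +(radius + gap / 2)]), radius),
        DiscObstacle(np.array([0.0, -(radius + gap / 2)]), radius),
    ])
    cell = init_cell_2d(params, center=(-22.0, 0.0))
    field = SignalField([ChemokineSource(np.array([26.0, 0.0]), 3.0e6)], D=D, dim=2)
    return Scenario("cavity", [cell], field, world, t_end=2.0)


def _obstacle2d(params: CellParams | None, D: float) -> Scenario:
    params = params or CellParams()
    world = World([DiscObstacle(np.array([0.0, 0.0]), 12.0)])
    cell = init_cell_2d(params, center=(-30.0, -4.0))
    field = SignalField([ChemokineSource(np.array([22.0, 4.0]), OBSTACLE_GAMMA_S)],
                        D=D, dim=2)
    return Scenario("obstacle2d", [cell], field, world, t_end=3.0)


def _obstacle3d(params: CellParams | None, D: float) -> Scenario:
    """Spherical cell crawling over a rigid sphere toward a 3D source.

    Uses the standard 3D fundamental solution (1/(4 pi D r)): the
    inverse-square flavour's gradient falls off as 1/r^4 and cannot move a
    cell at the tens-of-μm source distances of this scenario for any
    plausible secretion rate.  The rate is chosen so the approach happens
    at the ~100 μm/h scale.
    """
    params = params or defaults_3d()
    world = World([DiscObstacle(np.array([0.0, 0.0, 0.0]), 12.0)])
    cell = init_cell_3d(params, center=(-26.0, 0.0, 0.0))
    field = SignalField([ChemokineSource(np.array([20.0, 0.0, 0.0]), 1.0e9)],
                        D=D, dim=3, form="physical")
    return Scenario("obstacle3d", [cell], field, world, t_end=1.0)


def _vessel(params: CellParams | None, D: float, epsilon: float = 0.5,
            omega: float = 0.5) -> Scenario:
    """Vessel wall with two apertures: intravasation then extravasation.

    Two parallel rough walls bound a lumen of half-width 5 μm.  The upper
    wall has an aperture near the left end, the lower wall one near the
    right end; the cell starts above the upper wall and the source sits
    below the lower aperture, so the path crosses both wall openings.
    """
    params = params or CellParams()
    y0, T = 5.0, 1.5
    x0, x1 = 0.0, 60.0
    from .world import RoughSlabWall

    def seg(side, a, b):
        return RoughSlabWall(x0=a, x1=b, y0=y0, eps=epsilon, omega=omega,
                             side=side, thickness=T, end_faces=False)

    # staggered walls: the upper sheet is open left of x=28 (the entry
    # aperture), the lower sheet open right of x=32 (the exit aperture);
    # both overlap in a 10-μm-wide lumen neck in between
    world = World([seg(+1, 28.0, x1), seg(-1, x0, 32.0)])
    cell = init_cell_2d(params, center=(6.0, 10.0))
    field = SignalField([ChemokineSource(np.array([48.0, -30.0]), 4.0e6)], D=D, dim=2)
    chan = RoughChannel(y0=y0, epsilon=epsilon, omega=omega, x_entry=x0,
                        length=x1 - x0)
    return Scenario("vessel", [cell], field, world, channel=chan, t_end=2.0,
                    apertures=(("upper", x0, 28.0), ("lower", 32.0, x1)))


def build_scenario(name: str, *, params: CellParams | None = None,
                   D: float = 3600.0, epsilon: float = 1.0, omega: float = 0.5,
                   gamma_s: float | None = None,
                   source_offset: float | None = None) -> Scenario:
    """Fresh preset scenario; every call returns independent objects.

    ``epsilon``/``omega`` set the channel roughness (channel and vessel
    presets), ``D`` the chemokine diffusivity, ``gamma_s``/``source_offset``
    override the channel source (defaults above).
    """
    if name == "channel":
        return _channel(params, D, epsilon, omega, gamma_s, source_offset)
    if name == "cavity":
        return _cavity(params, D)
    if name == "obstacle2d":
        return _obstacle2d(params, D)
    if name == "obstacle3d":
        return _obstacle3d(params, D)
    if name == "vessel":
        return _vessel(params, D, epsilon=min(epsilon, 0.5), omega=omega)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
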