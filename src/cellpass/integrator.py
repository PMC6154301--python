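"""IMEX Euler time stepping of the coupled membrane/nucleus system.

Each step advances, in this order: (1) fit the polarity rotation phi;
(2) membrane nodes by a linear-implicit update -- relaxation and the
denominator of the chemotactic drift implicit, the drift's distance
denominator explicit at the old positions -- followed by contact
projection; (3) nucleus nodes, using the *already advanced* membrane
(the ordering is fixed by the nucleus equation referencing the new
membrane positions), followed by contact projection; (4) recompute the
nucleus centre as the area/volume centroid of the nucleus shape;
(5) check for source consumption.

With the stiff relaxation terms implicit the update divides by
(1 + dt*alpha) resp. (1 + dt*alpha_n) > 1, so the relaxation cannot
oscillate or blow up for any time step; the chemotactic split adds
dt*beta*g to the membrane denominator which only strengthens this.
Noise (a Wiener increment per node) is added before the projection, so
contacts constrain random motion as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import signals as _signals
from .cell_model import CellState, fit_rotation, offset_rotation
from .exceptions import IntegrationUnstableError
from .world import World, cell_cell_contact

__all__ = ["StepConfig", "Trajectory", "wiener_increment", "step_membrane",
           "step_nucleus", "advance", "run_scenario"]

#: relaxation tail simulated after the last source is consumed, h
#: (0.05 h is 12.5 e-foldings of the default membrane relaxation alpha=250/h)
RELAXATION_TAIL = 0.05


@dataclass
class StepConfig:
    """Time stepping controls.

    dt    : step, h (model default 1e-4 in 2D; 3D runs use 1e-2)
    eta   : noise amplitude μm/sqrt(h); None defers to the cell's value
    seed  : RNG seed (int or numpy SeedSequence); eta=0 runs are exactly
            deterministic regardless
    t_end : hard time limit, h
    record_every : store a trajectory frame every k-th step (None: events only)
    stop  : "auto"  -- stop at t_end, or a relaxation tail after the last
                       source is consumed, whichever is first;
            "transit" -- additionally stop as soon as a channel transit
                       completes (used by the Monte Carlo driver)
    """

    dt: float = 1e-4
    eta: float | None = None
    seed: int | np.random.SeedSequence | None = None
    t_end: float = 1.0
    record_every: int | None = 1
    stop: str = "auto"
    contact_tol: float = 1e-2

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.stop not in ("auto", "transit"):
            raise ValueError("stop must be 'auto' or 'transit'")

    def with_overrides(self, **kw) -> "StepConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Recorded run: frame arrays, centroid trace and an event log."""

    times: np.ndarray
    membrane: np.ndarray          # (frames, N, dim)
    nucleus: np.ndarray
    centroids: np.ndarray         # membrane polygon/mesh centroid per frame
    contact: np.ndarray           # any node in contact during the frame's step
    events: dict
    channel: object | None = None
    faces: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self):
        """Tidy per-node table: t, entity, node_id, x, y[, z]."""
        import pandas as pd

        frames, n, dim = self.membrane.shape
        cols = ["x", "y", "z"][:dim]
        recs = []
        for entity, arr in (("membrane", self.membrane), ("nucleus", self.nucleus)):
            df = pd.DataFrame(arr.reshape(frames * n, dim), columns=cols)
            df.insert(0, "node_id", np.tile(np.arange(n), frames))
            df.insert(0, "entity", entity)
            df.insert(0, "t", np.repeat(self.times, n))
            recs.append(df)
        return pd.concat(recs, ignore_index=True)


def wiener_increment(dim: int, dt: float, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """n i.i.d. Wiener increments: Normal(0, dt) per component, shape (n, dim)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return rng.standard_normal((n, dim)) * math.sqrt(dt)


def _eta(state: CellState, cfg: StepConfig) -> float:
    return state.params.eta if cfg.eta is None else cfg.eta


def step_membrane(state: CellState, fld, world: World, cfg: StepConfig,
                  rng: np.random.Generator, t: float = 0.0,
                  B: np.ndarray | None = None):
    """Advance the membrane nodes one IMEX step; returns (x_new, contact_mask).

    Solves, per node,
        (1 + dt*alpha + dt*beta*g) x_new = x_old + dt*(beta*G
            + alpha*(x_nucleus_old + B xhat)) + eta dW,
    where g, G are the explicit (old-position) coefficients of the
    linear-implicit chemotactic gradient, then resolves contacts on the
    realised displacement.
    """
    p = state.params
    if B is None:
        B = offset_rotation(state)
    target = state.x_n + state.xhat @ B.T
    g, G = fld.imex_coefficients(state.x, t) if fld is not None else (0.0, 0.0)
    eta = _eta(state, cfg)
    noise = eta * wiener_increment(state.dim, cfg.dt, rng, len(state.x)) if eta > 0 \
        else 0.0
    rhs = state.x + cfg.dt * (p.beta * G + p.alpha * target) + noise
    denom = 1.0 + cfg.dt * p.alpha + cfg.dt * p.beta * np.atleast_1d(g)[:, None] \
        if fld is not None else 1.0 + cfg.dt * p.alpha
    x_new = rhs / denom
    dx, contact = world.resolve(state.x, x_new - state.x, cfg.contact_tol)
    return state.x + dx, contact


def step_nucleus(state: CellState, x_membrane_new: np.ndarray, world: World,
                 cfg: StepConfig, rng: np.random.Generator,
                 B: np.ndarray | None = None):
    """Advance the nucleus nodes one IMEX step (membrane already at t+dt)."""
    p = state.params
    if B is None:
        B = offset_rotation(state)
    eta = _eta(state, cfg)
    noise = eta * wiener_increment(state.dim, cfg.dt, rng, len(state.x_n)) if eta > 0 \
        else 0.0
    pull = -p.alpha * (state.x_n + state.xhat @ B.T - x_membrane_new)
    anchor = p.alpha_n * (state.x_c + state.xhat_n @ B.T)
    rhs = state.x_n + cfg.dt * (pull + anchor) + noise
    xn_new = rhs / (1.0 + cfg.dt * p.alpha_n)
    dxn, contact = world.resolve(state.x_n, xn_new - state.x_n, cfg.contact_tol)
    return state.x_n + dxn, contact


def advance(state: CellState, fld, world: World, cfg: StepConfig,
            rng: np.random.Generator, t: float = 0.0,
            extra_normals=None) -> dict:
    """One full time step (rotation, membrane, nucleus, centre, consumption).

    ``extra_normals`` optionally carries ``(mask, normals)`` from cell-cell
    contact detection; masked membrane nodes get the same tangential
    projection against those normals.  Mutates ``state``; returns a dict
    with contact flags and consumption events.
    """
    state.phi = fit_rotation(state)
    B = offset_rotation(state)

    x_new, c1 = step_membrane(state, fld, world, cfg, rng, t, B)
    if extra_normals is not None:
        mask, normals = extra_normals
        if mask.any():
            dx = x_new[mask] - state.x[mask]
            comp = np.einsum("ij,ij->i", dx, normals[mask])
            inward = comp < 0
            dx[inward] -= comp[inward, None] * normals[mask][inward]
            x_new[mask] = state.x[mask] + dx
            c1 = c1 | mask

    step_max = np.linalg.norm(x_new - state.x, axis=1).max()
    if step_max > state.params.R:
        raise IntegrationUnstableError(
            f"membrane node moved {step_max:.3g} μm (> R = {state.params.R}) in one "
            f"step at t={t:.6g}; reduce dt"
        )

    xn_new, c2 = step_nucleus(state, x_new, world, cfg, rng, B)
    state.x = x_new
    state.x_n = xn_new
    state.x_c = state.nucleus_center()

    consumed = []
    if fld is not None:
        active_before = [s.is_active(t) for s in fld.sources]
        if any(active_before):
            # cheap bounding-box precheck before the exact containment test
            lo, hi = state.x.min(axis=0), state.x.max(axis=0)
            for src, was in zip(fld.sources, active_before):
                if was and np.all(src.position >= lo) and np.all(src.position <= hi):
                    _signals.consume_sources(fld, state.x, faces=state.faces, t=t)
                    break
            consumed = [i for i, (s, was) in enumerate(zip(fld.sources, active_before))
                        if was and not s.active]
    return {"contact": bool(c1.any() or c2.any()), "consumed": consumed}


def run_scenario(scenario, cfg: StepConfig) -> Trajectory:
    """Integrate a scenario and return its (possibly subsampled) trajectory.

    The event log always contains full-resolution times for channel entry
    (first membrane node past x_entry), channel exit (all nodes past the
    channel end) and source consumption, independent of ``record_every``.
    """
    cells = [c.copy() for c in scenario.cells]
    fld = scenario.field
    world = scenario.world
    channel = scenario.channel
    rng = np.random.default_rng(cfg.seed)

    times, mem, nuc, cents, contacts = [], [], [], [], []
    events: dict = {}
    state = cells[0]

    # multi-cell runs record the first cell's trajectory; the collision
    # rule still constrains every cell each step
    def record(t, contact):
        times.append(t)
        mem.append(state.x.copy())
        nuc.append(state.x_n.copy())
        cents.append(state.membrane_centroid())
        contacts.append(contact)

    if cfg.record_every:
        record(0.0, False)

    x_exit = channel.x_entry + channel.length if channel is not None else None
    t = 0.0
    step = 0
    t_stop = cfg.t_end
    nsteps_max = int(round(cfg.t_end / cfg.dt))
    while step < nsteps_max and t < t_stop - 1e-12:
        contact_any = False
        pairs = cell_cell_contact(cells, cfg.contact_tol) if len(cells) > 1 else None
        for k, cell in enumerate(cells):
            info = advance(cell, fld, world, cfg, rng, t,
                           extra_normals=None if pairs is None else pairs[k])
            contact_any = contact_any or info["contact"]
            if info["consumed"]:
                events.setdefault("source_consumed", t + cfg.dt)
        t += cfg.dt
        step += 1

        if channel is not None:
            xs = state.x[:, 0]
            if "channel_entry" not in events and xs.max() > channel.x_entry:
                events["channel_entry"] = t
            if "channel_entry" in events and "channel_exit" not in events \
                    and xs.min() > x_exit:
                events["channel_exit"] = t
                if cfg.stop == "transit":
                    t_stop = t

        if "source_consumed" in events and fld is not None \
                and not any(s.is_active(t) for s in fld.sources):
            t_stop = min(t_stop, events["source_consumed"] + RELAXATION_TAIL)

        if cfg.record_every and (step % cfg.record_every == 0 or t >= t_stop - 1e-12):
            record(t, contact_any)

    if not times:  # record_every=None: keep first/last frame for metrics
        record(t, False)

    return Trajectory(
        times=np.asarray(times),
        membrane=np.asarray(mem),
        nucleus=np.asarray(nuc),
        centroids=np.asarray(cents),
        contact=np.asarray(contacts),
        events=events,
        channel=channel,
        faces=state.faces,
    )
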