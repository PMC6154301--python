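"""Configuration files, fixture generation, output writing and rendering.

Configs are YAML with four optional blocks -- ``cell``, ``step``,
``channel``/``scenario``, ``sources`` -- plus an optional ``mc`` block for
Monte Carlo studies.  Unspecified values fall back to the model defaults;
unknown keys are rejected.  Every run can be reproduced from its echoed
effective config plus the master seed.

Output conventions: coordinates in absolute μm in the scenario frame,
time in hours; trajectory CSV is comma-separated, '.' decimal, header
row, UTF-8; metrics go to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cell_model import CellParams
from .integrator import StepConfig, Trajectory
from .measurements import (
    in_channel_mean_speed,
    penetration_time,
    polygon_area,
    speed_series,
)
from .scenarios import SCENARIO_NAMES, Scenario, build_scenario
from .signals import ChemokineSource, SignalField
from .world import RoughChannel, World

__all__ = ["RunConfig", "load_config", "save_config", "generate_fixture",
           "write_outputs", "trajectory_from_csv", "render"]

_CELL_KEYS = {f.name for f in dataclasses.fields(CellParams)}
_STEP_KEYS = {f.name for f in dataclasses.fields(StepConfig)}
_CHANNEL_KEYS = {f.name for f in dataclasses.fields(RoughChannel)}
_SOURCE_KEYS = {"x", "y", "z", "gamma_s", "t_on", "t_off"}
_MC_KEYS = {"distributions", "n_samples", "seed", "scenario", "workers"}
_TOP_KEYS = {"scenario", "cell", "step", "channel", "sources", "D",
             "greens_3d", "mc", "out"}


@dataclass
class RunConfig:
    """Validated, fully defaulted run description."""

    scenario: str | None = None
    cell: CellParams | None = None
    step: StepConfig | None = None
    channel: RoughChannel | None = None
    sources: list[dict] | None = None
    D: float = 3600.0
    greens_3d: str = "paper"
    mc: dict | None = None
    out: str | None = None

    def effective(self) -> dict:
        """The complete effective configuration (defaults applied)."""
        return {
            "scenario": self.scenario,
            "cell": dataclasses.asdict(self.cell or CellParams()),
            "step": {k: v for k, v in dataclasses.asdict(self.step or StepConfig()).items()
                     if not isinstance(v, np.random.SeedSequence)},
            "channel": dataclasses.asdict(self.channel) if self.channel else None,
            "sources": self.sources,
            "D": self.D,
            "greens_3d": self.greens_3d,
            "mc": self.mc,
            "out": self.out,
        }

    def build(self) -> tuple[Scenario, StepConfig]:
        """Materialise the scenario and step config this run describes."""
        step = self.step or StepConfig()
        if self.scenario:
            chan = self.channel
            kw = {}
            if chan is not None:
                kw = dict(epsilon=chan.epsilon, omega=chan.omega)
            sc = build_scenario(self.scenario, params=self.cell, D=self.D, **kw)
        else:
            if self.channel is None and not self.sources:
                raise ValueError("config needs a scenario, a channel or sources")
            cell_params = self.cell or CellParams()
            from .cell_model import init_cell_2d

            world = World(self.channel.to_obstacles() if self.channel else [])
            srcs = [_source_from_dict(s) for s in (self.sources or [])]
            field = SignalField(srcs, D=self.D, dim=2, form=self.greens_3d)
            cell = init_cell_2d(cell_params,
                                center=(-cell_params.R - 2.5, 0.0))
            sc = Scenario("custom", [cell], field, world, channel=self.channel,
                          t_end=step.t_end)
        return sc, step


def _source_from_dict(d: dict) -> ChemokineSource:
    unknown = set(d) - _SOURCE_KEYS
    if unknown:
        raise ValueError(f"unknown source keys: {sorted(unknown)}")
    pos = [d["x"], d["y"]] + ([d["z"]] if "z" in d else [])
    return ChemokineSource(np.array(pos, dtype=float), float(d["gamma_s"]),
                           t_on=d.get("t_on"), t_off=d.get("t_off"))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; defaults applied."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for block, allowed in (("cell", _CELL_KEYS), ("step", _STEP_KEYS),
                           ("channel", _CHANNEL_KEYS), ("mc", _MC_KEYS)):
        extra = set(raw.get(block) or {}) - allowed
        if extra:
            raise ValueError(f"unknown {block} keys: {sorted(extra)}")
    scenario = raw.get("scenario")
    if scenario is not None and scenario not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {scenario!r}")
    cell = CellParams(**raw["cell"]) if raw.get("cell") else None
    step = StepConfig(**raw["step"]) if raw.get("step") else None
    channel = RoughChannel(**raw["channel"]) if raw.get("channel") else None
    for s in raw.get("sources") or []:
        _source_from_dict(s)  # validate early
    return RunConfig(
        scenario=scenario, cell=cell, step=step, channel=channel,
        sources=raw.get("sources"), D=float(raw.get("D", 3600.0)),
        greens_3d=raw.get("greens_3d", "paper"), mc=raw.get("mc"),
        out=raw.get("out"),
    )


def save_config(cfg: RunConfig, path) -> None:
    """Round-trippable YAML dump of the raw (non-defaulted) config."""
    doc: dict = {}
    if cfg.scenario:
        doc["scenario"] = cfg.scenario
    if cfg.cell:
        doc["cell"] = dataclasses.asdict(cfg.cell)
    if cfg.step:
        doc["step"] = dataclasses.asdict(cfg.step)
    if cfg.channel:
        doc["channel"] = dataclasses.asdict(cfg.channel)
    if cfg.sources:
        doc["sources"] = cfg.sources
    doc["D"] = cfg.D
    if cfg.greens_3d != "paper":
        doc["greens_3d"] = cfg.greens_3d
    if cfg.mc:
        doc["mc"] = cfg.mc
    if cfg.out:
        doc["out"] = cfg.out
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# -- fixtures --------------------------------------------------------------

FIXTURE_KINDS = ("smooth-channel", "rough-channel", "cavity", "vessel",
                 "free-cell", "synthetic-trajectory")


def generate_fixture(kind: str, seed: int, outdir) -> list[Path]:
    """Write a self-contained, deterministic test fixture to ``outdir``.

    Configs regenerate bit-identically from the same seed.  The
    ``synthetic-trajectory`` fixture is a hand-constructed CSV (labelled
    synthetic) with a transit time of exactly 0.30 h and uniform speed,
    for exercising the transit metrics without running a simulation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def dump(name: str, doc: dict) -> None:
        p = outdir / name
        p.write_text(yaml.safe_dump(doc, sort_keys=True))
        written.append(p)

    step = {"dt": 0.0001, "eta": 0.0, "seed": int(seed), "t_end": 1.0}
    if kind == "smooth-channel":
        dump("smooth_channel.yaml", {
            "scenario": "channel",
            "channel": {"y0": 5.0, "epsilon": 0.0, "omega": 0.0,
                        "x_entry": 0.0, "length": 60.0},
            "step": step})
    elif kind == "rough-channel":
        dump("rough_channel.yaml", {
            "scenario": "channel",
            "channel": {"y0": 5.0, "epsilon": 1.0, "omega": 0.5,
                        "x_entry": 0.0, "length": 60.0},
            "step": step})
    elif kind == "cavity":
        dump("cavity.yaml", {"scenario": "cavity", "step": step})
    elif kind == "vessel":
        dump("vessel.yaml", {"scenario": "vessel", "step": step})
    elif kind == "free-cell":
        dump("free_cell.yaml", {
            "sources": [{"x": 60.0, "y": 0.0, "gamma_s": 1.2e6}],
            "step": step})
    elif kind == "synthetic-trajectory":
        # synthetic: uniform 200 μm/h translation entering x=0 at t=0.10
        # and clearing x=60 at t=0.40 -> tau = 0.30 h by construction
        dump("synthetic_trajectory.yaml", {
            "channel": {"y0": 5.0, "epsilon": 0.0, "omega": 0.0,
                        "x_entry": 0.0, "length": 60.0},
            "step": step})
        import pandas as pd

        t = np.round(np.arange(0.0, 0.5001, 0.01), 6)
        rows = []
        for ti in t:
            xc = -20.0 + 200.0 * ti  # enters x=0 at t=0.10, exits 60 at 0.40
            for node, off in ((0, 0.0), (1, -0.001)):
                rows.append({"t": ti, "entity": "membrane", "node_id": node,
                             "x": xc + off, "y": float(node)})
        p = outdir / "synthetic_trajectory.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return written


# -- outputs ---------------------------------------------------------------


def write_outputs(traj: Trajectory, outdir, metrics: dict | None = None) -> dict:
    """Write trajectory CSV + metrics JSON; returns the metrics dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(outdir / "trajectory.csv", index=False)
    m = dict(metrics or {})
    m.setdefault("t_final_h", float(traj.times[-1]))
    m.setdefault("events", {k: float(v) for k, v in traj.events.items()})
    if traj.membrane.shape[2] == 2:
        m.setdefault("final_area_um2", polygon_area(traj.membrane[-1]))
    if traj.channel is not None:
        tau = penetration_time(traj, traj.channel)
        m.setdefault("penetration_time_h", tau)
        if tau is not None and len(traj.times) > 2:
            m.setdefault("in_channel_mean_speed_um_per_h",
                         in_channel_mean_speed(traj, traj.channel))
    if len(traj.times) > 1:
        _, v = speed_series(traj)
        m.setdefault("max_speed_um_per_h", float(v.max()))
    (outdir / "metrics.json").write_text(json.dumps(m, indent=2))
    return m


def trajectory_from_csv(path, channel: RoughChannel | None = None) -> Trajectory:
    """Rebuild a Trajectory from its tidy CSV (inverse of ``to_frame``).

    Only positional information survives the round trip (the event log and
    contact flags are stored in the metrics JSON), which is all rendering
    and the shape metrics need.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    times = np.sort(df["t"].unique())
    frames = {}
    for entity in ("membrane", "nucleus"):
        sub = df[df.entity == entity]
        if sub.empty:
            frames[entity] = None
            continue
        sub = sub.sort_values(["t", "node_id"])
        n = sub.node_id.nunique()
        frames[entity] = sub[cols].to_numpy().reshape(len(times), n, len(cols))
    mem = frames["membrane"]
    nuc = frames["nucleus"] if frames["nucleus"] is not None else np.zeros_like(mem)
    if mem.shape[2] == 2 and mem.shape[1] >= 3:
        from .measurements import polygon_centroid

        cents = np.array([polygon_centroid(f) for f in mem])
    else:
        cents = mem.mean(axis=1)
    return Trajectory(times=times, membrane=mem, nucleus=nuc, centroids=cents,
                      contact=np.zeros(len(times), dtype=bool), events={},
                      channel=channel)


def render(traj: Trajectory, outdir, every: int = 1, dpi: int = 80) -> list[Path]:
    """Frame images: cell red, nucleus green, obstacles gray, source asterisk."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(0, len(traj.times), every):
        fig, ax = plt.subplots(figsize=(6, 4))
        if traj.channel is not None:
            xs = np.linspace(traj.channel.x_entry,
                             traj.channel.x_entry + traj.channel.length, 200)
            w = traj.channel.y0 + traj.channel.epsilon * np.sin(traj.channel.omega * xs)
            ax.fill_between(xs, w, w + 8, color="0.7")
            ax.fill_between(xs, -w - 8, -w, color="0.7")
        mem = traj.membrane[k]
        nuc = traj.nucleus[k]
        ax.fill(mem[:, 0], mem[:, 1], color="tab:red", alpha=0.6)
        ax.fill(nuc[:, 0], nuc[:, 1], color="tab:green", alpha=0.8)
        ax.set_aspect("equal")
        ax.set_title(f"t = {traj.times[k]:.4f} h")
        p = outdir / f"frame_{k:05d}.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        paths.append(p)
    return paths
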