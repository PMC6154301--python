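"""Monte Carlo uncertainty quantification of channel transit times.

Parameters with uncertain values are sampled from stated distributions
(normal for the rate constants, uniform for the wall roughness), one
channel simulation is run per sample with the random walk enabled, and
the resulting penetration times are aggregated into a mean, a sample
standard deviation S_n, per-parameter Pearson correlations, and a
histogram/empirical CDF.  The total numerical error splits into a time
integration part bounded by C*dt (C estimated by Richardson pairs) and a
Monte Carlo part S_n/sqrt(N_s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .cell_model import CellParams
from .exceptions import UndefinedCorrelationError
from .integrator import StepConfig, run_scenario
from .measurements import penetration_time
from .scenarios import build_scenario

__all__ = [
    "ParamDistribution",
    "TABLE_NORMALS",
    "ROUGHNESS_UNIFORMS",
    "MCResult",
    "ErrorBudget",
    "sample_params",
    "run_mc",
    "pearson_r",
    "richardson_constant",
    "error_budget",
    "cdf_hist",
]

_KNOWN = ("D", "beta", "alpha", "alpha_n", "epsilon", "omega")
#: parameters that are physically strictly positive (negative normal draws
#: are rejected and redrawn; astronomically rare at the default sigmas)
_POSITIVE = ("D", "beta", "alpha", "alpha_n", "epsilon")


@dataclass
class ParamDistribution:
    """Sampling distribution for one model parameter."""

    name: str
    kind: str  # "normal" | "uniform"
    mu: float | None = None
    sigma: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _KNOWN:
            raise ValueError(f"unknown parameter {self.name!r}; choose from {_KNOWN}")
        if self.kind == "normal":
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ValueError("normal distribution needs mu and sigma > 0")
        elif self.kind == "uniform":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError("uniform distribution needs lo < hi")
        else:
            raise ValueError("kind must be 'normal' or 'uniform'")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, n)
        x = rng.normal(self.mu, self.sigma, n)
        if self.name in _POSITIVE:
            bad = x <= 0
            while bad.any():
                x[bad] = rng.normal(self.mu, self.sigma, bad.sum())
                bad = x <= 0
        return x


def TABLE_NORMALS() -> list[ParamDistribution]:
    """The four rate-constant distributions of the transit UQ study."""
    return [
        ParamDistribution("D", "normal", mu=3600.0, sigma=30.0),
        ParamDistribution("beta", "normal", mu=60.0, sigma=3.0),
        ParamDistribution("alpha", "normal", mu=250.0, sigma=40.0),
        ParamDistribution("alpha_n", "normal", mu=2500.0, sigma=125.0),
    ]


def ROUGHNESS_UNIFORMS() -> list[ParamDistribution]:
    """Wall-roughness amplitude and frequency distributions."""
    return [
        ParamDistribution("epsilon", "uniform", lo=0.5, hi=1.5),
        ParamDistribution("omega", "uniform", lo=0.0, hi=0.6),
    ]


def sample_params(dists, n_samples: int, seed=None) -> pd.DataFrame:
    """Independent draws per distribution; one column per parameter."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({d.name: d.draw(n_samples, rng) for d in dists})


def pearson_r(x, y) -> float:
    """Pearson linear correlation coefficient, bounded by [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def richardson_constant(tau_dt: float, tau_2dt: float, dt: float) -> float:
    """First-order error constant C = (tau(dt) - tau(2dt)) / dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (tau_dt - tau_2dt) / dt


@dataclass
class ErrorBudget:
    """Total-error bound: time integration plus Monte Carlo sampling."""

    C: float
    dt: float
    S_n: float
    N_s: int
    E_ti: float = field(init=False)
    E_mc: float = field(init=False)
    E_total: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.C, self.dt, self.S_n) < 0 or self.N_s < 1:
            raise ValueError("error budget inputs must be non-negative, N_s >= 1")
        self.E_ti = self.C * self.dt
        self.E_mc = self.S_n / math.sqrt(self.N_s)
        self.E_total = self.E_ti + self.E_mc


def error_budget(C: float, dt: float, S_n: float, N_s: int) -> ErrorBudget:
    return ErrorBudget(C=C, dt=dt, S_n=S_n, N_s=N_s)


@dataclass
class HistCDF:
    bin_edges: np.ndarray
    frequency: np.ndarray      # relative frequency per bin (sums to 1)
    ecdf_x: np.ndarray         # sorted values
    ecdf_y: np.ndarray         # right-continuous empirical CDF at ecdf_x
    lognormal_mu: float
    lognormal_sigma: float


def cdf_hist(tau, bins: int = 20) -> HistCDF:
    """Relative-frequency histogram, empirical CDF and a lognormal fit."""
    tau = np.asarray(tau, dtype=float)
    tau = tau[np.isfinite(tau)]
    if len(tau) == 0:
        raise ValueError("need at least one finite value")
    counts, edges = np.histogram(tau, bins=bins)
    freq = counts / counts.sum()
    xs = np.sort(tau)
    ys = np.arange(1, len(xs) + 1) / len(xs)
    if np.all(tau > 0) and np.ptp(tau) > 0:
        shape, _, scale = _stats.lognorm.fit(tau, floc=0.0)
        mu, sigma = math.log(scale), shape
    else:
        mu, sigma = math.nan, math.nan
    return HistCDF(edges, freq, xs, ys, mu, sigma)


@dataclass
class MCResult:
    """Aggregated Monte Carlo transit study."""

    samples: pd.DataFrame         # one row per sample (parameter draws)
    tau: np.ndarray               # penetration time per sample (nan: failed)
    penetrated: np.ndarray        # bool per sample
    mean_tau: float
    S_n: float
    r: dict                       # per-parameter Pearson r against tau
    n_failed: int
    seed: int | None = None

    def hist(self, bins: int = 20) -> HistCDF:
        return cdf_hist(self.tau[self.penetrated], bins=bins)

    def budget(self, C: float, dt: float) -> ErrorBudget:
        return error_budget(C, dt, self.S_n, int(self.penetrated.sum()))

    def summary(self) -> dict:
        return {
            "n_samples": int(len(self.tau)),
            "n_penetrated": int(self.penetrated.sum()),
            "n_failed": int(self.n_failed),
            "mean_tau_h": self.mean_tau,
            "S_n_h": self.S_n,
            "pearson_r": {k: float(v) for k, v in self.r.items()},
        }


#: fall-back transit cap: ten times the default-parameter transit time, h
TRANSIT_CAP = 4.0


def _one_sample(idx: int, row: dict, master_seed, scenario_name: str,
                dt: float, eta: float | None, cap: float,
                base_params: CellParams):
    """Run one seeded channel simulation for one parameter draw.

    The per-sample RNG stream is derived from the master seed and the
    sample index, so results do not depend on worker scheduling.
    """
    overrides = {k: row[k] for k in ("beta", "alpha", "alpha_n") if k in row}
    params = base_params.with_overrides(**overrides) if overrides else base_params
    sc = build_scenario(
        scenario_name,
        params=params,
        D=row.get("D", 3600.0),
        epsilon=row.get("epsilon", 1.0),
        omega=row.get("omega", 0.5),
    )
    if sc.channel is None:
        raise ValueError("Monte Carlo transit study needs a channel scenario")
    seed = np.random.SeedSequence(entropy=master_seed, spawn_key=(idx,))
    cfg = StepConfig(dt=dt, eta=eta, seed=seed, t_end=cap,
                     record_every=None, stop="transit")
    traj = run_scenario(sc, cfg)
    tau = penetration_time(traj, sc.channel)
    return math.nan if tau is None else tau


def run_mc(scenario: str = "channel", dists=None, n_samples: int = 100,
           seed: int | None = 0, workers: int = 1, dt: float = 1e-4,
           eta: float | None = None, cap: float = TRANSIT_CAP,
           base_params: CellParams | None = None) -> MCResult:
    """Monte Carlo transit-time study: one channel simulation per sample.

    Parameters not listed in ``dists`` stay at their defaults.  Samples
    that never complete the transit within the time cap are recorded and
    excluded from the tau statistics.  The same master seed yields the
    same result regardless of ``workers``.
    """
    dists = TABLE_NORMALS() if dists is None else dists
    base_params = base_params or CellParams()
    samples = sample_params(dists, n_samples, seed=np.random.SeedSequence(
        entropy=seed, spawn_key=(0xA5,)))
    rows = samples.to_dict("records")
    args = [(i, row, seed, scenario, dt, eta, cap, base_params)
            for i, row in enumerate(rows)]
    if workers > 1:
        from joblib import Parallel, delayed

        tau = Parallel(n_jobs=workers)(delayed(_one_sample)(*a) for a in args)
    else:
        tau = [_one_sample(*a) for a in args]
    tau = np.asarray(tau, dtype=float)
    ok = np.isfinite(tau)
    if not ok.any():
        raise RuntimeError("all Monte Carlo samples failed to penetrate")
    good = tau[ok]
    r = {}
    for col in samples.columns:
        try:
            r[col] = pearson_r(samples[col].to_numpy()[ok], good) \
                if ok.sum() >= 2 else math.nan
        except UndefinedCorrelationError:
            r[col] = math.nan
    return MCResult(
        samples=samples,
        tau=tau,
        penetrated=ok,
        mean_tau=float(good.mean()),
        S_n=float(good.std(ddof=1)) if ok.sum() > 1 else 0.0,
        r=r,
        n_failed=int((~ok).sum()),
        seed=seed,
    )
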