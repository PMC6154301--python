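# cellpass

Simulation of single-cell and nucleus deformation during confined
migration — amoeboid transit through pores, channels and vessel walls —
with Monte Carlo uncertainty quantification of the transit time.

Motile cells squeezing through tissue (immune cells leaving venules,
metastatic cells crossing endothelium) deform both their body and their
much stiffer nucleus.  `cellpass` implements a phenomenological
cell-based model of that process for researchers in cell biomechanics who
want transit-time statistics at interactive cost: a full channel
transmigration simulates in well under a second, so thousands of
parameter samples are feasible on a laptop.

## The model

The cell is a ring of `N` membrane nodes `x_i` tethered to matching
nucleus-surface nodes `xⁿ_i` (spherical lattices in 3D).  Fixed offset
vectors `x̂_i = x_i(0) − xⁿ_i(0)` and `x̂ⁿ_i = xⁿ_i(0) − x_c(0)` encode
the rest shape, and the overdamped stochastic dynamics

    dx_i  = β ∇c(x_i) dt + α (xⁿ_i + B(φ) x̂_i − x_i) dt + η dW_i
    dxⁿ_i = αⁿ (x_c + B(φ) x̂ⁿ_i − xⁿ_i) dt − α (xⁿ_i + B(φ) x̂_i − x_i) dt + η dW_i

combine chemotactic drift up the gradient of a point-source Green's
function field `c`, spring-like shape memory with relaxation rates α
(cell) and αⁿ (nucleus), a per-step best-fit rotation `B(φ)` that gives
the cell persistent polarity, and a Wiener-process random walk.  Rigid
obstacles remove the normal component of any displacement into them, so
cells slide along walls and squeeze through openings.  An
implicit–explicit (IMEX) Euler scheme makes the stiff relaxation terms
unconditionally stable; defaults are `R = 12.5` μm, `Rⁿ = 5` μm,
`α = 250/h`, `αⁿ = 2500/h`, `β = 60/h`, `D = 3600` μm²/h, `Δt = 10⁻⁴` h.

The headline measurement is the channel **penetration time** τ: the
interval from the first membrane node entering a 60 μm long, ≈10 μm wide
channel with sinusoidally rough walls `y = ±(y0 + ε sin ωx)` until the
last node leaves it.  Monte Carlo machinery draws uncertain parameters
(`D, β, α, αⁿ` normal; roughness `ε, ω` uniform), runs one seeded
simulation per draw, and reports mean, spread `S_n`, histograms/CDFs with
a lognormal fit, per-parameter Pearson correlations, and the error budget
`E ≤ C·Δt + S_n/√N_s`.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Simulate the deterministic rough-channel transit (no random walk) and
print the transit metrics:

```bash
cellpass simulate --scenario channel --eta 0 --dt 0.0001 --out out/
```

which prints:

```json
{
  "t_final_h": 0.4359999999999683,
  "events": {
    "channel_entry": 0.012799999999999978,
    "channel_exit": 0.3789999999999746,
    "source_consumed": 0.3859999999999738
  },
  "final_area_um2": 487.29464062322705,
  "penetration_time_h": 0.3661999999999746,
  "in_channel_mean_speed_um_per_h": 232.2999462899539,
  "max_speed_um_per_h": 1124.787629268393
}
```

The cell needs 0.366 h to squeeze through the channel, migrating at
≈ 230 μm/h while inside (the 1–5 μm/min amoeboid range); the speed spikes
(here to ≈ 1100 μm/h) as it closes on the singular source, and after
engulfing it the cell relaxes back to its circular rest shape within the
0.05 h tail (final area = the 30-gon rest area 487.3 μm²).  A Monte Carlo screen over the wall
roughness:

```bash
cellpass mc --study two --samples 200 --seed 7 --out mc_out/
```

writes one row per sample (ε, ω, τ, penetrated) to `mc_out/samples.csv`
plus a JSON summary with the mean, `S_n` and the Pearson correlations of
ε and ω with τ.  `cellpass convergence` runs the Δt-refinement study and
reports the Richardson error constant, and `cellpass render` turns any
saved config into frame images (cell red, nucleus green, obstacles gray).

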