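# Model and methods

## The model

A cell is represented by `N` nodal points on its membrane and `N` matching
nodal points on the surface of its nucleus (a spherical lattice of
`N × (M-1) + 2` nodes per surface in 3D).  Two families of fixed
*equilibrium offset vectors* encode the rest shape: `x̂_i` connects nucleus
node *i* to membrane node *i* at time zero, and `x̂ⁿ_i` connects the
nucleus centre to nucleus node *i*.  The overdamped dynamics per membrane
node are

    dx_i = β ∇c(x_i) dt + α (xⁿ_i + B(φ) x̂_i − x_i) dt + η dW_i,

and per nucleus node

    dxⁿ_i = αⁿ (x_c + B(φ) x̂ⁿ_i − xⁿ_i) dt
            − α (xⁿ_i + B(φ) x̂_i − x_i) dt + η dW_i,

with `x_c` the area (2D) or volume (3D) centroid of the nucleus surface,
recomputed every step, and `W` a vector Wiener process applied
independently per node.  `B(φ)` is the rigid rotation best aligning the
initial (centred) membrane shape with the current one — fitted once per
step about the current membrane centroid, in closed form in 2D
(`φ = atan2(Σ x̃×d, Σ x̃·d)`) and by orthogonal Procrustes (Kabsch/SVD)
with Euler-angle extraction in the `B_x·B_y·B_z` factor order in 3D.
Rotating the offsets gives the cell a persistent polarity: after a
deformation it recovers its shape *and* its orientation.

The chemoattractant field of a point source of strength `γ_S` in a medium
of diffusivity `D` is the free-space fundamental solution,
`c = −γ_S/(2πD)·ln r` in 2D; fields of several sources superpose, and a
source is switched off permanently once it lies inside the membrane
polygon (even–odd containment; boundary counts as inside).  The drift uses
the linear-implicit (IMEX) gradient convention

    ∇c_i = γ_S (x_S − x_i^{p+1}) / (π D ‖x_S − x_i^p‖²)     (2D),

i.e. the direction is implicit, the squared distance explicit.  Note the
`πD` denominator: it is deliberately a factor 2 larger than the analytic
gradient of the logarithmic solution; the drift is phenomenological and
`β` absorbs constant factors.  A regression test pins this convention.
In 3D two flavours exist: the inverse-square concentration
(`form="paper"`, the default, gradient ∝ 1/r⁴) and the standard
`1/(4πDr)` fundamental solution (`form="physical"`, gradient ∝ 1/r²);
the CLI exposes the choice as `--greens-3d {paper|physical}`.

### Time integration

An IMEX Euler scheme advances membrane first, then nucleus (the nucleus
equation references the *new* membrane positions).  Relaxation terms and
the gradient direction are implicit, so each update divides by
`1 + Δt·α (+ Δt·β·g̃)` resp. `1 + Δt·αⁿ`; the relaxation can therefore not
oscillate or blow up for any `Δt`, and the exact equilibrium
(`x_i = xⁿ_i + B x̂_i`, `xⁿ_i = x_c + B x̂ⁿ_i`) is a machine-precision
fixed point of the noise-free scheme.  Noise is added before contact
resolution so obstacles also constrain random motion.  The scheme is
first order: deterministic channel transit times at `Δt, Δt/2` pairs halve
their differences almost exactly (measured ratios 2.00–2.08 over
`Δt ∈ [5·10⁻⁵, 8·10⁻⁴]` h).  A node displacement exceeding one cell
radius in a single step aborts the run with a suggestion to reduce `Δt`.

### Contact

Obstacles are rigid and immobile, described by a signed distance
(positive outside) and an outward normal.  A node within `tol = 10⁻²` μm
of a boundary and moving inward loses the normal component of its
displacement (tangential sliding); a node whose step still ends inside is
clamped back to the nearest boundary point along the local normal, which
prevents slow tunnelling at finite `Δt`.  Pure point-membership almost
never triggers in floating point, hence the tolerance plus swept-crossing
operationalisation.  The same projection applies between cells: nodes of
one cell inside or within `tol` of another cell's membrane polygon are
projected against the outward normal of the nearest boundary segment.

An important structural property of this contact law: it is kinematic,
with no force threshold.  A node whose drive points into the constraint
cone of a flat or concave rigid feature is pinned, and a pinned node
arrests the entire cell through the shape-memory springs, whose force
scale `α·(R−Rⁿ) ≈ 1900` μm/h exceeds the chemotactic pull (of order
100–300 μm/h) by an order of magnitude.  A cell of radius 12.5 μm
therefore cannot squeeze into a 10 μm opening guarded by thick walls with
capped ends — the configuration is statically stable and the simulation
deadlocks.  The transmigration scenarios consequently model endothelial
walls as **open-ended thin sheets** (thickness 1–1.5 μm, the scale of real
capillary endothelium away from its nuclei): contact acts through the two
sinusoidal faces, the micron-scale sheet edges carry none, and a cell
wider than the channel spreads its flanks over the outside of the sheet
while its core (in particular the nucleus, which is wider than the
narrowest points of a rough channel) transits the lumen and feels the
roughness.  The cavity scenario similarly uses posts small enough for the
membrane to wrap around while the nucleus is forced through the
sub-nucleus pore.

### The rough channel and the transit time

The channel walls are `y = ±(y0 + ε sin(ωx))` over `x ∈ [0, L]` with
`y0 = 5` μm and `L = 60` μm (width ≈ 10 μm).  The penetration time τ runs
from the first membrane node exceeding `x = 0` to all membrane nodes
exceeding `x = L`; entry/exit are detected online at full step resolution.

Scenario constants the study does not fix are reconstructed as follows
and then frozen.  The cell starts on the axis with its front 2.5 μm before
the entry.  The source sits 46 μm past the exit — far enough that the cell
clears the channel before engulfing the source even for fast parameter
draws (engulfment kills the drift and leaves the cell relaxing in place) —
and secretes at `γ_S = 7.65·10⁶` mol/(h·μm³).  Two facts force a rate well
above the free-migration default: the assembly of membrane plus drift-free
nucleus translates at about *half* the bare membrane drift speed
`βγ_S/(πDr)` (the nucleus is dragged through the same α springs that
propel the membrane), and the published transit statistics sit at the
~200 μm/h amoeboid speed scale.  The pair (offset, rate) was calibrated
once against the three published anchors jointly — deterministic
`τ(N=30) = 0.3735` h, converged Monte Carlo mean `0.356` h, in-channel
speed `≈ 200` μm/h — giving `τ = 0.366` h and a mean in-channel speed of
`≈ 228` μm/h for the deterministic default run, insensitive to the node
count (≤ 2.5% variation over `N ∈ {10, 30, 50, 100}`).

### Noise amplitude

The parameter table gives no value for η.  We use `η = 5` μm·h^(−1/2)
throughout: the stationary fluctuation of a tethered membrane node is then
`η/√(2α) ≈ 0.22` μm (sub-micron ruffling, a perturbation rather than a
driver) and the per-step RMS kick at the default `Δt` is 0.05 μm.  The
random walk is enabled in every Monte Carlo sample and disabled (`η = 0`)
in the deterministic reference runs, which are then bit-reproducible; with
a fixed master seed the stochastic runs are reproducible too, and each
Monte Carlo sample derives its own stream from the master seed and the
sample index, so results do not depend on worker scheduling.

## Monte Carlo uncertainty quantification

Uncertain parameters are sampled independently — `D ~ N(3600, 30²)`,
`β ~ N(60, 3²)`, `α ~ N(250, 40²)`, `αⁿ ~ N(2500, 125²)`,
`ε ~ U(0.5, 1.5)` μm, `ω ~ U(0, 0.6)` μm⁻¹ — with non-positive draws of
strictly positive parameters redrawn (astronomically rare at these σ).
One seeded channel simulation runs per sample; samples that have not
completed the transit by `t = 4` h (ten times the default transit) are
recorded as non-penetrating and excluded from the τ statistics with their
count reported.  Aggregates: mean, sample standard deviation `S_n`,
relative-frequency histogram, right-continuous empirical CDF with a
lognormal fit (`scipy.stats.lognorm`, location fixed at zero), and the
Pearson correlation of each sampled parameter with τ.  The error budget
combines the first-order time-integration bound `E_ti = C·Δt` (C from
Richardson pairs at `Δt, 2Δt`) with the sampling error
`E_mc = S_n/√N_s`.

Problem sizes: the full study uses 10,000 samples; the packaged
acceptance computation and test suite use 500 samples for the
four-parameter and roughness studies and 200 for the six-parameter study,
enough for correlation standard errors of ≈ 0.04 and a mean-τ standard
error of ≈ 0.002 h.

### What the scaled-down studies do and do not show

The generator reproduces the *structure* of the published study: the same
distributions, the same scenario, the same estimators.  Three quantitative
discrepancies are expected and documented rather than tuned away:

- **r(D, τ).**  With `σ_D/D = 0.83%` while `σ_β/β = 5%`, and τ depending
  on D and β essentially through the drift `βγ_S/(πDr)`, the τ-variation
  attributable to D is ≈ 6× smaller than that from β.  Any such model
  yields `|r_D| ≈ 0.1·|r_β|`; a strong positive `r_D ≈ 0.6` alongside a
  moderate negative `r_β` is not reproducible from the stated
  distributions, and this package measures `r_D ≈ 0` (positive but within
  sampling noise).
- **S_n of the six-parameter study.**  Our roughness mechanisms (nucleus
  squeezing at the bump waists, tangential-projection losses and path
  lengthening along the sinusoidal faces, for the flank nodes on either
  face of the thin sheets) spread τ by a few hundredths of an hour,
  roughly a third of the published spread.
- **ε vs ω ordering.**  Increasing ε both narrows the channel
  (min width `10 − 2ε`) and steepens the bumps, while ω only steepens and
  multiplies them; amplitude therefore dominates frequency here
  (`r_ε > r_ω`), the reverse of the published ordering.

One further measured property: the transit time is non-decreasing along
the two published roughness sweeps (ε at `ω = 0.5`; ω at `ε = 1.0`), but
not over the full ε×ω product grid — at `(ε, ω) = (1.5, 0.75)` the bump
wavelength approaches the nucleus size and transit is slightly faster
than at `(1.5, 0.5)`.

## Numerical choices and degenerate inputs

- Shoelace areas are returned as absolute values so node orientation never
  flips downstream metrics; zero-area polygons fall back to the vertex
  mean (with a warning) for centroids.
- Mesh volume uses the x-projection of the divergence theorem; y/z
  projections are cross-checked and a >1% disagreement warns of an open or
  inconsistently oriented mesh.  The 3D lattice merges the `N` coincident
  north-pole nodes and adds the (otherwise missing) south pole so the
  triangulation closes; the inscribed 30×30 lattice underestimates the
  sphere volume by ≈ 1.0%.
- Coincident-node (2D) or collinear (3D) configurations make the rotation
  fit degenerate; the identity is returned with a warning.
- Channel membership is by x-interval, membrane nodes only; entry strictly
  `> x_entry`, exit strictly `> x_entry + L` for all nodes.
- The per-step hot path (polygon centroid, rotation angle, IMEX gradient
  coefficients, wall-pair contact) is additionally implemented as numba
  kernels that mirror the vectorised reference implementations;
  equivalence is pinned by tests and the package runs (slowly) without
  numba.

## Limitations

Inertia, adhesion, ECM degradation, elastic obstacles and membrane-bound
chemical species are outside the model.  The contact law is node-based:
membrane *edges* may cross thin obstacles even though nodes cannot.  The
synthetic scenarios use a single stationary source and rigid geometry;
real transmigration involves deformable endothelium, flow and multiple
cues, so agreement of the packaged statistics with the published ones
should be read as internal consistency of the model family, not as
validation against experiment.
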