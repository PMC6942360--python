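# Methods

## Model

`dynspom` simulates single-species metapopulation occupancy on a dynamic
network of habitat patches with an Incidence Function Model (IFM): a
discrete-time, two-state (presence/absence) Markov chain per patch,
coupled across patches through a dispersal kernel.

For patch *i* with area *A_i* (ha), age *a_i* (steps since creation) and
occupancy indicator *p_i*:

- **Connectivity** — `S_i = A_i^c · Σ_{j≠i} p_j · exp(−α·d_ij) · A_j^b`,
  with *d_ij* the centroid-to-centroid distance in metres. α is the
  inverse mean dispersal distance (1/m); *b* scales emigration with the
  source patch's area and *c* immigration with the focal patch's area.
- **Spatial colonization** — `C_is = S_i² / (S_i² + y²)`. The squared
  terms encode an Allee effect (colonization accelerates once connectivity
  is substantial); *y* is the half-saturation constant, so smaller *y*
  means higher colonization efficiency.
- **Spatial extinction** — `E_is = min(1, e / A_i^x)`, and exactly 1 when
  `A_i ≤ e^(1/x)`. *e* = `A0^x` is the extinction probability of a 1-ha
  patch, *A0* the critical area below which persistence is impossible,
  and *x* the strength of the area–extinction relation.
- **Succession** — each patch's age maps to temporal modifiers `E_it`,
  `C_it` per guild:
  - early-successional: `E_it = 1/(1+exp(−0.09·a))`,
    `C_it = 1/(1+exp(0.09·a))` (young patches suitable);
  - late-successional: the mirrored sigmoids (old patches suitable);
  - mid-successional: `E_it = exp(−0.08·a)` for `a < 50` and
    `exp(0.08·(a−100))` for `a ≥ 50` (U-shaped, minimum `e^(−4)` at age
    50), and `C_it = 1 − E_it`-shaped unimodal curves from the same
    branches (maximum `1 − e^(−4)` at 50). All outputs are clamped to
    [0, 1]; mid-successional extinction therefore saturates at 1 past age
    100 and mid colonization at 0.

  The mid-successional branch form is the minimal parameterization that
  keeps the 0.08 rate constant, the age-50 optimum, continuity at the
  optimum, and valid probabilities while producing the intended
  U-shaped/unimodal curves; naive one-branch exponentials cannot do all
  four at once.
- **Combination** — defaults are the products `C_i = C_is·C_it` and
  `E_i = E_is·E_it`: successional unsuitability vetoes colonization and
  scales stochastic extinction. A probabilistic-OR alternative
  (`1−(1−a)(1−b)`) is available for both rules but is not the extinction
  default: the early-successional `E_it` never drops below 0.5, so
  OR-extinction imposes `E_i ≥ 0.5` per step on early species at every
  age and forbids their persistence entirely, inverting the guild's
  intended behaviour. Under the product rules all three guilds behave as
  designed (see "What the tests show" below).
- **Update** — synchronous Bernoulli transitions: empty patches colonize
  with `C_i`, occupied ones go extinct with `E_i`; one uniform deviate
  per patch in ascending patch-id order. There is no rescue effect
  (`E_i` never depends on `S_i`), so the stationary single-patch law is
  `J = C/(C+E)` for constant rates.

## Landscape dynamics

Landscapes are square arenas (default side 3163 m, ≈1000 ha) holding
`round(arena_ha · cover / mean_area)` circular patches — 100/200/400 at
5/10/20% cover with 0.5-ha mean patches. Areas are normal(0.5, 0.2) ha,
resampled below a 0.01-ha floor; positions come from rejection sampling
with a 10-m minimum edge-to-edge spacing (circles never overlap, and the
dispersal kernel still uses centroid distances, the standard IFM
point-with-area abstraction). A clear diagnostic is raised when a
parameterization is too crowded to place.

**Turnover** (landscape dynamism) destroys `round(f·N)` uniformly chosen
patches per step and creates the same number elsewhere — fresh areas from
the same distribution, age 0 — so patch count is exactly conserved and
habitat cover conserved in expectation. Destroyed patch ids retire
permanently. **Aging** increments every living patch's age once per step.

A trajectory's per-step order is: turnover → rates on the post-turnover
landscape → occupancy update → aging. Occupants of a destroyed patch die
immediately (they do not disperse in the destruction step), and a patch
created this step is colonizable this step at age 0. This makes patch
destruction the dominant, deterministic extinction pathway in dynamic
scenarios, which is the regime the experiment is designed to probe.

**Initial ages** default to integer-uniform on [0, 100] so every
successional stage is represented at t = 0 and no guild starts
artificially disadvantaged; an all-zero mode is available. Initial
occupancy places `round(0.5·N)` occupants uniformly at random.

## Virtual species

The factorial set crosses α ∈ {0.02, 0.004, 0.001} (mean dispersal 50 m /
250 m / 1 km), y ∈ {5, 10, 20}, A0 ∈ {0.05, 0.1} ha (hence e ∈ {0.05,
0.1} with x = 1) and the three guilds: 54 species, 18 per guild. x = 1
and c = 1 are fixed; b defaults to 1 and is configurable. Ids run in
guild blocks (early 1–18, mid 19–36, late 37–54), within a block by (A0
asc, y asc, dispersal ability asc), which places the high-dispersal y = 5
mid-successional pair at ids 21 and 30.

## Experiment design and summaries

The full design is 54 species × 3 covers × 4 dynamism levels (0, 5, 10,
20% per step) = 648 cells, 216 per guild block, 12 landscape scenarios;
the headline profile runs 500 iterations × 100 steps per cell with 50%
initial occupancy. Equilibrium occupancy is the fraction of occupied
patches at step 100, averaged over iterations; 95% CIs use the normal
approximation across iterations (a percentile bootstrap is available),
clamped to [0, 1]. Extinct iterations count as occupancy 0 in the mean
and are also reported as `extinct_fraction`.

Each iteration regenerates its landscape by default, so CIs absorb both
landscape and demographic stochasticity; a shared-landscape mode isolates
the demographic component. Seeding is hierarchical
(`SeedSequence([base_seed, cell_index, iteration])` split into landscape
and trajectory streams), making results bit-identical across execution
orders and worker counts.

The test suite and the reproduction script use a reduced profile — 100
iterations × 100 steps on single-species sub-grids — which keeps every
directional effect many CI-widths wide while finishing in minutes on one
core. The full 648-cell × 500-iteration design runs overnight on a
multicore workstation via `run_experiment(grid, parallel_workers=n)`.

## Guild representatives in the pattern checks

The directional checks (mid-successional peak at intermediate turnover,
late-successional monotone decline, early-successional rise from the
static scenario, occupancy increasing with cover) use the high-dispersal,
high-colonization-efficiency representative of each guild (α = 0.001,
y = 5, A0 = 0.05; ids 3/21/39) at 10% cover. With areas in hectares and
distances in metres, mean-field connectivity at 50% occupancy and 10%
cover is roughly `S ≈ 0.04 / 1 / 16` for α = 0.02 / 0.004 / 0.001 — so
for the two lower dispersal levels `C_is = S²/(S²+y²) ≲ 0.04` cannot
offset per-step losses and those metapopulations collapse regardless of
guild or turnover. Dispersal ability and colonization efficiency are
therefore strong positive filters on occupancy in this parameter space,
and the guild-specific disturbance responses are expressed by the viable
high-dispersal species.

## What the synthetic landscapes do and do not emulate

The generator reproduces: overall habitat amount, a realistic patch-size
distribution, enforced patch separation, balanced stochastic turnover,
and succession via patch age. It deliberately omits: spatial or temporal
autocorrelation of disturbance, unbalanced creation/destruction rates,
habitat-quality gradients, raster geometry, and within-patch abundance
dynamics. Passing pattern checks therefore demonstrate the interplay of
succession, turnover and dispersal under spatially random disturbance;
they do not speak to clustered disturbance regimes or directional habitat
loss.

## Numerical choices

- Probabilities are clamped to [0, 1] after every composition; the
  critical-area comparison uses `≤`.
- Sigmoid/exponential overflow at extreme ages is suppressed and resolves
  to the correct clamped limit.
- Turnover count rounding is half-up (`floor(f·N + 0.5)`).
- Rejection sampling allows 5000 position attempts per patch before
  raising a placement error.
- The static-landscape fast path caches the distance matrix once per
  trajectory; dynamic landscapes recompute it after each turnover.
- CI bounds are clamped to [0, 1]; a single iteration yields NaN bounds
  plus a warning rather than a fabricated interval.

## Known limitations

- Equilibrium is operationalized as occupancy at step 100, not a formal
  stationarity diagnostic; slow transients (e.g. late-successional
  species in static landscapes still gaining patches) are reported as-is.
- The normal-approximation CI is slightly anticonservative for cells
  whose iteration distribution is a point mass at 0 with rare survivors;
  the bootstrap option covers that case.
- Landscape feasibility is parameter-dependent: very high cover with
  large minimum spacing fails placement by design rather than degrading
  silently.
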