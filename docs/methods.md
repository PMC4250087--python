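# Methods

## Model structure

The simulator couples three layers:

1. **World.** A rectangular grid of cells with static capitals in [0, 1].
   The default surfaces are deterministic gradients: crop productivity
   `crop(x, y) = f + (1 − f)·x/(W−1)` with floor `f = 0.05`, and natural
   capital `nat(x, y) = crop(x, y)·(0.5 + 0.5·y/(H−1))`. Both are maximised
   in the rightmost column, so the most productive land is contested by all
   types, while the vertical modulation of natural capital separates
   conservation-oriented occupancy towards the top of the arena. Capitals
   never change within a run. The coordinate convention is 0-based with `x`
   increasing rightwards and `y` upwards. The surfaces are configurable
   (`GradientSpec`) because only their qualitative shape, not their exact
   texture, is pinned down; see *Known limitations*.

2. **Agents and market.** Each agent functional type (AFT) has Cobb–Douglas
   sensitivities over both capitals and optimal productions per service
   (six tabulated presets: high/mid/low-intensity farmers in
   single-function and multifunctional versions, plus the conservationist).
   A single utilisation factor per type multiplies every service's optimal
   production, so each preset reproduces its tabulated output exactly at
   full capitals, and lower-intensity types (smaller exponents) hold an
   advantage on marginal land. Unmet demand is normalised per accounting
   scope to the dimensionless fraction `x = (D − S)/D` (0 when `D = 0`, the
   no-inducement convention), which puts the linear benefit gradient
   (`a = 3`), the thresholds (0–0.2) and the exponential form `e^x` on a
   common O(1) scale. Regionalised runs divide the same global demand
   equally over four quadrant regions and evaluate competitiveness with the
   cell's own region's unmet fractions; search remains arena-wide (demand is
   regionalised, movement is not).

3. **Engine.** Per timestep: market refresh at the current demand levels,
   an abandonment pass over occupied cells in randomised order (occupants
   vacate when competitiveness ≤ their abandonment threshold, with
   incremental market updates so later checks see the raised unmet demand),
   then interleaved round-robin search turns for all types in a randomised
   per-timestep order. Each search iteration samples `cells_per_search`
   distinct cells uniformly, ranks them by the searching type's
   competitiveness (ties broken by uniform random keys) and attempts
   takeovers in rank order until one succeeds. A takeover requires the cell
   to be unmanaged or the challenger to exceed the occupant's
   competitiveness by strictly more than the occupant's competition
   threshold, and the challenger's competitiveness to exceed its own
   freshly sampled abandonment threshold; the incoming agent's thresholds
   are sampled at creation and fixed for its lifetime. Markets update
   immediately on every change, which makes expansion self-limiting: as
   supply approaches demand, benefit falls and takeovers stop paying.
   Displaced and abandoning agents are discarded — the model tracks types,
   not persistent individuals.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| arena | 60 × 60 | cells | quadrant regions of 30 × 30 when regionalised |
| timesteps | 25 | years | demand change after timestep 11 in dynamic runs |
| realisations | 30 | – | seeds `base_seed + i` |
| search iterations | 5000 (100 in experiment 7) | per type per timestep | |
| cells per search | 10 | cells | sampled without replacement |
| benefit | linear, gradient 3.0 | utility per unit unmet fraction | exponential `e^x` in experiments 8, 12, 13, 19 |
| thresholds | 0.0 | utility units | 0.2 or N(0.2, 0.03) clamped at 0 where varied |
| recreation demand drop | 75% | of base | applied from timestep 12 onwards |
| calibration headroom | 0.02 | fraction | see below |

**Demand calibration.** The base demand per service is
`D = (1 + headroom)·mean(per-service supplies of the optimal allocation)`,
where the optimal allocation assigns each cell to the type with the largest
total production there (ties to the first-declared type). Because that
allocation maximises total production cell-by-cell, the summed demand `2 D`
exceeds the total supply achievable by *any* configuration by the headroom
factor — demands are almost, but never fully, satisfiable, keeping every
cell contested. With the default surfaces the per-cell argmax is the
high-intensity farmer everywhere (natural capital never exceeds crop
productivity), so the calibration is driven by the food-production
capacity of the arena.

## Randomness and determinism

One `numpy` generator per realisation, seeded `base_seed + index`, drives
initial placement, threshold draws, visit orders, cell sampling and
tie-breaks, in a fixed consumption order; a run is bit-reproducible from
its seed, and constant threshold specs consume no draws. Ranking ties use
random keys; takeover margins must be *strictly* greater than the
competition threshold, so zero-margin contests (e.g. same-type challenges)
always fail.

## Ensemble diagnostics

The steady-state detector follows the convergence notion used for the
experiment envelopes: the ensemble is steady at `t` when the
between-realisation standard deviation of supply exceeds the one-step
change of the ensemble mean for every service, required to persist for 3
consecutive timesteps to guard against single-step flukes. Zero-dispersion
(degenerate) ensembles never qualify. This criterion is deliberately
literal — dispersion exceeding drift — and is sensitive to large
inter-realisation variability; the stabilisation-time metric
(`stabilisation_time`, earliest timestep from which the land-use
composition stays within L1 distance 0.05 of its final value) is the
complementary, composition-based view. Because composition shares can sit
near their final values while the map still churns spatially, the latter is
a weak detector of slow spatial reorganisation; comparisons between
configurations should be read at the ensemble-mean level only.

Concentration of land use is summarised by the mean same-type neighbour
fraction over managed cells (von Neumann 4-neighbourhood, unmanaged cells
excluded from numerator and denominator, boundary cells using their
existing neighbours); capital-space occupancy by 2-D histograms of a type's
cells over (crop, natural) bins.

## What the synthetic arena does and does not emulate

The generated world reproduces the *structure* of the study system —
smooth capital gradients, co-located maxima, equal quadrant regions, equal
static demands with a single step change — not any real geography. Passing
tests therefore demonstrate the mechanics of threshold-mediated competition
and demand accounting, not predictions for real land systems: there is no
spatial texture or noise in the capitals, no capital dynamics, no
conversion costs, no prices or inter-regional trade, and thresholds are not
linked to named real-world behaviours.

## Numerical choices and degenerate inputs

Supply is maintained incrementally (O(1) per allocation change) and
verified against from-scratch recomputation to 1e−9. `0^0 = 1` in the
utilisation factor, so zero sensitivity means indifference. `D = 0` maps to
unmet fraction 0 rather than ±∞. Gaussian threshold draws are clamped at 0
(with mean 0.2, sd 0.03 the clamp is vanishingly rare). Width- or
height-1 arenas degenerate to the gradient ceiling. Empty ensembles,
non-divisible region grids and out-of-range capitals raise errors rather
than being silently corrected.

## Scale used in the shipped checks

The ensemble-level checks in the test suite run at a reduced scale chosen
to preserve the relative search effort of the full setup (20×20 arena, 500
search iterations, 25 timesteps, 10 realisations; experiment 7 keeps its
defining 100 iterations). The full-scale configuration (60×60, 5000
iterations, 30 realisations) runs at roughly 15 s per realisation per
experiment variant on one CPU.

## Known limitations

- The exact spatial texture of the natural-capital surface is not
  recoverable from its published depiction; only "maximised on the right"
  is certain. The default vertical modulation keeps natural capital at or
  below crop productivity everywhere (arena total 0.75× crop), which makes
  recreation capacity structurally tighter than food capacity. Two
  consequences observed in the shipped checks: lower-intensity farmer
  types retain a stable marginal-land niche under globalised demand rather
  than being fully eliminated (no competitor can post a positive takeover
  margin against them where crop capital < 0.25), and under exponential
  utilities with static globalised demand the competitive equilibrium
  commits too little land to recreation to over-supply it. Alternative
  surfaces can be explored through `GradientSpec`.
- Displaced agents are discarded rather than re-entering a relocation
  pool; search is arena-wide in regionalised runs. Both are configurable
  points of departure for sensitivity analyses rather than claims about
  land-manager behaviour.
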