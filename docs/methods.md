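# Methods

## Scope and phenotype axis

floralscape models selection on a single quantitative floral trait exerted
by a guild of pollinator functional types within one selective episode.  The
phenotype axis is dimensionless and normalised to [0, 1]; the two canonical
visitor optima are placed at 0.25 (bee) and 0.75 (hummingbird).  Fixed
placements make every example and test reproducible; rescaling to a real
trait (e.g. tube length in mm) is a linear change of variable that affects
nothing but axis labels.

## Visitor-specific fitness curves

Each visitor type contributes three ingredients:

| quantity | symbol | units | canonical default |
|---|---|---|---|
| attraction | a(z) | visitation-probability weight in [0, 1] | 0.9 at own optimum, 0.1 at the other's |
| removal | r(z) | pollen grains per visit | 10 000 at own optimum, 2 500 at the other's |
| transfer efficiency | e | fraction of removed grains deposited | 0.02 (bee), 0.04 (hummingbird) |

Curves are Gaussian, flat, or tabulated (linear interpolation between
strictly increasing knots, clamped to the endpoint values outside them).
The schematic curves of the conceptual figures are not stated to be any
particular family; the Gaussian/flat/tabulated set is this package's
modelling choice, with tabulated curves as the escape hatch for arbitrary
shapes.

A Gaussian specified by its value at two points (its own optimum and a
reference point, typically the other visitor's optimum) has the closed-form
width `w = |z_ref − z_opt| / sqrt(2 ln(v_opt / v_ref))`.  Equal values at
the two points are rejected as a degenerate calibration (infinite width):
a constant contribution must be requested explicitly as a flat curve.

## Landscape diagnostics

`summarize_landscape` works on an even grid.  Local optima are grid points
whose value exceeds both neighbours; a plateau of exactly equal values that
stands above its neighbours is reported once, at its lowest phenotype, and
a grid endpoint strictly above its single neighbour counts as a local
optimum (so a monotone landscape still reports its boundary maximum, and
the global optimum is always a member of the local optima unless the
landscape is flat).  A landscape is *flat* when its total range is within
1e−12 (relative) of its maximum — a pure floating-point guard.
`valley_depth` is the global maximum minus the highest of the minima
separating consecutive local optima; `steepness` is the maximum
|Δvalue/Δphenotype| over adjacent grid points, which for a Gaussian
converges to `peak · e^{−1/2} / width` as the grid refines.  Ties for the
global optimum, and ties in `nearest_contributor`, resolve toward the
lowest phenotype / the visitor listed first, so outputs are deterministic.

`combine_components` joins female (seed set) and male (pollen export)
fitness components either as a sum (default — total reproductive output
through two pathways) or as a product (a zero in either component zeroes
total fitness).  Both are exposed by name because either reading is
defensible; no silent choice is made.

## The visit simulator

One iteration executes exactly `total_visits` (default 3 500) sequential
visit events on a population of `n_flowers` (default 100) with equal pollen
budgets (default 160 000 grains).  Each event draws a visitor type from the
abundance mixture, then a target flower with probability proportional to
that visitor's attraction at each flower's phenotype, removes
`min(r(z), remaining)` grains, and credits `e ×` removed grains to the
flower's pollen export; the remainder leaves the system (no stigma-side
deposition, carryover chains, or selfing are modelled).  Design choices
worth stating:

- **Fixed visit total, per-event randomness.** The visit schedule is a
  multinomial allocation realised sequentially, so depletion can act
  between events while the total stays fixed.
- **Attraction ignores depletion.** Running out of pollen caps removal but
  does not make a flower less attractive; empty flowers may still be
  visited and yield nothing.  The opportunity trade-off emerges from the
  fixed visit total and the shared pollen pool alone.
- **Seeding.** Iteration *i* of a run uses an independent stream seeded
  `seed + i`; the additive baseline's single-visitor runs offset their
  seeds by `10 000 × visitor index`.  Identical configurations and seeds
  reproduce results bit for bit.  Categorical draws use inverse-CDF
  sampling on `rng.random()` blocks so that a degenerate mixture (1, 0)
  consumes the same stream as a single-visitor guild and matches it
  exactly.
- **Budget cap is exact.** Per-flower depletion is computed as a capped
  cumulative sum; a few ulps of floating-point overshoot from re-summing
  per-visitor shares are pushed back so removal never exceeds the budget.

The **additive baseline** simulates each visitor alone (same schedule,
independent seeds) and sums the per-flower means.  Its removal can exceed
the physical budget — deliberately: that unrealism is what the comparison
with the interactive model is for.

### Binning and smoothing

Per-flower iteration means are grouped into `n_bins` equal-width phenotype
bins (default 20) and smoothed with a local mean over bin centres within
`bandwidth × axis length` (default 0.15).  The plotted-curve smoothing of
the original figures is unstated; a boxcar local mean is the simplest
method that preserves constants, and both knobs are recorded in run
metadata.  Empty bins are recorded as missing and skipped.  Optima of
smoothed landscapes are reported at bin centres, ties toward the lowest
phenotype.

## Temporal aggregation

`TemporalSeries` holds weighted epochs (weights normalised on construction,
so unequal year lengths or frequencies are expressible).  The geometric
mean landscape is `exp(Σ wᵢ ln fᵢ(z))`, defined as exactly 0 wherever any
positively weighted epoch is 0 (the limit convention, avoiding `ln 0`).
The arithmetic mean is provided purely as the comparison baseline; the
AM–GM inequality and the zero-sensitivity of the geometric mean are the
properties the tests pin down.

## What the synthetic data does and does not show

The fixture generator draws guilds (optima, peaks, cross-values,
efficiencies) uniformly from stated ranges, with the canonical
bee/hummingbird guild reserved as fixture 0.  All inputs are synthetic:
passing tests demonstrate the internal consistency of the model — its
conservation laws, determinism, and the qualitative landscape phenomena
(flattened mixed-guild visitation and removal, unphysical additive removal,
the export optimum displaced beyond the better vector's peak, the
geometric-mean penalty on unreliable visitors).  They do not validate the
model against field data: real visitation is overdispersed, attraction and
rewards feed back on each other, pollen deposition is not a fixed fraction
of removal, and real phenotype distributions are neither uniform nor fixed.

## Problem sizes

Tests and the acceptance script use the canonical run sizes (100 flowers,
3 500 visits, 10 iterations, 10 seeded replicates; 10 001-point grids for
brute-force landscape checks, 100 001 points for the steepness
convergence check).  A full replicate suite runs in a few seconds on one
core.

## Known limitations

- Single trait; no multivariate landscapes or correlated selection.
- One selective episode; no evolutionary dynamics across generations.
- Export is credited at removal; recipient-side pollen fate is out of scope.
- The smoothing and the visit-sampling unit of the original model are
  under-specified; the conventions above are explicit choices, configurable
  where they matter.
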