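# Methods

## The analysis

The pipeline assigns each census tract a daily boolean for three
heat-related hazards, combines them into coexposure flags, and
summarises the result as tract-day and person-day rates, monthly and
annual distributions, Mann-Kendall trends, and sociodemographic
disparity tables. A tract-day exposed to several hazards contributes
one day to each hazard's metric and one to their coexposure metric; no
deduplication is applied, so single-hazard and coexposure accounts can
be read side by side.

### Extreme heat

A tract-day is extreme heat when its daily maximum temperature is at or
above both thresholds:

* **relative**: the 95th percentile (linear interpolation between order
  statistics, the numpy default) of the tract's warm-season (May 1 to
  Sep 30) daily maxima over a baseline of the first five study years
  (fewer if the study window is shorter) — this encodes local
  acclimatisation;
* **absolute**: 32.22 °C (90 °F) — this prevents implausibly low
  cut-offs in cool climates.

Both comparisons are inclusive ("equaled or exceeded"). Classification
runs on every calendar day; only the threshold derivation is restricted
to the warm season, and the dual threshold makes winter flags
effectively impossible. The share of tracts whose relative threshold
falls below the absolute one is reported alongside the thresholds — in
warm study regions most tracts sit above it.

### Wildfire burn zones and smoke

A burn-zone tract-day has at least one active-fire point inside the
tract (closed polygon containment; a boundary point is assigned to the
lowest tract id so counts are conserved; points outside every tract are
tallied as unassigned, never dropped silently). A smoke tract-day has
wildfire-specific PM2.5 strictly above the threshold — `> 0 µg/m³` by
default, `> 5 µg/m³` as the sensitivity setting, so raising the
threshold can only shrink the flag set.

### Coexposure windows

Same-day coexposure is the elementwise AND of the hazard flags. The
2-day window pairs events on the same or adjacent days; by default both
participating days are flagged (one EH day next to one WFBZ day yields
two coexposure tract-days). The written definition of the window is
one-sided and does not fix this choice, so the alternative — crediting
only the later day — is available as `credit="later"`. The triple
combination under the 2-day window requires all three pairwise
conditions on the day, which implies at least one hazard is active
then and keeps the triple a subset of every pair.

### Exposure metrics

Seven quantities (see README for formulas): region and state annual
tract-day totals, per-tract annual averages, and their person-day
analogues with `PDE_i = P_i × E_i` under the assumption that a hazard
in a tract exposes its whole population. `E_y` in the annual total is
the sum over all tracts of exposure days in year `y` (the quantity
reported is region-wide). Reported tables round per-tract averages to
one decimal and totals to integers; raw values are retained in the
tidy output.

### Trend testing

The classical Mann-Kendall test, implemented from the definition:
`S = Σ_{i<j} sgn(x_j − x_i)`, tie-corrected variance
`[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`, continuity-corrected normal
deviate, two-sided p. No seasonal or autocorrelation-corrected variant
is applied. Correctness is checked two independent ways: an exhaustive
permutation test (exact null distribution of |S|) for n ≤ 7, and the
empirical false-positive rate on i.i.d. Gaussian series. Series
shorter than 10 years carry a small-sample caution flag; p-values from
~15-year series should be read as indicative only.

### Disparity summaries

Quintile breaks are the 20/40/60/80th percentiles of the unweighted
tract exposure-day distribution over populated tracts (a
population-weighted option exists); a tract equal to a break falls in
the lower quintile, and identical exposures everywhere raise a
degenerate-bins error directing users to manual categories. Group
percentages weight tracts by `P_i × share_g` with fractional persons
kept. Manual day-count categories (default `[0], [1–2], [3–5], [6–10],
[≥11]` days — a configurable convention chosen for skewed, zero-heavy
burn-zone exposures) serve distributions where quintiles are
uninformative. The SVI overlay flags tracts with SVI strictly above
0.9 and at least one exposure day. The tribal-land comparison restricts
to tracts with ≥ 1 burn-zone day before comparing mean days on and off
tribal-overlap tracts. Top-N tables report the most-exposed tracts
with age/disability/poverty percentages and non-white percent computed
as 100 − NH-white%.

## Spatial aggregation

Grid-to-tract aggregation is the area-weighted mean of intersecting
cell values. The aggregation method for gridded inputs is a
documented package choice (the standard zonal statistic); weights are
intersection areas on an equal-area representation — a sinusoidal
projection for geographic (EPSG:4326) inputs, identity for the planar
CRS used by toy fixtures — normalised within each tract. A tract with
zero intersecting area is an error, not a silent NaN. Temperature
inputs declaring K or °F units are converted to °C on read.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the physics behind it:

* **Tracts**: an `n × n` lattice of square polygons (chosen over
  realistic polygons so zonal means are exactly hand-checkable),
  partitioned into contiguous pseudo-states, with Poisson populations
  around 4000 (the census design size), Dirichlet race/ethnicity shares
  centred on the Western-US mix (~30% Hispanic, ~50% NH white, 1.1% NH
  AIAN), poverty/age/disability percentages around national figures,
  and a small fraction (0.3%) of zero-population tracts whose SVI is
  missing. SVI is the percentile rank `(rank−1)/(n−1)` of a latent
  vulnerability score correlated with poverty and disability, ranked
  over populated tracts only.
* **Temperature**: a seasonal sinusoid peaking July 15 (default base
  14 °C, amplitude 20 °C, so typical warm-season maxima straddle the
  32.22 °C absolute threshold as they do across the Western US) plus
  i.i.d. Gaussian noise (2.5 °C), plus planted heat events — Poisson
  per tract-summer (2 expected), 1–5 consecutive days, +6 °C by
  default. Every planted day is recorded in a truth ledger.
* **Fires and smoke**: Poisson ignitions per tract-year (0.8 expected),
  85% of the mass in June–September, burning 1–7 consecutive days with
  ≥ 1 fire point inside the tract each burn day. Smoke on burn days is
  a source amplitude (20 µg/m³) decayed multiplicatively (0.5 per tract
  of Chebyshev distance) out to a plume radius of 2 tracts —
  deliberately simple, but it reproduces the key phenomenon that smoke
  reaches tracts the burn zone never touches — plus a zero-inflated
  exponential background (nonzero on 5% of tract-days, mean 1 µg/m³).
* **Determinism**: one RNG stream is derived from the seed and consumed
  in a fixed order (tracts → temperature → fires/smoke); identical
  config and seed reproduce the bundle bit for bit. The calendar is
  ISO-8601 daily with leap days.

`grid_cells_per_tract` is the grid refinement per tract *side* (k²
cells per tract), keeping the temperature/smoke grid rectilinear.

What the generator does **not** emulate: real meteorology or spatial
temperature gradients, fire spread and persistence across tracts,
smoke advection and chemistry, population growth, or realistic tract
geometry. Passing tests therefore demonstrate that the pipeline's
logic — thresholds, windows, aggregation, formulas, rankings — is
correct, not that any particular real-world exposure estimate is
reproduced.

## Numerical choices and degenerate inputs

* Percentiles use linear interpolation throughout (thresholds and
  quintile breaks).
* Boolean comparisons: inclusive (≥) for both heat thresholds, strict
  (>) for smoke and for the SVI cut.
* Boundary fire points: closed containment, ties to the lowest
  tract id; conservation (Σ counts + unassigned = points) holds per
  date by construction.
* 2-day windows at series boundaries use only existing neighbours.
* Mann-Kendall needs n ≥ 3; the pipeline's trend stage marks shorter
  series `insufficient_years` instead of failing, so short demo runs
  still emit a complete trend table.
* Empty flag matrices produce an all-zero monthly distribution with a
  warning rather than 0/0.

## Problem sizes

The shipped test and acceptance configurations use lattices of 16–64
tracts and 2–15 simulated years — large enough for every structural
property (conservation, nesting, recovery of planted events, type-I
error of the trend test at 2000 replicates) while keeping full runs in
seconds. Paper-scale inputs (tens of thousands of tracts) stream
through the same code paths; nothing in the implementation is
specialised to the small sizes.

## Known limitations

* Coexposure is counted in tract-day units; event durations and
  overlapping spells are not modelled.
* Prescribed burns and wildfires are not distinguished in fire-point
  inputs.
* The disparity analyses are descriptive; no inferential statistics
  are attached to composition differences.
* Zonal aggregation supports rectilinear grids only; reprojection or
  resampling of rasters is out of scope.
* The sinusoidal equal-area transform is exact for area ratios on the
  sphere but ignores ellipsoidal corrections (< 0.7% in area), which is
  immaterial for normalised zonal weights at tract scale.
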