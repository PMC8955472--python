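# Methods

This note records the modeling choices behind `aedesrisk`: the
establishment response, the predictor definitions, the ensemble and its
assessment, the mapping stage, and what the synthetic-data generator
does and does not emulate.

## Establishment response

Ovitrap slats are exposed for two weeks; the season holds ten biweekly
periods anchored at ISO week 20 (period `p` covers weeks `20+2(p−1)` and
`21+2(p−1)`; dates outside weeks 20–39 never produce labels). A slat is
positive when *Ae. albopictus* eggs are found; when an egg count is
recorded it is authoritative (`egg_count > 0`), otherwise the boolean
flag is.

A trap-year is **established** when some run of consecutive positive
analyzed slats spans at least 28 days from first to last positive.
Decisions embedded in that sentence:

* **≥ vs >.** The 28-day window exists to accommodate alternate-round
  analysis (slats analyzed every 28 days), under which two consecutive
  positives span exactly 28 days. A strict `>` would make that regime
  unable to ever establish with two positives, so the default comparator
  is `≥`, with `strict=True` available.
* **"Consecutive".** Adjacent in the date-ordered sequence of *analyzed*
  slats, regardless of calendar gap. Unanalyzed slats are invisible; an
  analyzed negative breaks the run. Without this reading,
  alternate-round data could never form a run at all. Whether the
  original coding treated an intervening unanalyzed period the same way
  is unknowable from the published description; both behaviors are
  exercised in tests.

A cell-year is established when at least one of its traps is, and is
*observed* (labeled at all) when at least one trap in the cell analyzed
at least one slat that year. Traps bin to cells by half-open intervals
anchored at the grid origin; a trap exactly on a boundary belongs to the
greater-index cell.

## Predictors (79)

| group | n | definition |
|---|---|---|
| terrain | 3 | elevation (m a.s.l.), aspect (deg), slope (deg) |
| land cover | 32 | CORINE level-3 class fractions `clc111`…`clc512`, each in [0,1] |
| population | 1 | resident count per cell, one static snapshot for all years |
| seasonal weather | 36 | per season × series: mean + percentiles 5/25/75/95 (RAIN: mean/75/95 only) |
| biweekly extremes | 6 | extreme 14-day spells of Tmin, Tmax, warm-season RAIN |
| dispersal | 1 | car distance to establishment (min) |

* **Seasons.** Warm season of year *y*: May 1 – Sep 30 of *y* (the
  reproductive season). Cold season: Dec 1 of *y−1* – end of February of
  *y* (Feb 29 in leap years) — the coldest stretch diapausing eggs must
  survive. Weather coverage therefore always starts the December before
  the first modeled year; the generator enforces this rather than
  silently truncating.
* **Percentile rule.** Linear interpolation between closest order
  statistics (the "type 7" convention, numpy's default). Any monotone
  rule changes values by O(1/n) over ~90–153-day seasons; the choice is
  centralized in one function so it can be swapped.
* **Biweekly windows** slide with a 1-day step; temperature windows
  range over the calendar year (full windows only, no wrap across Dec
  31), RAIN windows lie wholly inside the warm season. The RAIN p5/p25
  seasonal percentiles are omitted because daily rainfall is zero on
  most days, making them identically zero.
* **Aspect** is passed through linearly in degrees with no circular
  encoding, mirroring a raw-grid predictor; a north-facing slope (355°)
  and a near-identical one (5°) thus get distant values. Known
  limitation.
* **Met-grid lookup.** Each 200 m cell inherits the weather of the
  coarser met-cell containing its centroid (1 km emulated as 5×5 model
  cells).
* **Car distance.** For cell *c* in year *y*: the minimum over all cells
  established in *y−1* of the travel time (minutes) into *c*. The
  contract is directional (min over sources of time(source→cell));
  the synthetic grid provider is symmetric so direction is moot there.
  An empty prior-year set is a hard error unless the caller explicitly
  supplies a fallback layer — for extrapolation regions without
  surveillance history, a constant 0.5 min (30 s) layer encodes "assume
  establishment has already occurred nearby", and a point-seeded layer
  serves areas with a few known occurrence points.

## Normalization

Min–max scaling to [0, 1], bounds recorded from the training subset.
Features constant in training map to 0 (they are kept, not dropped —
selection is the penalty's job). Values outside the training range are
*not* clipped, so extrapolated inputs may map outside [0, 1]. Bounds are
fit **per member** on that member's seven-year training subset — the
most defensible reading of a leave-one-year-out protocol — with a
global-bounds switch for sensitivity checks.

## Ensemble

Members are scikit-learn `LogisticRegression` fits with a pure L1
penalty (`l1_ratio=1.0`) at inverse penalty strength `C = 0.1`, solver
`saga` (tolerance 1e-8, generous iteration cap, fixed `random_state`;
all recorded in the model manifest). `saga` is used precisely because it
leaves the intercept unpenalized; in the `C → 0⁺` limit all slopes
vanish and the intercept approaches the logit of the training
prevalence (the solver's tiny-step stopping rule leaves a residual of a
few hundredths on the probability scale at realistic n). Note the
convention: *smaller* C = *stronger* penalty.

One member per training year, each fit on the other years' data; a
member's fit is invariant to the content of its excluded year (tested).
Ensemble prediction = arithmetic mean of member probabilities;
uncertainty = their **population** standard deviation (divide by the
member count — with eight fixed members there is no sampling correction
to make). "Non-zero" coefficients use an explicit 1e-6 tolerance on the
normalized scale, since coordinate-style solvers only approximately
return exact zeros at loose tolerances.

## Assessment

AUC is the Mann–Whitney rank estimate with half credit for ties,
computed via `sklearn.metrics.roc_auc_score` and cross-checked in tests
against O(n²) pair counting. Cross-validation scores each member on its
own left-out year; a year is evaluable iff it has at least
`min_established = 5` established cells and one non-established cell.
The published protocol excluded years with 0 and 3 established cells and
retained one with 16, so any threshold in (3, 16] reproduces the
pattern; 5 is the default and is exposed as configuration. Test-year
assessment reports each member's AUC, their mean/SD, and the AUC of the
ensemble-mean prediction (average first, then one AUC); single-class
years are flagged, not scored.

## Mapping

For each weather-scenario year the full feature matrix is rebuilt (that
year's meteorology, the static layers, a caller-chosen dispersal layer)
and every member predicts, giving members × scenarios probabilities per
cell. Yearly mean maps average over members within a scenario; the
summary map averages the whole stack; SD maps use the population
convention on the corresponding set. All SD maps produced in one run are
normalized **jointly** by the single global maximum SD (recorded in the
raster metadata), so the most uncertain cell in the run reads exactly
1.0 and maps share one scale; comparing across runs requires passing an
explicit divisor. No-data cells are NaN, excluded from the divisor.

Rasters are ESRI ASCII grids — a plain-text, widely readable format with
georeferencing in the header — plus a JSON sidecar carrying the CRS
label and metadata; round-trips preserve values to 32-bit float
precision. Rows are stored north-to-south per the format and flipped
back on read.

## Synthetic world

The generator emulates the statistical structure the analysis assumes,
at a desk scale (default 40×40 cells of 200 m, eleven years, 400 traps):

* **Landscape.** Elevation = north-increasing ramp + smoothed Gaussian
  field (≈200–1500 m); slope/aspect from its gradient. Land cover:
  per-cell Dirichlet fractions over the 32 classes with urban classes
  (clc111/112/121) up-weighted at low elevation. Population: log-normal
  scaled by the urban fraction.
* **Weather.** Tmean = seasonal cosine (base 11 °C, amplitude 9 °C, peak
  ~July 19) − 6.5 °C/km lapse × met-cell elevation + AR(1) noise
  (sd 2 °C, ρ 0.7); Tmin/Tmax subtract/add positive gamma spreads; RAIN
  is zero-inflated gamma (35 % wet days) whose scale rises west→east by
  ±40 % — a persistent spatial wetness gradient, as real precipitation
  climatologies have.
* **Travel.** 4-connected grid graph with per-edge minutes drawn once,
  uniform 0.2–1.0 min per 200 m hop; shortest paths via Dijkstra. Chosen
  so a brute-force oracle is feasible.
* **Truth process.** Year 1 seeds the lowest-elevation cell of each of
  five column bands (an invasion entering at several points along the
  warm edge). Thereafter each non-established cell becomes established
  with probability `σ(−1.5 + Σ βⱼ·x̃ⱼ)` on per-year min–max-normalized
  features, with true support elevation −4, car distance −6, clc112 +3,
  clc121 −3, clc142 +3; establishment is absorbing. Traps (a fixed
  random subset of cells; per-year activation lists and an
  alternate-round mode are available) emit one slat per biweekly period,
  positive with probability 0.85 in truly established cell-years and
  0.02 otherwise — rates at which the 28-day rule recovers the truth in
  trap cells with high probability, while three consecutive
  false-positive slats are vanishingly rare.

The truth support was designed for identifiability, which the
cumulative-presence response makes non-trivial: a recoverable true
effect must (a) vary persistently in space — the label integrates
hazards over years, so purely transient weather noise leaves no
footprint; (b) not sit inside a tightly correlated feature group — LASSO
keeps one representative per group (the rain statistics correlate at
r ≈ 0.9, so a rain-borne effect is recovered under an arbitrary sibling
name, exactly the group-selection behavior seen on real data); and
(c) keep a well-spread distribution after min–max scaling — a feature
compressed by outliers (slope, population) carries almost no effect per
normalized unit. Land-cover fractions are mutually independent by
construction, which is why three of the five true effects live there.

What the generator does **not** emulate: real topography or
climatology, trap-density gradients that follow human settlement, the
multi-species egg-identification problem, imperfect trap servicing, and
calibration to any real invasion curve. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the
inference recovers a known process under favorable signal-to-noise —
not that the specific coefficient estimates transfer to any real region.

## Problem sizes and numerics

The default study — 1600 cells × 10 modeled years (12 800 cell-years,
8 train years), 79 features, 8 members — fits in well under a minute per
ensemble; tests and the acceptance script use this scale, with 20×20
worlds for unit tests. Degenerate inputs are handled explicitly:
1×N grids get flat terrain (no finite-difference gradient), single-class
training subsets and empty prior-establishment sets are hard errors
naming the cause, all-zero uncertainty stacks normalize to zero with a
reported divisor of 0, and ties in AUC take half credit. All randomness
flows from a single integer seed through named SeedSequence streams, so
every artifact is bit-reproducible.
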