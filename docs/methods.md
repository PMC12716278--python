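# Methods

## Survival model

Cohort survival after `t` hours of exposure at temperature `T` (degC) is
modelled as logistic in the degree-hour dose below a threshold:

    logit S(t, T) = a + b · t · (T − c)

`a` (dimensionless) is the logit of survival with no cold exposure, i.e. it
absorbs handling and background mortality; `b` (> 0, per hour·degC) is the
rate at which injury accrues per degree-hour below the threshold; `c` (degC)
is the ULCIZ, the warmest temperature at which chill injury accumulates.
Two derived metrics summarise cold tolerance: SIT = a/b (degree-hours; the
dose that halves survival, equal to the LT50 exposure time one degree below
the ULCIZ) and the LT50 time at any `T < c`, `−a / (b·(T − c))`.

Evaluation is always on the logit scale with the linear predictor clipped to
±700, and the returned probability clipped into the open unit interval, so
downstream logits of predicted survival never overflow.

### Fitting

`ChillInjuryModel.fit()` minimises the (optionally weighted) sum of squared
differences between observed and predicted cell survival with
`scipy.optimize.least_squares` (Levenberg–Marquardt). The objective is
non-convex in `c`, so a deterministic multi-start grid is used: `c` over the
observed temperature range plus 10 degC headroom in 2 degC steps, `b` over
{1e-4, 1e-3, 1e-2, 1e-1}, and `a` started at the logit of the
best-condition survival. The lowest SSE wins; exact ties go to the smaller
|b|. Standard errors are the usual asymptotic ones from the Jacobian at the
optimum with variance SSE/(n−3).

Two weighting modes exist because replicate-level data are rarely published:
`cells` (each cell mean weighted equally; identical to replicate-level least
squares when the design is balanced) and `counts` (cells weighted by number
of individuals; the default). Degenerate inputs — fewer than 4 cells, fewer
than 2 distinct temperatures or exposure times, all-alive or all-dead
tables — are rejected outright.

A caveat documented by the tests: the packaged thrips table's printed cell
means do not reproduce that species' published parameter triple under any
least-squares weighting we tried (the published optimum has a *worse*
cell-mean SSE than ours, and the table's "0 ± 0.001" entries suggest the
printed means are model-adjusted rather than raw). The corresponding refit
check is therefore expected to fail while the beetle-table refit passes;
both refits are reported as computed.

## Mortality accumulation

For a temperature series with resolution `x` hours per record, each record
at `T_i ≤ c` advances the recursion via the equivalent-exposure-time form

    t_i = [logit(S_{i−1}) − a] / [b (T_i − c)] + x,   S_i = S(t_i, T_i),

implemented internally as the algebraically identical logit decrement
`logit(S_i) = logit(S_{i−1}) + b·x·(T_i − c)`. Consequences that the tests
exploit as oracles: constant-temperature runs reproduce the survival
surface exactly; the final survival has the closed form
`logit(S_N) = a + b·x·Σ_{T_i≤c}(T_i − c)`; and cumulative mortality is
order-invariant and telescopes to `S_0 − S_N` with `S_0 = expit(a)`.

Numerical choices: records with `T_i > c` leave survival untouched (no
recovery between chill events — a deliberate, conservative assumption that
overestimates mortality if real populations recover); `T_i = c` is an
injurious-boundary no-op, with the audit `t_i` reported as missing to avoid
the division by zero in the time form; survival is floored at 1e-12 before
any logit so the recursion stays finite once mortality saturates (this
floor, not 1, is the effective mortality ceiling: cumulative mortality can
never exceed `expit(a)`). Gaps in the record contribute neither injury nor
time.

Monthly cumulative mortality resets survival to `S_0` at each calendar-month
boundary — one month approximates one generation, so each month's figure is
the winter kill a single cohort would experience. A month with fewer than
75% (configurable) of its expected records is reported missing. The *peak
winter mortality* of a July–June winter year is the maximum over its
reportable months, ties to the earliest.

## Station processing

Canonical input is a long CSV (`station_id,timestamp,temp_c`); rows are
sorted, duplicate timestamps collapsed by mean, and the resolution inferred
as the modal spacing. An ASOS one-minute (DSI-6405-style) adapter
best-effort-parses station id and local timestamp from the leading token and
takes the dry-bulb temperature (degF) as the second-to-last numeric field,
skipping unparseable lines and rejecting files where they exceed half; the
packaged 10-line sample is synthetic, with hand-converted temperatures.

Winter years run July 1–June 30 so a winter never straddles files. Station
QC keeps stations inside a configurable contiguous-US bounding box (default
lat 24–50, lon −125 to −66; a box, since no geometry is published) with at
least 10 winter years each missing no more than 25% of their pooled
October–April records (the pooled reading of an ambiguous rule; a per-month
variant would be stricter). "10 years" counts QC-passing winters, not
calendar span. Station summaries are the arithmetic mean and sample SD
(n−1) of annual peaks.

## Spatial interpolation and suitability

Distances are great-circle (haversine, R = 6371.0088 km). The empirical
semivariogram is the Matheron estimator on equal-width bins up to half the
maximum pairwise distance (extended to the full maximum only when nothing
would otherwise fall inside, e.g. a single pair); a spherical model
γ(h) = nugget + psill·(1.5 h/r − 0.5 (h/r)³) is fitted by least squares
weighted by pair counts, with non-negativity bounds and a pure-nugget
fallback. Ordinary kriging predicts each grid cell from its 12 nearest
stations (the GIS reading of a "variable search radius of 12 points"),
solving the standard OK system with the unbiasedness row so weights sum to
one; singular systems get one 1e-10 diagonal jitter retry, then the cell is
flagged missing. Predictions are clipped to [0, 1]. A dense all-station
solve is available and doubles as the test oracle for the neighbourhood
path. The grid is a plain lat/lon lattice (default 0.25 deg) over the
station bounding box, with no land/water mask.

Predicted mortality maps to five suitability classes as a half-open
partition keeping the published lower anchors — [0, 0.25] highly suitable,
(0.25, 0.50] moderately suitable, (0.50, 0.75] moderately unsuitable,
(0.75, 0.95] highly unsuitable, (0.95, 1] completely unsuitable — because
the bins as published contain printer's gaps and overlaps and a classifier
must partition. Occurrence thinning is a deterministic greedy scan in
ascending record id, keeping a point iff it is ≥ 15 km (default) from every
point already kept. Extraction assigns each occurrence its nearest predicted
cell (within one cell diagonal) and reports percentages per class and for
the combined suitable (highly + moderately) grouping.

## Retrospective regression

Per program year, peak mortality of the preceding winter is computed at the
collection site from the nearest station with adequate data (a kriged
surface per year is the published approach; nearest-station is the testable
default) and regressed by OLS against the spring collection count. The
predictor is mortality in *percent*, so the slope reads as insects lost per
percentage-point of predicted winter mortality — documented to prevent
silent 100-fold slope mismatches. The assay tables' dose-response check is
a binomial GLM (logit link) of cell mortality on exposure hours and negated
temperature, weighted by individuals per cell.

## Synthetic data

Every pipeline input has a seeded generator: binomial assay outcomes at any
(T, t, n) design including the two packaged designs (33-cell incomplete
cross at n=50; complete 4×5 cross at n=68, the study total spread evenly
since per-cell replication was unpublished); temperature series as annual
plus diurnal sinusoids with AR(1) noise and scheduled cold snaps; a station
network whose annual mean cools with latitude (defaults: 20 degC at the
southern edge, −1.5 degC per degree latitude, 12 degC annual and 4 degC
diurnal amplitude, AR(1) sd 1.5, hourly resolution, ≥ 11 winter years so QC
passes); and clustered occurrence points. Generators are pure functions of
(parameters, seed). The default scenario puts a Gulf-Coast-like station
near zero beetle mortality while temperate stations approach the mortality
ceiling for the beetle but not the thrips, mirroring the qualitative
contrast between the two agents.

What the generators do *not* emulate: spatially correlated weather between
stations, real climatological extremes and inversions, observation error in
temperatures, or occurrence sampling bias. Passing tests therefore
demonstrate correctness of the estimation and accounting machinery under
the stated model, not climatological realism.

## Problem sizes and determinism

The test suite runs the full synthetic pipeline at desk scale: a 9-station
network with 11 hourly winter years, 200-point thinning instances, and 200
replicate assay simulations for parameter recovery (median ULCIZ error is
~0.15 degC at the packaged design, comfortably under the 1 degC check).
Every stochastic test and generator takes an explicit seed; the acceptance
script's quantities are all deterministic recomputations from the packaged
tables.

## Known limitations

- No recovery or repair between chill events; mortality is over-predicted
  where intermittent warming allows recovery.
- Single life stage; no acclimation, photoperiod or developmental-threshold
  effects.
- Cumulative mortality is capped at `expit(a)`: the model cannot predict
  kills beyond its own handling-survival intercept.
- The bounding-box "contiguous US" filter and the pooled Oct–Apr
  completeness rule are pragmatic readings of loosely specified screening
  rules.
- Kriging is not intended to reproduce any particular GIS product
  numerically; only its defining properties (exactness, unbiasedness
  weights) are guaranteed.
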