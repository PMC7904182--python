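# Methods

## Quantification model

All intensity measurements are ratios of *unit intensities* (summed pixel
signal divided by pixel count) between a target region and a nearby
background region, taken on raw images. This makes the measurements
invariant to multiplicative gain (exposure, illumination) but **not** to
additive offsets — adding a constant to an image changes the ratios. That
matches the convention of reporting raw relative intensities rather than
background-subtracted ones; users with significant camera offset should
subtract it before quantification.

A pixel belongs to a polygon ROI iff its **center** lies inside under the
even-odd (crossing-number) rule; a center exactly on an edge counts as
inside. Coordinates are 0-based `(row, col)` with pixel centers at integer
positions. This rule is implemented directly (not delegated to a drawing
library) because it defines every downstream quantity, and the test
oracle — an independent per-pixel point-in-polygon loop — applies the same
stated rule. The annulus ("donut") measurement subtracts the inner
polygon's total and area from the outer's; annuli whose inner polygon is
not strictly contained in the outer are rejected rather than clipped.
Polygon simplicity and containment are validated with shapely.

For quantifying rendered circular rings, `ring_annulus` builds the inner
polygon *circumscribing* the inner circle and the outer polygon *inscribed*
in the outer circle. Every selected pixel then lies inside the true ring:
boundary pixels carrying non-ring signal are excluded instead of being
diluted into the measurement, which is why the render → quantify round
trip is exact at zero noise rather than merely within a rasterization
tolerance.

The background-region helper builds a disk of area matched to the
reference ROI (default tolerance 5% relative, configurable) at a
caller-given offset, since the background must be an equivalent-size
region nearby.

## Time-series analysis

Traces are background-relative intensities on an irregular grid of minutes
post-first embryonic division. The default acquisition grid is 2.5-min
steps on [560, 680] and 5-min steps on [685, 900]; analysis windows are
`full` 560–800, `period1` 560–695 (up to the mean time swelling becomes
visible), `period2` 696–800 (PS becomes detectable and grows). A trace
must carry ≥ 10 points to qualify for integral or regression analysis;
the rule can be explicitly overridden per call.

- **Onset detection**: first time the value exceeds a threshold fold for a
  minimum run of consecutive samples. Defaults: threshold 1.2 (the level
  ER-store-deficient traces never exceed, so it separates genuine release
  transients from baseline fluctuation), run 2 samples. Event times in the
  source recordings were assigned by eye; this algorithmic criterion is a
  design decision and both knobs are exposed.
- **Swelling**: first time the equivalent radius exceeds 1.2× its initial
  value.
- **Integration**: trapezoid on the native grid, no smoothing. Window
  edges are linearly interpolated by default (`edge_mode="interpolate"`);
  `"observed"` integrates only between observed samples, for data where
  interpolating across gaps is not wanted. A trace that does not cover a
  window bound is truncated with a warning. Trapezoid integration is exact
  on piecewise-linear traces, additive across subwindows, and invariant
  under grid refinement of the interpolant (tested to 1e-9 relative).
- **Peak metrics**: one record per maximal supra-threshold run — maximum
  value, its time, and the duration between linearly interpolated
  threshold crossings (so a single supra-threshold sample still has
  positive width).

## Cohort statistics

- Normalization divides each cell's RPS by the reference cohort's mean;
  the reference's own normalized mean is 1 by construction, and the
  operation is scale-invariant and idempotent.
- The Ca²⁺↔PS coupling regression is ordinary least squares of
  `ln(∫PS)` on `ln(∫Ca)` (scipy's `linregress`). Natural logs are used:
  slope and r are base-invariant for a log–log fit, only the intercept
  depends on the base. `R²` is stored as `r*r`, so the identity is exact.
- Count summaries partition animals, in input order, into consecutive
  groups (default 10 per group; 15 or 25 for strains scored that way),
  keep and flag a trailing partial group, and report the mean of group
  means with its s.e.m. over groups. Intensity summaries use s.e.m. over
  cells. An optional anatomical maximum (2 for PLMs) validates counts.
- PS-positive fractions among living cells use a positivity threshold of
  RPS > 1.5 by default (unspecified in the source protocol;
  config-exposed, and the supplementary reproduction reports sensitivity
  at 1.2/1.5/2.0). The s.e.m. of the percentage is the binomial standard
  error.
- Dose–response tables normalize each dose's PS to the vehicle (dose 0)
  cohort and attach a monotonicity report; a missing vehicle dose is an
  error.

## Synthetic-scene generator

The generator is phenomenological: it reproduces the *statistical
structure* the analysis assumes — trace shapes, event ordering, coupling,
cohort scaling — not ER/cytosol Ca²⁺ kinetics (no compartment ODEs), no
DIC rendering, and no embryo motion beyond optional random time-point
dropout (which exercises the ≥10-point rule).

- **Ca²⁺ traces**: baseline fold (1 unless reuptake is blocked) plus
  transient bumps with half-Gaussian rise (σ drawn from 5–10 min) and
  exponential decay (τ from 12–28 min), 2–4 peaks per cell at uniform
  random times in [590, 740] min. Peak amplitudes are
  `1 + channel_leak · er_release_gain · U(0.4, 4.0)` fold, which spans the
  observed necrotic range 1.4–5× at the default gains; `crt-1`-like cells
  use gain 0.05 with a hard cap at 1.2 fold. Chosen as the simplest smooth
  form matching transients that rise sharply and relax to baseline.
- **Swelling**: threshold crossing of the running trapezoidal integral of
  (Ca − 1). The default threshold (80 fold·min) was calibrated once so the
  default 4-cell necrotic cohort's mean swelling time lands near the
  boundary between the fast and slow acquisition epochs (~695 min), after
  which the radius grows linearly from 4 px to 2.5× by the recording end.
- **PS**: onset a fixed delay (default 40 min) after swelling, rising as a
  cubic smoothstep over 30 min to a plateau. The plateau is derived so the
  *integrated PS enrichment* over the 560–800 window equals
  `exp(intercept + slope · ln ∫(Ca−1))` exactly — the coupling is defined
  on integrals, which is what the cohort regression estimates, so a
  noise-free cohort returns the programmed slope to numerical precision.
- **Noise** is multiplicative Gaussian on intensities, clipped at 0,
  applied after ground truth is recorded. Seeding is explicit per scenario
  and per cell (`default_rng([seed, cell_index])`), so cohorts are
  bit-reproducible.
- **Rendering** paints a flat background plane of known unit intensity,
  the cell disk at `Ca_R × background` in the Ca channel, and a
  3-px-wide ring just outside the boundary at `RPS × background` in the
  PS channel, using the same center-inside pixel rule as quantification.
- **Pharmacology presets**: a dantrolene-like dose d sets
  `er_release_gain = 1/(1 + 0.35 d)` (monotone release reduction); a
  thapsigargin-like dose raises the baseline by `0.04 d` per cell (scaled
  by U(0.5, 1.5) across cells), so higher doses push more cells over the
  swelling threshold.

What passing tests on synthetic data do **not** show: robustness to
focus drift, segmentation error, bleed-through, photobleaching, or
non-uniform backgrounds — real recordings have all of these and the
generator has none.

## Cohort definition for the coupling regression

Under measurement noise, cells that never expose PS contribute only a
noise-floor PS integral, which is meaningless on a log scale and biases
the fit; the regression cohort therefore includes only cells with a
detected PS onset, mirroring the practice of correlating integrals over
neurons that actually expose PS.

## Supplementary-data reproduction

`reproduce-paper` recomputes printed summary values from the published
data workbook. Sheet names are mapped to figure keys through a shipped
pattern file (`data/sheet_map.json`) so the mapping can be corrected
without code changes when the workbook's internal naming differs; unmapped
sheets are kept raw with a warning. Two open conventions are handled by
computing both readings and reporting which is used: the Fig 2E pairs are
interpreted as cumulative-to-date integrals and as per-interval
increments (the report states which reading's r is quoted), and windowed
integrals are computed on raw relative intensities (value 1 baseline
included), matching the description of integrals of relative signal
intensities. Agreement rules: 5% relative for recomputed ratios and
correlations, printed rounding for means, and upper bounds for quantities
stated as "less than".

## Problem sizes

Default cohorts are 4–10 cells per scenario on the 93-point default grid;
rendered stacks are 64×96 px or similar; the property suite uses ≤ 32×32
images for oracle comparisons and 20 seeded cohorts for noisy parameter
recovery. These sizes keep the full suite and the acceptance script in the
tens of seconds on one CPU while leaving every statistical check
well-powered.
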