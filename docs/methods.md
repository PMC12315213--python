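# Methods

This note records the model formulations, default parameters and design
choices behind `agroclim`, and what the synthetic-data experiments do and
do not demonstrate.

## Synthetic climate generator

The generator stands in for bias-corrected, dynamically downscaled daily
climate projections on a ~5 km grid. It is a conventional WGEN-family
construction, chosen because every downstream model needs only realistic
marginal behaviour and day-to-day persistence, not full spatial-temporal
covariance:

- **Temperature.** Daily mean = seasonal sinusoid + AR(1) anomaly.
  The sinusoid peaks in mid-January for southern-hemisphere cells
  (mid-July north of the equator); per-cell annual mean and amplitude
  come from the grid builder, which imposes a north–south gradient
  (default: 13 °C at 41° S, 0.6 °C per degree of latitude, amplitude
  5.5 °C — a New Zealand-like range). The anomaly has lag-1
  autocorrelation 0.65 and stationary SD 2.2 °C. `tmax`/`tmin` are the
  mean ± half a fixed diurnal range (9 °C), which guarantees
  `tmax ≥ tmin` without rejection sampling.
- **Precipitation.** First-order two-state Markov occurrence
  (wet→wet 0.60, dry→wet 0.24, giving a stationary wet-day fraction
  0.375) with gamma amounts (shape 0.75, scale 8 mm). These values
  produce ~1100 mm yr⁻¹ with realistic wet-spell persistence for a
  temperate maritime climate.
- **Radiation, humidity, wind.** Climatological sinusoid (radiation) or
  constant mean (RH 78 %, wind 4 m s⁻¹) plus Gaussian noise, clipped to
  physical ranges. They are deliberately uncorrelated with precipitation
  — a documented simplification; real overcast-wet-day covariance would
  slightly lower ET on rain days.
- **Scenarios.** A scenario is an additive warming offset and a
  multiplicative precipitation scale. The offset ramps linearly from zero
  at the series start to its full value at the end (mimicking a transient
  pathway, so 20-year slices cut from one run differ); a constant-offset
  mode exists for controlled experiments. Bundled magnitudes
  (RCP2.6 +0.7 °C ×1.00, RCP4.5 +1.4 ×1.02, RCP6.0 +1.8 ×1.02,
  RCP8.5 +3.0 ×1.04 by series end) are end-of-century magnitudes typical
  of published New Zealand projections; they are labels for experiments,
  not emulations of any particular model run.
- **Ensemble members** differ only by RNG stream (seed, member, cell).
  Two scenarios generated from the same seed share their weather noise
  exactly, so scenario differences are pure perturbation signal. This is
  the opposite of a real multi-model ensemble, whose members differ
  structurally; the generator cannot represent inter-model spread, and
  nothing downstream should be read as quantifying projection
  uncertainty.

Passing tests on this generator therefore demonstrate correctness of the
risk algorithms and the directional response to imposed warming — not
skill against observed weather, which would require real forcing data.

## Hazard counting

A hazard rule is a strict inequality (`>` or `<`, exactly as printed in
the source table the built-ins encode) on one daily variable inside a
month-day sensitive window. Windows whose end month-day precedes their
start (e.g. 15 Dec–15 Feb) span the calendar-year boundary and belong to
the season of their end date; "29 Feb" resolves to 28 Feb in non-leap
years; partial first/last seasons of a series are dropped, never padded.
The extreme-rainfall rule ("more than 3 days in any 7 with ≥ 5 mm/day")
triggers when a span of 7 consecutive days lying *wholly inside* the
window contains ≥ 4 qualifying days — the alternative convention
(anchoring spans that may protrude) differs only at window edges. Risk
change between climates is the arithmetic difference of mean annual
event-day counts per cell; ratios are deliberately not the default since
baseline counts are frequently zero.

## Phenology

Degree-days use the simple-average method,
`max(0, min((tmin+tmax)/2, T_cut) − T_base)`, the least-assumption method
when only daily extremes are available. Accumulation starts the day
*after* sowing, so under constant forcing *d* the crossing of threshold
*H* occurs exactly `ceil(H/d)` days after sowing — a closed form the
tests pin. Stage boundaries are inclusive (reaching a threshold enters
the stage).

Maize-silage defaults — base 8 °C, cutoff 30 °C, sowing fixed 1 October,
stage thresholds 150/450/950/1350 °C·day with Kc 0.3/0.7/1.2/0.5, season
cutoff 30 June of the harvest year — are conventional temperate-maize
values (the Kc triplet 0.3/1.2/0.5 is the standard crop-coefficient
convention; the development-stage 0.7 is its midpoint). They are exposed
in YAML and must not be read as a calibrated cultivar: published regional
studies calibrate these against field trials, which this package does
not. A temperature-triggered sowing rule (earliest day after a date when
the 10-day trailing mean reaches a trigger) supports experiments on
sowing advance under warming. A season whose sowing rule never fires is a
model outcome (unsown, not mature), not an error.

## Water balance and PED

Reference ET defaults to Priestley–Taylor, α = 1.26, with net radiation
simplified to `max(0, 0.77·Rs − 1.5)` MJ m⁻² day⁻¹ (albedo 0.23 and a
flat net-longwave allowance) — radiation-and-temperature-only, keeping
the model deliberately simple; an FAO-56 Penman–Monteith variant using
humidity and wind sits behind a switch. The bucket is a single
plant-available store: demand `Kc·ET_ref`; actual ET scales linearly once
the store drops below a stress fraction f = 0.5 of capacity, and is
additionally capped by store + rain (without that cap, tiny stores could
violate non-negativity while keeping the mass balance exact). Overflow
beyond capacity drains. The daily unmet demand accumulates into PED.
Storage change equals precip (+ irrigation) − actual ET − drainage to
< 1e−9 mm per step, property-tested over random forcing.

PED accumulates over the growth window (sowing to maturity, stage-wise
Kc) by default; a calendar mode applies a constant Kc over the whole
July–June season year — the classic fixed-coefficient PED, used for
pasture-like covers and as the cross-check target of an independent
reimplementation in the tests. The store starts each season (1 July) full
— a winter-recharge assumption appropriate to temperate maritime winters
— configurable via `initial_fraction`. Unlimited irrigation mode supplies
exactly the unmet demand (deficit 0) and logs the applied depth.

## Suitability

Memberships are trapezoids (a ≤ b ≤ c ≤ d): the minimal shape providing a
plateau, linear transitions and exact discretisation. The default
combiner is `min` (Liebig-style limiting factor, the standard in
land-evaluation practice); `product` and a weighted geometric mean are
available because the published rule-based systems this framework
mirrors do not all agree. Class bounds 0.25/0.5/0.75 (left-closed) are a
declared convention. The shipped apple and kiwifruit rule files are
illustrative only — labelled synthetic, not calibrated against any
published suitability surface.

## Occurrence risk and THI

The occurrence model is a Bernoulli GLM with logit link on period
covariates (default: monthly mean temperature and monthly rainfall total;
the covariate builder is pluggable since published applications differ in
their predictors). Counts reduce to exceedance (> 0) rather than a
separate count likelihood. Degenerate designs fail loudly: single-class
outcomes and single-covariate complete separation raise a fit error
naming the covariate. Projection flags (but still returns) covariates
more than three training-range widths outside the training interval.
The identical machinery serves any binary climate-driven health outcome
by swapping the training records.

THI = `0.8·T + (RH/100)(T − 14.4) + 46.4` on daily mean temperature, the
widely used dairy form; exceedance threshold 68 (conventional onset of
mild heat stress). Both are configurable.

## Aggregation

Two-stage order is normative and pinned by test: within-slice statistic
per member first (mean by default), then the median across members
(matching the usual published multi-model convention; configurable), with
member min/max as spread. Proportional change flags zero-baseline cells
as undefined rather than emitting infinities. Slice windows are always
explicit arguments — source studies are inconsistent about baselines, so
nothing is hard-coded.

## I/O

Two dialects: long CSV (cell_id, ISO date, six variables, plus provenance
columns) and CF-style NetCDF3 with dims (time, y, x), written through
xarray's scipy backend so no binary-HDF5 dependency is required. Both
round-trip float64 exactly and are byte-stable. The gridded dialect
requires complete `r{row}c{col}` grids; irregular station sets use CSV.
GeoTIFF export is not provided.

## Experiment design in the acceptance script

`scripts/acceptance.py` uses a 2 × 5 latitudinal grid, 20 full July–June
seasons, and compares the baseline against +0.7 °C and +1.4 °C constant
offsets applied to the *same* weather realisation (mid- and late-century
levels of an RCP4.5-like ramp). Differencing scenario variants over a
common realisation isolates the imposed climate signal from sampling
noise — the analogue of comparing bias-corrected scenario runs driven by
the same internal variability. Problem sizes (10 cells, 20 seasons,
5,000 training records) are chosen so the whole script completes in
seconds while keeping Monte-Carlo noise well below the effects measured.

## Known limitations

- No spatial correlation between cells; no cross-variable correlation
  with precipitation; no inter-model structural spread.
- No CO₂ fertilisation effect on development or water demand.
- Crop parameters and suitability rules are conventional defaults, not
  calibrations; absolute outputs are illustrative, directional responses
  are the tested claims.
- Single-layer soil store: no runoff routing, drainage is lost, no
  groundwater.
- The logistic risk model assumes independent periods; serial dependence
  within cells is not modelled.
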