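# agroclim

Direct climate-change risk modelling for agriculture, driven by daily
gridded climate series.

Climate change shifts where and how well crops and livestock systems
perform. `agroclim` implements the family of light-weight biophysical risk
models that agronomists and land-use planners run against downscaled daily
climate projections (per grid cell, per emissions scenario, per ensemble
member) to map those shifts:

- **Threshold-exceedance crop hazards** — days inside a crop's sensitive
  window with `T_max > c` (heat stress), `T_min < c` (frost), or a
  sliding-window extreme-rainfall rule; built-in rules for six arable crops
  (chestnuts, onions, peas, potatoes, wheat, maize).
- **Degree-day phenology** — GDD accumulation
  `max(0, min(T̄, T_cut) − T_base)` from a sowing rule through the
  four-stage crop-coefficient scheme; maturity failure over 20-year time
  slices; stage-timing shifts.
- **Crop water balance and drought** — a single-store soil bucket with
  stage-dependent demand `Kc · ET_ref` (Priestley–Taylor reference ET by
  default), accumulating the potential evapotranspiration deficit
  PED = Σ (demand − actual ET) over the growth period; monthly demand
  profiles.
- **Fuzzy land suitability** — trapezoidal memberships over mean-annual
  climate attributes combined by a limiting-factor (min), product or
  weighted-geometric rule into a 0–1 score, discretisable into classes.
- **Empirical animal-health risk** — a statsmodels-style logistic
  occurrence model (`OccurrenceRiskModel(...).fit()` →
  results with coefficients, standard errors and `summary()`) relating
  e.g. facial-eczema risk to monthly temperature and rainfall, projected
  onto future climate; and the dairy temperature–humidity index
  `THI = 0.8 T + (RH/100)(T − 14.4) + 46.4`.
- **Time-slice / ensemble aggregation** — per-member within-slice means,
  then the median across members, and absolute or proportional change
  maps.

Because real downscaled projections are bulky and access-restricted, the
package ships a seeded stochastic weather generator (seasonal sinusoid +
AR(1) temperatures, two-state Markov / gamma precipitation) that emulates a
5 km gridded daily product, with scenario perturbations (ramped warming
offset, precipitation scaling) and pseudo-ensemble members. Everything
downstream is format-agnostic: series move through long CSV or CF-style
NetCDF.

## Worked example

```python
import agroclim as ac

config = ac.WeatherGenConfig.grid(seed=42, n_years=22, nx=2, ny=5,
                                  start_year=1985)
baseline = ac.generate_series(config, ac.ScenarioPerturbation.baseline(),
                              "r3c0")
warmed = baseline.with_temperature_offset(1.4)   # late-century RCP4.5-like

spec = ac.hazards.get_hazard_spec("wheat", "heat_stress")
change = ac.hazards.hazard_risk_change(
    ac.hazards.count_all_seasons(baseline, spec, range(1986, 2006)),
    ac.hazards.count_all_seasons(warmed, spec, range(1986, 2006)),
)
print(f"wheat heat-stress days: {change.loc['r3c0']:+.2f} per season")

params = ac.phenology.maize_silage_params()
frac = ac.phenology.maturity_failure_fraction(baseline, params, (1986, 2005))
frac_w = ac.phenology.maturity_failure_fraction(warmed, params, (1986, 2005))
print(f"maize maturity failure: {frac:.0%} -> {frac_w:.0%}")
```

prints

```
wheat heat-stress days: +0.90 per season
maize maturity failure: 30% -> 0%
```

— this cool southern cell gains about one extra day per season above the
25 °C wheat heat-stress threshold under ~1.4 °C of warming, while maize
silage, which failed to reach maturity in 6 seasons of 20 at baseline,
always accumulates the required 1350 °C·day before the 30 June cutoff in
the warmed climate.

The same models are scriptable from the shell:

```sh
agroclim synth --config cfg.yaml --scenario RCP4.5 --members 3 \
    --out grid.nc --seed 42
agroclim hazards --climate grid_m0.nc --climate grid_m1.nc \
    --climate grid_m2.nc --crop wheat --hazard heat_stress \
    --baseline 1982:1991 --future 2011:2020 --out change.nc
agroclim phenology --climate grid_m0.nc ... --slices 1982:1991,2011:2020 \
    --out maturity.csv
```

## Layout

```
src/agroclim/
  climate.py        daily series container and invariants
  weather.py        stochastic gridded weather generator, scenarios
  io.py             long-CSV and CF-NetCDF dialects
  hazards.py        threshold-exceedance hazard counting, change maps
  phenology.py      GDD engine, stages, maturity failure, timing shifts
  water_balance.py  reference ET, soil bucket, PED, monthly demand
  suitability.py    fuzzy memberships, combiners, classes
  empirical_risk.py logistic occurrence model, THI
  aggregation.py    time-slice / ensemble summaries, change maps
  cli.py            `agroclim` command group
```

See `docs/methods.md` for model formulations, default parameters and known
limitations.
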