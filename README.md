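# etcalib

Daily reference evapotranspiration (ET0) modelling for agro-hydrology:

- **FAO-56 Penman–Monteith** daily ET0 as the reference, with the full
  supporting chain (saturation/actual vapour pressure, vapour pressure
  deficit, saturation-curve slope, psychrometric constant, extraterrestrial /
  clear-sky / net radiation).
- **Six mass-transfer ET0 estimators** — Dalton, Rohwer, Penman, Romanenko,
  WMO and Mahringer — each with its declared unit dialect (VPD in hPa for
  most, mmHg for Rohwer/Penman; wind in m s⁻¹ except Penman's miles day⁻¹).
  The dispatcher converts from the internal kPa / m s⁻¹ representation, so
  callers never pre-convert.
- **Linear calibration** of each estimator against the FAO-56 PM reference
  (`reference = a·estimated + b`) by closed-form ordinary least squares.
- **Skill metrics** — MAE, MAPE, RMSE, Nash–Sutcliffe efficiency and R² —
  with categorical accuracy bands (MAPE: excellent/good/reasonable/inaccurate;
  NSE: good/satisfying/less satisfactory) and strict acceptability limits
  (MAE < 0.52, RMSE < 0.50 mm day⁻¹, NSE > 0.75).
- **A seeded synthetic weather generator** producing April–October daily
  records whose pooled mean/SD/skewness per variable hit configurable
  targets (seasonal cycles plus cumulant-matched skew-normal noise; shifted
  lognormal wind; humidity anti-correlated with temperature; solar radiation
  capped at the clear-sky limit).
- **A pipeline + CLI** that reads delimited daily weather, calibrates on a
  multi-year-average training season, validates on held-out years, and
  renders coefficient, monthly-mean and metric tables.

## CLI

```bash
# generate a synthetic season of weather
etcalib simulate --out weather.csv --seed 1 --seasons 3

# daily ET0 series (reference + all six models)
etcalib compute --weather weather.csv --out et0/

# calibration coefficients against FAO-56 PM
etcalib calibrate --weather weather.csv --out coefficients.csv

# metric table for a pair of series
etcalib evaluate --actual et0/et0_fao56pm.csv --estimated et0/et0_mahringer.csv

# full study (train/validate split) from a YAML config
etcalib run --config run.yaml --weather weather.csv --out report/
```

A minimal `run.yaml`:

```yaml
station: {latitude: 38.4667, elevation: 1669.0}
train_years: [2012, 2013, 2014]
test_years: [2015]
soil_heat_flux: 0.0
```

Weather files are comma-delimited with header
`date,tmax,tmin,tmean,rhmax,rhmin,rhmean,rs,u2` (temperatures °C,
humidities %, solar radiation MJ m⁻² day⁻¹, wind at 2 m in m s⁻¹).

## Conventions and assumptions

- Internal units are kPa for vapour pressure and m s⁻¹ for wind; dialect
  conversions happen only at model boundaries. The Penman wind conversion
  uses the statute mile (1609.344 m, configurable).
- Soil heat flux G defaults to 0 for daily steps (configurable).
- rs/Rso in the net-longwave term is capped at 1.0.
- Negative VPD or negative calibrated ET0 is propagated with a logged
  warning, never clipped silently.
- Skewness is the adjusted Fisher–Pearson (spreadsheet-compatible) form.
- Monthly means weight days equally within a month; the seasonal average
  defaults to the equal-weight mean of monthly means (a day-weighted
  convention is also provided).
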