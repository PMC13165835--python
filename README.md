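# vitidss

Agro-climatological decision support for viticulture: a Python library and
CLI that turns station weather observations into irrigation, downy-mildew
and phenology alerts, viticultural bioclimatic indices, and a minimal
process-based yield estimate. It is aimed at agrometeorologists and
developers of vineyard decision-support platforms in Mediterranean
growing regions, with a shipped phenology calibration for the
autochthonous Montenegrin variety Vranac.

## What it computes

**Weather pipeline** (`weather_core`) — parses 30-min station records
(48 samples/day), validates them against plausibility limits, aggregates
UTC calendar days (tmin/tmax/tmean, precipitation totals, mean RH), and
fills missing days from the nearest national station by haversine
distance, recording donor id and distance as provenance.

**Irrigation alerts** (`irrigation`) — a recursive daily Dryness Index
soil water balance,

    DI_t = min(200, DI_{t-1} + P_t − Tv_t − Es_t),
    Tv_t = k1·ETP_t,   Es_t = (1 − k1)·ETP_t·min(P_t/5, 1),

initialised at a 200 mm reserve, with daily Thornthwaite potential
evapotranspiration (mean temperature, photoperiod, annual heat index) and
a seasonal crop coefficient k1. Days with DI < 50 mm trigger an
irrigation alert.

**Disease alerts** (`disease`) — the cumulative Goidanich index for
*Plasmopara viticola*: activation by the 3–10 rule (>10 mm rain/24 h,
mean T > 10 °C, shoots > 10 cm), then daily accumulation
GI_t = min(100, GI_{t-1} + f(T_t, RH_t)) from a temperature×humidity
development-rate table. GI > 50 % raises a treatment alert; spray records
(manual mode) or an assumed treatment at first exceedance (automatic
mode) reset GI to zero.

**Phenology** (`phenology`) — cumulative growing degree days (base 10 °C
from Jan 1) against calibrated BBCH thresholds (Vranac: bud burst 07 at
139, full flowering 65 at 492, veraison 81 at 1203, harvest ripeness 89
at 2188 °C·day), blending sensor observations with Cold/Median/Hot
continuations built from the 25th/50th/75th daily percentiles of a
multi-year history.

**Bioclimatic indices** (`bioclim`) — Winkler, Huglin, BEDD, cool-night,
growing-season T and P, De Martonne, Branas, ETCCDI-style extremes, the
seasonal Dryness Index, and multi-model ensemble climate normals.

**Yield** (`yield_sim`) — a deliberately minimal radiation-use-efficiency
model: biomass = RUE × intercepted PAR × FTSW water-stress factor, fruit
allocation after anthesis, yield read at GDD maturity.

**Synthetic weather** (`synthetic_weather`) — a seeded generator
(sinusoid + AR(1) temperature, Markov-chain/Gamma precipitation) with
30-min disaggregation and dropout injection, so every engine is testable
without any data download.

## Worked example

Forecast Vranac stage dates for a synthetic season with sensor data
through May 31, against a 30-year synthetic climatology:

```python
from vitidss.synthetic_weather import WeatherGenParams, generate_daily_weather
from vitidss.phenology import (load_calibration, build_climatology_scenarios,
                               forecast_stage_dates)

history = generate_daily_weather(WeatherGenParams(seed=11), 1991, 30)
year = generate_daily_weather(WeatherGenParams(seed=42), 2026, 1)
observed = [d for d in year if d.date.month < 6]

forecasts = forecast_stage_dates(observed,
                                 build_climatology_scenarios(history),
                                 load_calibration())
for f in forecasts:
    when = f.predicted_date.isoformat() if f.predicted_date else "not reached"
    print(f"BBCH {f.bbch:02d} [{f.scenario:>8}] -> {when}  ({f.gdd_at_forecast:.0f} GDD)")
```

```
BBCH 07 [observed] -> 2026-05-08  (145 GDD)
BBCH 65 [    cold] -> 2026-06-14  (502 GDD)
BBCH 65 [  median] -> 2026-06-12  (497 GDD)
BBCH 65 [     hot] -> 2026-06-11  (499 GDD)
BBCH 81 [    cold] -> 2026-08-06  (1207 GDD)
BBCH 81 [  median] -> 2026-07-31  (1205 GDD)
BBCH 81 [     hot] -> 2026-07-27  (1218 GDD)
BBCH 89 [    cold] -> not reached  (1970 GDD)
BBCH 89 [  median] -> 2026-11-13  (2189 GDD)
BBCH 89 [     hot] -> 2026-10-07  (2194 GDD)
```

Bud burst was already crossed by the sensor record (145 ≥ 139 °C·day on
May 8), so its date is identical under every scenario. Later stages fan
out: under the cool continuation the harvest-ripeness threshold
(2188 °C·day) is never accumulated by Dec 31, while the warm continuation
reaches it on Oct 7 — warmer continuations never delay a stage.

The same season through the CLI:

```sh
vitidss --seed 42 simulate-weather --start-year 2026 --years 1 --out w.csv
vitidss irrigation --daily w.csv --lat 42.44 --out di.csv
vitidss indices --daily w.csv --lat 42.44 --out ix.csv
```

For this (fairly wet) synthetic year the Dryness Index ranges
136.4–200.0 mm and never crosses the 50 mm alert level, and the annual
indices include Winkler 2132 °C·day, Huglin 2459 °C·day, cool-night
16.0 °C and De Martonne 40.2 — a warm, humid viticultural climate.

Other subcommands: `ingest`, `aggregate`, `fill-gaps`, `disease`,
`phenology`, `yield`, `export` (CSV/XLSX). Exit codes: 0 success,
1 validation error, 2 missing data.

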