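# Methods

This note documents the models implemented in `vitidss`, the defaults
chosen where the underlying conventions leave room, and what the
synthetic-data tests do and do not demonstrate.

## Weather pipeline

Sub-daily records are treated as UTC instants and days as UTC calendar
days; this makes daily aggregation unambiguous across stations. A day is
aggregated only when at least 80 % of the expected 48 half-hour samples
(≥ 39) are present; below that it becomes a gap. Gap-filling substitutes
the *whole* daily record of the nearest national station holding that
date (haversine distance, Earth radius 6371.0088 km; equidistant ties
broken by lexicographic station id), never a per-variable blend — whole-
record substitution keeps provenance simple and auditable (each filled
day carries the donor id and distance). The same plausibility limits are
applied to all stations regardless of kind. Aggregation sorts samples
deterministically before reducing, so it is exactly permutation-
invariant despite floating-point summation.

## Dryness Index

Daily recursion `DI_t = min(cap, DI_{t-1} + P_t − Tv_t − Es_t)` with
`Tv = k1·ETP`, `Es = (1−k1)·ETP·min(P/5, 1)`; the `min(P/5, 1)` factor
means bare-soil evaporation happens only on days when rain wets the
surface — with P = 0, Es is exactly 0. Defaults: initial reserve and cap
200 mm, alert level 50 mm (strict `<`), rain scale 5 mm. No lower bound
is applied; negative DI is reported as a genuine deficit. The k1
schedule follows the Riou/Tonietto seasonal convention
(Apr 0.1, May 0.3, Jun–Sep 0.5, other months 0.1) and is configurable.

Thornthwaite ETP is a monthly formulation; the daily adaptation used
here evaluates the monthly formula at the day's mean temperature,
applies the photoperiod correction L/12 (L from the standard
solar-declination day-length formula, rejected poleward of 66.5°), and
divides by the number of days in the month. The annual heat index
`I = Σ (max(0,T_m)/5)^1.514` is computed per year from the driving
series' own calendar-month means; months absent from a partial-year run
fall back to the series' climatological monthly means (an approximation
logged at run time, adequate because I only enters through the exponent
`a(I)`).

Two run variants exist: the annual profile starts Jan 1 at the full
reserve (the operational display), and `seasonal_dryness_index` runs
Apr 1 → Sep 30 for the bioclimatic-index variant. Whether both should
share one k1 schedule is not settled in the underlying conventions; this
implementation reuses the same schedule for both.

## Goidanich downy-mildew model

Two phases. Activation: precipitation > 10 mm/24 h AND mean T > 10 °C
AND shoot length > 10 cm, all strict. The shoot condition is
configurable: a recorded observation date, a GDD proxy (satisfied once
cumulative base-10 GDD from the series start reaches 150 °C·day; the
default, since shoot length is rarely measured), or always-true for
laboratory runs. Activation is latched for the season — resets zero the
index but do not de-activate; the index resets annually.

Accumulation begins the day **after** activation (the activation day
itself reads GI = 0): daily `GI_t = min(100, GI_{t-1} + f(T, RH))`, with
f looked up in a left-closed right-open (temperature, RH) bin table.
The shipped table (`data/goidanich_table.yaml`) is a curated
transcription of the classical incubation-rate convention —
100/incubation-days at RH ≥ 75 %, half rate at 60–75 %, halted below
60 % — and is deliberately editable; all correctness tests use toy
fixture tables so nothing depends on the transcription.

Alerts are strict (GI > 50). Resets: manual mode zeroes GI on recorded
spray dates; automatic mode assumes a treatment the day *after* the
threshold is first exceeded (so the alert is observable for exactly one
day); hybrid applies both. Automatic mode is exactly equivalent to
manual mode with sprays inserted the day after each exceedance — this
equivalence is a tested property, not an implementation shortcut.

## Phenology

Cumulative GDD uses daily mean temperature only, base 10 °C, from Jan 1.
Threshold crossing is inclusive (≥): a threshold met exactly on a day
flags that day. The shipped Vranac calibration is BBCH 07 → 139,
65 → 492, 81 → 1203, 89 → 2188 °C·day; other varieties load from YAML.
Scenario continuations are per-calendar-day 25th/50th/75th percentiles
of tmean across ≥ 3 years of history (linear interpolation between order
statistics; Feb 29 merged into Feb 28). Stages already crossed by the
observations are reported once as "observed" and are invariant to the
scenario choice; unreached stages report the scenario's end-of-year
cumulative GDD so the shortfall is visible.

## Bioclimatic indices

Growing season is fixed to the Northern-hemisphere Apr 1 – Oct 31
window (214 days; the leap day falls outside it), Huglin to
Apr 1 – Sep 30. Winkler = GDD base 10 over the growing season; BEDD caps
the daily contribution at 9 °C·day (simple capped form, no
diurnal-range adjustment); Huglin uses
`K·Σ max(0, ((tmean−10)+(tmax−10))/2)` with the standard stepwise
latitude table for K (1.03 at Montenegrin latitudes, 42–44°). Cool-night
is mean September tmin. The Branas hydrothermal index has no single
canonical formulation; the convention adopted is
`Σ_{Apr..Aug} (monthly mean T × monthly total P)`. Extremes are six
ETCCDI-style counts/maxima (frost days, summer days, tropical nights,
hot days, rx1day, cdd with the < 1 mm dry-day convention), all strict
comparisons. The dryness entry is the Apr 1 → Sep 30 DI recursion
above. Ensemble climate normals are the mean over models of each
model's period mean; a model missing any year of the period is an
error, not a silent skip. Inputs are assumed Gregorian daily tables
(360/365-day model calendars are out of scope).

## Yield simulator

A minimal mechanistic chain chosen for transparency: LAI grows linearly
with degree-days (0.005 m²·m⁻²/°C·day) toward `lai_max` 3, capped by a
trimming management record; interception is Beer–Lambert with k = 0.5;
daily biomass gain is `RUE · PAR · interception · stress` with RUE
1 g DM/MJ PAR; the stress factor is a linear FTSW ramp
(`min(1, ftsw/0.4)`); after anthesis (492 °C·day, the Vranac flowering
threshold) half of each day's gain goes to fruit; yield is fruit dry
mass at 2188 °C·day (maturity), or the season-end value flagged
immature. Incident PAR is Hargreaves–Samani
(`0.5 · 0.16·√(tmax−tmin)·Ra`) because field stations carry no
radiometer; the soil bucket (TTSW 150 mm) loses canopy-scaled
Thornthwaite ETP modulated by the same stress factor and gains rain
plus recorded irrigation (20 mm per event by default — management
records carry no depth). The simulator makes no claim of equivalence to
any published calibrated crop model; its tested guarantees are
structural (mass and water bookkeeping, anthesis gating, monotonic
response to water, linearity in RUE).

## Synthetic weather generator

Daily tmean is a sinusoid peaking at day-of-year 205 plus AR(1) noise
with stationary standard deviation `t_noise_sd`; tmax/tmin sit a fixed
half diurnal range above/below. Precipitation occurrence is a two-state
Markov chain (stationary wet-day probability
`p_wd/(1−p_ww+p_wd)` ≈ 0.42 at the defaults, ~150 wet days/yr) with
Gamma(0.9, 9 mm) wet-day amounts; RH is an affine function of the
temperature anomaly plus a wet-day bonus, clamped to [5, 100]. Defaults
describe a Podgorica-like regime (mean 15 °C, amplitude 10 °C, diurnal
range 10 °C) and were fixed once as test fixtures. A single integer
seed drives every draw through fixed-offset substreams, so identical
parameters give identical series.

What the generator does **not** emulate: spatial correlation between
sites, seasonal precipitation cycles (wet-day parameters are constant
year-round), heat waves and weather fronts (AR(1) has no skewness or
regime switching), and any covariance between rain amount and
temperature. Passing tests therefore demonstrate the *engines'*
correctness and invariances under realistic magnitudes, not calibrated
climatological skill for any real site.

## Numerical and degenerate-input choices

Days with zero temperature samples are emitted as missing, never
fabricated. Series gaps inside an engine run raise an error naming the
first missing date — silent skipping would bias every cumulative index.
Record validation tolerates 1e-9 on the tmin ≤ tmean ≤ tmax ordering.
The test suite runs everything at desk scale (single synthetic years,
30-year climatologies, 100-replicate property ensembles), which keeps
the full suite under ~10 s while exercising every code path.
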