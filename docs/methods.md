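# Methods

## Rate models

Chilling models map daily mean temperature `T` (°C) to a rate of chilling
(chill units/day). `C1`–`C6` are band counters: rate 1 for `T ≤ 5`
(`C1`), `−10 ≤ T ≤ 5` (`C2`), `0 ≤ T ≤ 5` (`C3`), `T ≤ 7` (`C4`),
`−10 ≤ T ≤ 7` (`C5`), `0 ≤ T ≤ 7` (`C6`); 0 outside. `C7` is the Utah
model (weights 0, 0.5, 1, 0.5, 0, −0.5, −1 across its printed breakpoints
1.4, 2.4, 9.1, 12.4, 15.9, 18 °C); `C8` is the Utah model with the negative
weights removed. `C10` is a Weibull-shaped rate
`3.13·z^2.10·exp(−z^3.10)` with `z = (T+4.66)/10.93`, fixed at 1 on the
open interval (2.5, 7.4) and 0 outside [−4.7, 16]. `C11` and `C12` are
triangular: `C11` rises from −3.4 °C to an optimum at 5 °C and falls to 0
at 10.4 °C; `C12` uses optimum 0.2 °C and support (−6.5, 6.9).

Boundary inclusivity follows the printed inequalities verbatim (e.g. `C1`
still rates 1 at exactly 5 °C; `C10` keeps its small discontinuities at 2.5
and 7.4). On the sliver [−4.7, −4.66) the `C10` expression has a negative
base under a fractional power; the rate is taken as 0 there, the value the
expression approaches continuously from above.

`C9` is the dynamic (chill-portions) model: a thermal precursor pool relaxes
toward a temperature-dependent equilibrium with first-order kinetics; once
the pool exceeds 1, a temperature-dependent sigmoidal fraction converts
irreversibly into banked chill portions. We implement the standard two-step
recursion with its published constant set (slope 1.6, T_melt 277 K,
E0 4153.5, E1 12888.8, A0 1.395e5, A1 2.567e18), applied at **daily** step
because the whole suite runs on daily temperatures. Portions are
non-decreasing; sustained warmth (≥ ~30 °C) drives the pool equilibrium
below 1 and destroys accumulated precursor without yielding portions. The
test oracle is an independent transliteration of the same recursion.

Forcing models map temperature to a rate of forcing (forcing units/day):
`F1 = max(T, 0)`, `F2 = max(T−5, 0)`, `F3`/`F4` the same on daily maximum
temperature, `F5 = 0.75·max(Tmax−5,0) + 0.25·max(Tmin−5,0)`,
`F6 = 28.4 / (1 + e^{−0.185(T−18.5)})` for `T > 0`,
`F7 = 1 / (1 + e^{−0.47T + 6.49})`, and `F8` the growing-degree-hour bell
with `T_L = 4`, `T_u = 25`, `T_c = 36` applied at daily step with the
stress factor ignored. The printed middle-branch condition of `F8` reverses
its inequalities; it is implemented as `T_L ≤ T ≤ T_u`, the only reading
under which the three branches partition the temperature axis (continuity
at `T_u` is verified numerically to ≤ 1e−9).

## Windows and accumulation

Day-of-year is 1-based; windows are closed intervals. CA runs from
1 November of the previous year to 30 April (trend analysis) or to the
event date (CA–HR analysis); HR runs from 1 January (alternatives
15 January, 1 February) to the event date. Leap days count as ordinary
days. `C9` starts every window from a fresh state; no carry-over between
seasons.

Missing data: a window containing any missing (NaN) required input is
rejected by default; an explicit tolerance (e.g. ≤ 5% missing) may be
enabled, in which case missing days contribute rate 0 (for `C9`, the state
does not advance). The choice is conservative because gap-filled chilling
sums would silently bias trend estimates.

## Trend analysis and validity classification

CA is regressed on calendar year by OLS; the two-sided p-value of the
regression F-test (identical to the t-test on the slope for simple
regression) classifies each station as significant/insignificant ×
negative/positive at α = 0.05 throughout. A slope of exactly 0 falls in
the insignificant-negative class and is never significant. No
multiple-testing correction is applied across stations.

A chilling model is **valid** for a record set when the pooled Pearson
correlation between its CA and the HR of a forcing model (default `F1`)
satisfies r < 0 and p < 0.05 (two-sided, t distribution with n−2 df);
otherwise invalid. Pooling is across all stations and years; station
effects are not modelled. The station-level analysis keeps stations with at
least 15 records and reports the fraction with significantly negative r.

For presentation, records are split into 20 equal-count groups along CA
(deterministic ordering by CA, then station, then year; when n is not
divisible by 20 the larger groups sit at the low-CA end) with per-group
means and sample SDs. The regression HR = a + b·CA that feeds the onset
simulator is always fitted on **raw records** with Wald 95% confidence
intervals; binning is diagnostics only. The latitude-band comparison fits
both groups and tests slope equality through the interaction term of a
pooled OLS.

## Onset simulation

The process-based model couples one chilling and one forcing model through
the fitted rule. For an event year, chilling accumulates from 1 November
(previous year) and heat from 1 January; the onset is the **first day whose
heat accumulation strictly exceeds** the current requirement
`max(a + b·CA_t, 0)` — exact equality does not trigger, and the floor at 0
exists because negative required heat is meaningless. If the threshold is
not reached by 31 July the year yields a sentinel, not an error. When a
fitted rule has b > 0 (the invalid-model regime) the same rule applies
unchanged. The simulation is deterministic and is tested against a naive
double-loop implementation on random scenarios.

Hindcast skill uses R² (squared Pearson correlation of simulated vs
observed values) and RMSE, for mean onset dates across locations (days)
and for per-location trends (days/year). Projections are summarised with
centered 11-year moving averages (edges truncated to available years) and
the decadal advance mean(reference decade) − mean(target decade), positive
meaning earlier; the reference decade defaults to 2010–2018 and the target
to 2090–2099.

## Synthetic data

Daily mean temperature at a location is

```
T(d) = annual_mean − amplitude · g(θ_d) + warming(year) + offset + AR1(d)
g(θ) = clip(s · cos θ, −1, 1),   θ_d = 2π (doy_d − coldest_day) / 365.25
```

with daily max/min at ±`diurnal_half_range` (default 5 °C). The saturation
`s` (`plateau_sharpness`, default 2) produces a long flat winter plateau
with fast spring/autumn transitions; `s = 1` recovers a pure sinusoid. The
plateau shape is load-bearing: the contrast between chilling models that do
and do not count freezing days requires winters that sit for months just
below 0 °C and transit quickly through the 2–8 °C band, which is the
Central-European pattern (December–February means nearly equal and near
0–1 °C) and which a slow sinusoidal dip does not emulate. With the default
annual mean 9 °C and amplitude 9 °C, the November–February mean is ≈ 1 °C.

Locations draw an annual-mean offset (uniform ±2 °C) and a seasonal
amplitude (uniform 9 ± 2.5 °C). The amplitude spread is the
maritime–continental gradient of the region — mild-winter west versus
cold-winter east — and is what gives the freezing-excluding models their
spatially increasing CA toward warm-winter locations. Coordinates are
drawn uniformly in a Central-European box; locations are statistically
independent (no spatial correlation of weather).

AR(1) noise uses `noise_sd` as the *stationary* SD (innovations scaled by
√(1−φ²); 200 burn-in days discarded), defaults φ = 0.7, SD = 3 °C.
Warming is a linear ramp, uniform across the year by default with an
optional winter weighting; the historical preset uses 0.025 °C/yr over
1951–2018 so that fitted November–February trends recover the observed
0.25 °C/decade. The pathway presets (2006–2099) use 0.034 °C/yr flattening
after 2065 (≈ +2 °C, moderate pathway) and a monotone 0.048 °C/yr
(≈ +4.5 °C, high pathway).

Phenology is generated by running the onset simulator under a known rule —
the default valid mechanism is HR = 600 − 2·CA(C1), giving April onsets
(mean ≈ DOY 105) with ≈ 7-day interannual spread — then rounding a normal
observation error (default SD 2 days). Years whose threshold is never
reached are dropped and counted. Because the mechanism is explicit, trend
classes, validity verdicts, parameter recovery and projection contrasts all
have known ground truth.

### What the generator does and does not emulate

It reproduces: the seasonal shape and winter level of Central-European
daily mean temperature, red-noise weather, a secular winter warming of the
observed magnitude, a maritime–continental gradient, and onset dates tied
to chilling through a negative CA–HR rule. It does **not** reproduce:
skewed/heavy-tailed cold spells, spatial correlation between stations,
multiple species with differing requirements, observation gaps, or
elevation-dependent lapse effects. Consequently, passing tests demonstrate
that the *pipeline* recovers a known mechanism under realistic statistical
structure — not that any particular chilling model is right for real
species.

One deliberate divergence matters for interpretation: because the winter
plateau sits at ≈ 0.5 °C, forcing models with effective thresholds ≥ 5 °C
on their input (`F2`, and the high-temperature-weighted `F7`, `F8`) record
essentially no winter heat in the synthetic world, so their HR degenerates
into a spring-window artifact and they are uninformative for the validity
partition here; real maritime winters place appreciable mass above 5 °C.
The forcing-robustness test therefore asserts the partition across the
0 °C-threshold models (`F1`, `F3`, `F4`, `F5`, `F6`).

## Problem sizes and numerical choices

The reference synthetic study is 100 locations × 60 years (≈ 5,900
records), which the full CA/HR tabulation processes in seconds; the trend
analogue uses the 200-location historical preset; projections use 10–15
locations per pathway; parameter-recovery checks use 100 replicates at
n = 500. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); there is no hidden global state. Equal-count
binning and station matching use the documented deterministic tie-breaks
(lowest grid index, first met row at equal distance). Station matching uses
haversine distance on a spherical Earth, R = 6371 km, with both thresholds
strict. Gridded I/O uses xarray with CF-like `time`/`lat`/`lon` dimensions
(NetCDF3 on disk); station and phenology files are plain CSV with ISO-8601
dates.

## Known limitations

* Daily-step application of models designed for hourly data (`C9`, `F8`)
  follows the analysis convention of the suite, not the models' original
  formulation.
* The pooled validity verdict ignores station random effects; with
  thousands of pooled records even tiny |r| is significant, so verdicts
  should be read together with the station-level fractions.
* The projection contrast between valid and invalid models is qualitative:
  magnitudes depend on the synthetic warming ramps and on the fitted rule,
  not on bias-corrected GCM forcing.
* Under the pure-sinusoid option (`plateau_sharpness = 1`) the
  freezing-sensitivity contrast between model families largely vanishes;
  analyses of that contrast should use the default plateau shape.
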