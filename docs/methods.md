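# Methods

This note records the models as implemented, the numerical conventions,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the known limitations.

## Day counting and thresholds

DOY is the 1-based Julian day within the calendar year; leap years
follow the real calendar. Every accumulation window is inclusive of both
its starting day and the candidate day, and the leafing day is the
*first* day on which the relevant inequality holds with ≥ (not >). At
the predicted day y the re-accumulated state at y−1 is strictly below
the threshold and at y is at or above it; the test suite spot-checks
this. A model that never reaches its threshold(s) by Dec 31 returns an
explicit "not reached" (`leafing_doy = None`); downstream code decides
the penalty, never a sentinel date. If a crossing happens before Jan 1
of the target year (possible only with unrealistic parameters, e.g. a
tiny alternating-model requirement against a warm autumn), the DOY is
reported as the signed offset from Jan 1 (≤ 0) rather than being
silently clamped.

## The predictors

**Spring warming (SW).** Degree-day sum max(0, x_t − T_b) from t0
(default Jan 1 of the leafing year) until F\*.

**Temperature–precipitation (TP).** Two independent first-crossing
problems — the SW thermal sum against F\*, and the hydrological sum
k1·P_b + k2·ΣR_i against P_crit — whose later crossing is the leafing
day. P_b is the previous *calendar* year's precipitation total, so TP
requires weather coverage from Jan 1 of the previous year. The
current-year precipitation sum starts at the same t0 as the thermal sum
(an open choice; tying both sums to one starting date keeps the model a
single-parameter family over t0). Flags report which of the two
conditions was met when no date is produced.

**Sequential (SM).** Triangular chilling rate between T_low and T_high
peaking at T_o, accumulated from t0 (default Sep 1 of the previous
year). The first day S_c ≥ C\* is t1; from t1 *inclusive* the sigmoid
forcing va/(1 + exp(vb(x_t + vc))) accumulates, gated to zero whenever
x_t ≤ T_b, until F\*. Giving T_b this gating role is a design choice:
it is the only reading that gives the base temperature a defined job
alongside the sigmoid constants.

**Parallel (PM).** Chilling and forcing run simultaneously from t0.
Daily forcing is scaled by competence K_m + (1−K_m)·min(S_c/C\*, 1)
(competence ≡ 1 when C\* = 0). The competence of a given day uses the
chilling state *including* that day's chilling increment; the
independent oracle mirrors the same convention, which matters only on
the exact day S_c crosses C\*.

**Alternating (AM).** S_c counts days with x_t < T_b (one chill unit per
qualifying day); S_f is the degree-day sum above the same T_b. Leafing
on the first day with S_c ≥ C\* and S_f ≥ a·exp(b·S_c). The
two-constant exponential form was chosen because the model's free
parameters are exactly {t0, T_b, C\*, a, b} with a of order 50–900 and
|b| < 0.1, which matches a scale+rate pair.

**Growing season index (GSI).** Evaluated from Jan 1 of the leafing
year. Daily indicators are linear 0–1 ramps: increasing in minimum
temperature (−2 to 5 °C), decreasing in vapour pressure deficit (900 to
4100 Pa), increasing in photoperiod (36 000 to 39 600 s, i.e. 10–11 h).
The index is the *trailing* mean of their product over
min(window, days since Jan 1) days — trailing, not centred, so the
prediction is causal. Leafing on the first day the mean reaches the
threshold. The default threshold is the original 0.5, but it is the one
GSI parameter exposed to the calibrator because 0.5 is demonstrably too
low in strongly continental climates and the optimum varies by species.
VPD uses the daily-mean temperature and humidity (a daytime VPD variant
is not implemented). Missing humidity anywhere in the evaluation year is
an error, never silently imputed.

Derived variables: saturation vapour pressure is Tetens,
es = 610.7·10^(7.5T/(237.3+T)) Pa, the standard choice in the GSI
source literature; photoperiod is the astronomical sunrise equation with
declination 0.409·sin(2π·doy/365 − 1.39) and no refraction correction —
accurate to a few minutes, ample for a ramp spanning an hour. Polar
latitudes (|φ| ≥ 66.5°) are outside the supported domain.

## Calibration

The objective is RMSE over the calibration years; a year in which the
model reaches no date contributes a fixed `penalty_days` (default 400,
constrained ≥ 365 so it always exceeds any real error) — this keeps the
objective finite and pushes the search back toward parameter regions
that produce dates. Inadmissible parameter combinations proposed by the
search (e.g. a chilling optimum outside its bounds when all SM/PM
parameters are free) are scored with the same penalty.

Simulated annealing: uniform box proposals perturbing every free
parameter by ±10 % of its range, Metropolis acceptance
min(1, exp(−Δ/T)), geometric cooling (factor 0.9) over 50 epochs of 200
steps, best-ever parameters retained, per-epoch best trace
non-increasing by construction. The initial temperature is calibrated
from 50 warm-up proposals so that roughly 80 % of initial uphill moves
would be accepted. The seed is mandatory; identical seeds give identical
results. The objective surface is piecewise constant (predictions are
integer days), so plateaus are normal; the warm-up calibration plus a
late-freezing schedule handles them adequately, and an exhaustive grid
search (≤ 3 free parameters) is provided as an independent optimality
check.

Default search bounds follow the observed ranges of fitted parameters
in the field: T_b ∈ [0, 15] °C, F\* ∈ [0, 1000] °C·day, k1, k2 ∈ [0, 1],
P_crit ∈ [0, 60] mm, C\* ∈ [0, 100] CU, K_m ∈ [0, 1], a ∈ [1, 1000],
b ∈ [−0.2, 0.2], T_o ∈ [−3, 10] °C, and, when the starting date is
parameterized, t0 as an integer day offset in [Sep 1 of the previous
year, Jun 30]. "Fixed-start" SM/PM calibration pins t0 = Sep 1 and the
response constants (T_low, T_high, va, vb, vc) =
(−3.4, 10.4, 28.4, −0.185, −18.4), the standard European values;
"free-start" mode frees them all.

Metrics: R² is the squared Pearson correlation of predicted vs observed
(not 1 − SSE/SST), so F = R²(n−2)/(1−R²) is the matching regression F
with df (1, n−2). R² is reported as undefined (NaN) rather than 0 when a
prediction vector is constant — e.g. when every year hit the penalty —
and F is +inf when R² = 1 exactly. The odd/even split is purely by
calendar-year parity with both counts reported (a 25-year record yields
13 calibration and 12 validation years).

## Synthetic data

`generate_weather` draws daily weather from a configurable climate:
sinusoidal mean-temperature cycle plus AR(1) anomalies, tmin = tmean
minus a folded-normal diurnal offset, precipitation as monthly
Bernoulli occurrence times a gamma amount, humidity as clipped Gaussian.
The temperature anomalies are AR(1) rather than white because
accumulation models are sensitive to runs of warm and cold days, not
just their marginal distribution.

The default configuration emulates a continental monsoon station:
annual mean 4.5 °C, seasonal amplitude 20.3 °C (half the January–July
range of roughly −18 to 22 °C; note a pure sinusoid cannot match both
that range and the 4.5 °C annual mean, whose midpoint would be 2.1 °C —
the annual mean takes precedence and the winters come out a few degrees
milder than the target extremes), warmest in mid-July, ~510 mm of
precipitation with about three quarters falling May–August, AR(1)
coefficient 0.7 with 3.5 °C innovations. A semi-arid western-steppe
preset (~300 mm yr⁻¹, drier air) supports water-limitation studies; its
companion `TruthSpec.water_limited()` is a TP parameterisation
(T_b = 5 °C, F\* = 120 °C·day, k1 = 0.04, k2 = 0.4, P_crit = 32 mm)
chosen so the water threshold delays leafing relative to the thermal
date in roughly a third to two thirds of years, the regime the TP model
exists for.

`generate_leafing` runs a truth model and adds rounded centred Gaussian
noise (clipped to the calendar). What the synthetic data does *not*
emulate: spatial correlation between stations, humidity–precipitation
coupling, temperature–precipitation cross-correlation, observation
biases of phenological networks, and trends. Passing tests therefore
demonstrate correctness of the algorithms and recoverability under
realistic persistence and noise — not skill on any real station record.

## Model properties worth knowing

- TP with k1 = k2 = 0 and P_crit = 0 is *exactly* SW; PM with K_m = 1 is
  independent of all chilling parameters; AM with b = 0 is SW plus a
  chill-day gate.
- Uniform warming never delays SW or TP. It can genuinely delay AM:
  warming removes chill days, which postpones meeting C\* and, for
  b < 0, raises the moving target a·exp(b·S_c). Only the chilling-free
  sub-family (C\* = 0, b ≥ 0) is provably monotone, and that is what the
  property test asserts.
- Adding precipitation never delays TP; raising P_crit never advances it.
- Identifiability: T_b and F\* trade off along a ridge (a lower base
  temperature simply requires a larger sum), so fitted parameter values
  need not match the generating ones even when predictions do.
  Recovery is therefore assessed at the prediction level (validation
  RMSE), not the parameter level.

## Problem sizes

The shipped checks use 100 random two-year series per oracle/reduction
comparison, 10 random two-parameter problems for the annealer-vs-grid
comparison (35-point grid per axis), 30-year series for parameter
recovery and the water-limitation study, and 200 years for the
noise-calibration check of the observation generator. These sizes give
stable pass/fail behaviour at fixed seeds while keeping a full run in
tens of seconds.

## Limitations

No gap-filling or quality control of weather input (gaps are errors);
no sub-daily data; no polar photoperiod handling; no multi-station
pooled calibration, Bayesian estimation, or information-criterion model
selection; no senescence or flowering models. The start date of the TP
precipitation sum follows t0 rather than being pinned to Jan 1 — with
the default fixed start the two coincide.
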