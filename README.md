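# phenoleaf

Spring leaf-unfolding (leafing) phenology models for temperate plants,
with a least-RMSE simulated-annealing calibrator, an odd/even-year
calibration–validation protocol, and a synthetic continental-monsoon
weather generator. The package is aimed at ecologists and land-surface
modellers who predict leafing dates from daily station weather —
particularly in arid and semi-arid regions where temperature-only models
break down because spring water supply, not heat, sets the leafing date.

## Models

Six predictors map a daily weather series to the leafing day of year
(DOY). Writing x_t for daily mean temperature, the classical
temperature-only family is:

- **SW — spring warming.** Leafing on the first day y with
  Σ_{t=t0..y} max(0, x_t − T_b) ≥ F\*, with fixed start t0 = Jan 1 by
  default.
- **SM — sequential.** Triangular chilling rate R_c(x_t) (0 at T_low and
  T_high, 1 at T_o) accumulates from t0 = Sep 1 of the previous year;
  once the chilling state S_c reaches C\* (day t1, onset of quiescence),
  sigmoid forcing R_f(x_t) = va / (1 + exp(vb (x_t + vc))) accumulates
  (zero at or below T_b) until S_f ≥ F\*.
- **PM — parallel.** Chilling and forcing accumulate simultaneously; the
  daily forcing is scaled by bud competence
  K_m + (1 − K_m) · min(S_c/C\*, 1).
- **AM — alternating.** Chill days (x_t < T_b) relax the forcing
  requirement exponentially: leafing when S_c ≥ C\* and
  S_f ≥ a · exp(b · S_c).
- **GSI — growing season index.** The 21-day trailing mean of
  iT_min · iVPD · iPhoto (linear 0–1 ramps on minimum temperature,
  vapour pressure deficit and photoperiod) crosses a threshold.

The package's centrepiece is the **TP — temperature–precipitation
model**, which adds a hydrological condition to SW: leafing occurs on
the first day y for which **both**

    k1 · P_b + k2 · Σ_{i=t0..y} R_i ≥ P_crit      (water)
    Σ_{i=t0..y} max(0, T_i − T_b) ≥ F*            (heat)

where P_b is the previous year's annual precipitation (mm), R_i the
current-year daily precipitation, and k1, k2 are the efficiencies with
which last year's and this year's water contribute to the threshold
P_crit. With k1 = k2 = 0 and P_crit = 0, TP reduces exactly to SW.

Calibration minimises RMSE = sqrt(mean (d_i(x) − d_iobs)²) over
odd-numbered years by simulated annealing inside box bounds; even-
numbered years are held out for validation. Fits are summarised by RMSE,
R² (squared Pearson correlation) and the regression F statistic
F = R²(n−2)/(1−R²).

## Worked example

`examples/04_water_limited_comparison.py` generates 30 years of
semi-arid steppe weather (~300 mm yr⁻¹), synthesises leafing dates from
a TP truth whose water threshold binds in a large fraction of years, and
fits SW and TP side by side:

```
water threshold delays leafing in 11/29 years

model  n_cal  n_val  cal_rmse  val_rmse  val_r2
   SW     14     15      2.31     23.09    0.45
   TP     14     15      1.07      5.48    0.95
```

The temperature-only model can fit the calibration years tolerably
(2.3 days) but collapses on held-out years (23 days RMSE) because it has
no way to express precipitation-driven delays; TP stays within a few
days of the truth. The other example scripts show single-year prediction
with all six models (`01`), a two-parameter spring-warming fit (`02`),
and full TP parameter recovery from noisy synthetic observations (`03`).

## Command line

A thin CLI wraps the library for shell use:

```sh
phenoleaf simulate --truth truth.yaml --years 30 --seed 1 \
    --out-weather weather.csv --out-phenology leafing.csv
phenoleaf fit --weather weather.csv --phenology leafing.csv \
    --model TP --seed 1 --out fit.json
phenoleaf compare --weather weather.csv --phenology leafing.csv \
    --models SW --models TP --seed 1 --out-json report.json
```

Weather CSV uses the header `date,tmean,tmin,precip,rh` (ISO dates, °C,
mm, %); phenology CSV uses `station_id,species,year,leafing_doy`. Exit
status is 0 on success, 2 for validation errors, 3 for weather-coverage
errors.

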