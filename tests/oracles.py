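"""Independent reference implementations used to cross-check the predictors.

Every oracle is a plain day-by-day Python loop over DailyRecord objects,
written directly from the model definitions and deliberately sharing no
code with the vectorised implementations in phenoleaf.models.
"""

from __future__ import annotations

import datetime as dt
import math


def _doy(day: dt.date, year: int) -> int:
    return (day - dt.date(year, 1, 1)).days + 1


def _window(records, start: dt.date, year: int):
    end = dt.date(year, 12, 31)
    return [r for r in records if start <= r.date <= end]


def oracle_sw(records, p, year):
    """First day the degree-day sum from t0 reaches F_star."""
    start = p.t0.resolve(year)
    total = 0.0
    for r in _window(records, start, year):
        total += max(0.0, r.tmean - p.T_b)
        if total >= p.F_star:
            return _doy(r.date, year)
    return None


def oracle_tp(records, p, year):
    """First day both the hydrological and thermal sums hold."""
    p_b = sum(r.precip for r in records
              if dt.date(year - 1, 1, 1) <= r.date <= dt.date(year - 1, 12, 31))
    start = p.t0.resolve(year)
    hydro = p.k1 * p_b
    thermal = 0.0
    for r in _window(records, start, year):
        hydro += p.k2 * r.precip
        thermal += max(0.0, r.tmean - p.T_b)
        if hydro >= p.P_crit and thermal >= p.F_star:
            return _doy(r.date, year)
    return None


def _tri(t, lo, opt, hi):
    if t <= lo or t >= hi:
        return 0.0
    if t <= opt:
        return (t - lo) / (opt - lo)
    return (hi - t) / (hi - opt)


def _sig(t, va, vb, vc):
    return va / (1.0 + math.exp(vb * (t + vc)))


def oracle_sm(records, p, year):
    """Chilling until C_star, then gated sigmoid forcing until F_star.

    Forcing starts on the day the chilling requirement is met (that day
    contributes both its chilling and its forcing)."""
    start = p.t0.resolve(year)
    s_c = 0.0
    s_f = 0.0
    quiescent = False
    for r in _window(records, start, year):
        s_c += _tri(r.tmean, p.T_low, p.T_o, p.T_high)
        if not quiescent and s_c >= p.C_star:
            quiescent = True
        if quiescent:
            if r.tmean > p.T_b:
                s_f += _sig(r.tmean, p.va, p.vb, p.vc)
            if s_f >= p.F_star:
                return _doy(r.date, year)
    return None


def oracle_pm(records, p, year):
    """Simultaneous chilling and competence-scaled forcing."""
    start = p.t0.resolve(year)
    s_c = 0.0
    s_f = 0.0
    for r in _window(records, start, year):
        s_c += _tri(r.tmean, p.T_low, p.T_o, p.T_high)
        if p.C_star == 0:
            comp = 1.0
        else:
            comp = p.K_m + (1.0 - p.K_m) * min(s_c / p.C_star, 1.0)
        s_f += comp * _sig(r.tmean, p.va, p.vb, p.vc)
        if s_f >= p.F_star:
            return _doy(r.date, year)
    return None


def oracle_am(records, p, year):
    """Chill-day count relaxes the forcing requirement a*exp(b*S_c)."""
    start = p.t0.resolve(year)
    s_c = 0
    s_f = 0.0
    for r in _window(records, start, year):
        if r.tmean < p.T_b:
            s_c += 1
        s_f += max(0.0, r.tmean - p.T_b)
        if s_c >= p.C_star and s_f >= p.a * math.exp(p.b * s_c):
            return _doy(r.date, year)
    return None


def _es_pa(t):
    return 610.7 * 10.0 ** (7.5 * t / (237.3 + t))


def _daylength_s(lat_deg, doy):
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    cosw = -math.tan(math.radians(lat_deg)) * math.tan(decl)
    cosw = max(-1.0, min(1.0, cosw))
    return math.acos(cosw) / math.pi * 86400.0


def _ramp_up(x, lo, hi):
    return max(0.0, min(1.0, (x - lo) / (hi - lo)))


def oracle_gsi(records, latitude, p, year):
    """Trailing mean of the indicator product, first threshold crossing."""
    window_records = [r for r in records
                      if dt.date(year, 1, 1) <= r.date <= dt.date(year, 12, 31)]
    igsi = []
    for i, r in enumerate(window_records, start=1):
        vpd = _es_pa(r.tmean) * (1.0 - r.rh / 100.0)
        itmin = _ramp_up(r.tmin, p.tmin_lo, p.tmin_hi)
        ivpd = 1.0 - _ramp_up(vpd, p.vpd_lo, p.vpd_hi)
        iphoto = _ramp_up(_daylength_s(latitude, i), p.photo_lo, p.photo_hi)
        igsi.append(itmin * ivpd * iphoto)
        k = min(p.window, i)
        if sum(igsi[-k:]) / k >= p.threshold:
            return i
    return None
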