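"""Seasonal climate covariates from daily series.

Four covariates summarise a trap-year's climate: growing degree-days over
the sampling season (1 Apr - 15 Oct), chilling degree-days over the
preceding winter (15 Oct - 1 Apr), mean winter snow depth and cumulative
season precipitation. Degree-day sums use a 5 degC reference.
"""
from __future__ import annotations

import numpy as np

#: Day counts of the fixed season calendar (non-leap): the sampling season
#: 1 Apr - 15 Oct inclusive, and the preceding winter 16 Oct - 31 Mar.
SUMMER_DAYS = 198
WINTER_DAYS = 167

DEGREE_DAY_BASE = 5.0


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("daily series must be a non-empty 1-D array")
    if np.isnan(arr).any():
        raise ValueError("daily series contains missing days")
    return arr


def growing_degree_days(daily_temps, base: float = DEGREE_DAY_BASE) -> float:
    """Thermal sum: sum of positive deviations of daily mean temperature
    above ``base`` over the sampling season."""
    t = _as_series(daily_temps)
    return float(np.clip(t - base, 0.0, None).sum())


def chilling_degree_days(daily_temps, base: float = DEGREE_DAY_BASE) -> float:
    """Winter chilling sum: sum of deviations below ``base``, reported as a
    positive magnitude (larger = colder winter)."""
    t = _as_series(daily_temps)
    return float(np.clip(base - t, 0.0, None).sum())


def winter_snow_mean(daily_snow) -> float:
    """Arithmetic mean of daily snow depth (cm) over the winter window."""
    s = _as_series(daily_snow)
    if (s < 0).any():
        raise ValueError("snow depth must be non-negative")
    return float(s.mean())


def season_precipitation(daily_precip) -> float:
    """Cumulative precipitation (mm) over the sampling season."""
    p = _as_series(daily_precip)
    if (p < 0).any():
        raise ValueError("precipitation must be non-negative")
    return float(p.sum())


def epoch_for_year(year: int, epochs=(2000, 2006, 2012, 2018)) -> int:
    """Map an observation year to its land-cover epoch.

    Year-centred assignment: the nearest epoch wins, with ties going to the
    earlier epoch. With the default epochs this reproduces the windows
    1998-2003 -> 2000, 2004-2009 -> 2006, 2010-2015 -> 2012, 2016+ -> 2018.
    """
    epochs = sorted(epochs)
    dists = [abs(year - e) for e in epochs]
    return epochs[int(np.argmin(dists))]  # argmin takes the first (earlier) tie


def climate_features(
    summer_temp, winter_temp, winter_snow, summer_precip
) -> dict[str, float]:
    """The four climate covariates for one cell-year."""
    return {
        "clim_gdd": growing_degree_days(summer_temp),
        "clim_cdd": chilling_degree_days(winter_temp),
        "clim_snow": winter_snow_mean(winter_snow),
        "clim_precip": season_precipitation(summer_precip),
    }
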