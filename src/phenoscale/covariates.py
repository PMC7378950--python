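"""Temperature series and derived climate/astronomical covariates.

All thermal-forcing phenology models in this package consume a daily mean
temperature series indexed by season-relative day of year (DOY).  DOY 1 is
1 January of the event year; DOY <= 0 indexes days of the preceding autumn
and winter, which matters when the forcing start day ``t1`` is fitted and
may fall before New Year.  The canonical grid runs from DOY ``DOY_MIN`` (-90,
early October of the prior year) to ``DOY_MAX`` (250, early September), which
comfortably brackets spring budburst and flowering in temperate systems.

Covariates derived here:

* spring mean temperature, the average of daily means over 1 January -
  31 March (DOY 1..90), the predictor of the linear regression model and the
  spatial correction term of the MSB model;
* chill days, the running count of days since 1 January with mean
  temperature strictly below 0 degC, which drives the Alternating and MSB
  forcing requirements;
* photoperiod (daylength in hours) from latitude and DOY, the spatial
  correction of the M1 model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "DOY_MIN",
    "DOY_MAX",
    "DOY_GRID",
    "N_DAYS",
    "SPRING_WINDOW",
    "TemperatureSeries",
    "CovariateBundle",
    "MissingTemperatureError",
    "spring_mean_temperature",
    "chill_days",
    "photoperiod_hours",
    "build_covariates",
]

#: Season-relative DOY grid shared by every temperature series.
DOY_MIN = -90
DOY_MAX = 250
DOY_GRID = np.arange(DOY_MIN, DOY_MAX + 1)
N_DAYS = DOY_GRID.size
#: 1 January - 31 March, inclusive, in every year (leap 29 Feb is an ordinary day).
SPRING_WINDOW = (1, 90)

TEMP_LIMITS = (-60.0, 60.0)
POLAR_LATITUDE = 66.0


class MissingTemperatureError(ValueError):
    """A required day is absent (gap) from a temperature series."""


def doy_index(doy) -> np.ndarray | int:
    """Map season-relative DOY to the position on :data:`DOY_GRID`."""
    idx = np.asarray(doy) - DOY_MIN
    if np.any(idx < 0) or np.any(idx >= N_DAYS):
        raise ValueError(f"DOY {doy!r} outside supported range [{DOY_MIN}, {DOY_MAX}]")
    return idx


@dataclass
class TemperatureSeries:
    """Daily mean temperature for one site-year on the canonical DOY grid.

    Parameters
    ----------
    site_id : str
        Site identifier.
    year : int
        Calendar year of the event season (DOY 1 = 1 January of this year).
    temps : numpy.ndarray
        Daily mean temperature in degC aligned with :data:`DOY_GRID`.  Gaps are
        NaN, never silently zero.
    latitude : float
        Site latitude in decimal degrees; needed for photoperiod.
    """

    site_id: str
    year: int
    temps: np.ndarray
    latitude: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        if t.shape != (N_DAYS,):
            raise ValueError(
                f"temps must have shape ({N_DAYS},) covering DOY {DOY_MIN}..{DOY_MAX}; "
                f"got {t.shape}"
            )
        finite = t[np.isfinite(t)]
        if finite.size and (finite.min() < TEMP_LIMITS[0] or finite.max() > TEMP_LIMITS[1]):
            raise ValueError(
                f"temperatures outside plausible range {TEMP_LIMITS} degC for "
                f"site {self.site_id} year {self.year}"
            )
        self.temps = t

    @classmethod
    def from_mapping(
        cls,
        site_id: str,
        year: int,
        temps: Mapping[int, float],
        latitude: float = float("nan"),
    ) -> "TemperatureSeries":
        """Build from a DOY -> temperature mapping; unlisted days become gaps."""
        arr = np.full(N_DAYS, np.nan)
        for doy, val in temps.items():
            arr[doy_index(int(doy))] = val
        return cls(site_id=site_id, year=year, temps=arr, latitude=latitude)

    def temp_at(self, doy: int) -> float:
        return float(self.temps[doy_index(doy)])

    def require(self, lo: int, hi: int) -> np.ndarray:
        """Return temps for DOY ``lo..hi`` inclusive, erroring on any gap."""
        sl = self.temps[doy_index(lo) : doy_index(hi) + 1]
        if np.isnan(sl).any():
            missing = DOY_GRID[doy_index(lo) : doy_index(hi) + 1][np.isnan(sl)]
            raise MissingTemperatureError(
                f"site {self.site_id} year {self.year}: missing temperature on "
                f"DOY {missing.tolist()[:5]}{'...' if missing.size > 5 else ''}"
            )
        return sl


@dataclass
class CovariateBundle:
    """Derived covariates for one site-year.

    ``ncd`` is the cumulative chill-day count aligned with :data:`DOY_GRID`
    (zero before 1 January, non-decreasing after); ``photoperiod`` is daylength
    in hours on the same grid.
    """

    tmean_spring: float
    ncd: np.ndarray
    photoperiod: np.ndarray = field(repr=False)


def spring_mean_temperature(series: TemperatureSeries) -> float:
    """Mean daily temperature over 1 January - 31 March (DOY 1..90).

    The window is 90 days in every year: 29 February, when present in the
    source data, is treated as an ordinary day of the calendar and the window
    still ends on DOY 90.
    """
    lo, hi = SPRING_WINDOW
    return float(series.require(lo, hi).mean())


def chill_days(series: TemperatureSeries, upto_doy: int) -> int:
    """Number of days in 1..``upto_doy`` with mean temperature strictly < 0 degC."""
    if upto_doy < 1:
        raise ValueError(f"upto_doy must be >= 1, got {upto_doy}")
    temps = series.require(1, upto_doy)
    return int(np.count_nonzero(temps < 0.0))


def photoperiod_hours(latitude: float, doy) -> np.ndarray | float:
    """Daylength in hours from the Forsythe et al. (1995) CBM model.

    Uses the standard daylight definition (p = 0: sunrise/sunset when the
    centre of the sun crosses the horizon).  Vectorised over ``doy``.

    Raises
    ------
    ValueError
        For polar latitudes (|lat| > 66 deg), where day length can hit 0 or 24
        and the models here are not meant to apply.
    """
    if not np.isfinite(latitude) or abs(latitude) > POLAR_LATITUDE:
        raise ValueError(
            f"latitude {latitude!r} unsupported: need finite |lat| <= {POLAR_LATITUDE}"
        )
    d = np.asarray(doy, dtype=float)
    # revolution angle theta and solar declination phi (radians)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (d - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))
    lat = np.deg2rad(latitude)
    cos_hour = -np.tan(lat) * np.tan(phi)
    cos_hour = np.clip(cos_hour, -1.0, 1.0)
    daylength = 24.0 - (24.0 / np.pi) * np.arccos(-cos_hour)
    out = np.asarray(daylength)
    return float(out) if out.ndim == 0 else out


def cumulative_chill_days(temps: np.ndarray) -> np.ndarray:
    """Running NCD(t) on the canonical grid for a temps array (or matrix).

    Days before DOY 1 never contribute (chill days are counted "since
    1 January"); gaps (NaN) contribute zero.
    """
    temps = np.atleast_2d(temps)
    chill = ((temps < 0.0) & (DOY_GRID >= 1)).astype(float)
    out = np.cumsum(chill, axis=-1)
    return out[0] if out.shape[0] == 1 and np.asarray(temps).ndim == 1 else out


def build_covariates(series: TemperatureSeries) -> CovariateBundle:
    """Compute every model covariate for one site-year."""
    calendar_doy = ((DOY_GRID - 1) % 365) + 1  # DOY -90 is calendar day 275 of prior year
    return CovariateBundle(
        tmean_spring=spring_mean_temperature(series),
        ncd=cumulative_chill_days(series.temps),
        photoperiod=photoperiod_hours(series.latitude, calendar_doy),
    )
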