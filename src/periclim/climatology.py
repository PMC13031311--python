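"""Per-station day-of-year climatology and daily temperature anomalies.

Each weather station's long-run expected temperature is modelled as a
degree-4 polynomial in day-of-year, fitted by ordinary least squares to the
station's daily mean temperatures over a multi-decade reference period.
The daily *anomaly* (deviation) is the observed daily mean minus the fitted
expectation for that day of year.  Because the fit is OLS with an intercept,
per-station anomalies average to zero over the fit period, which is what
makes them usable as quasi-random exposure variation downstream.

Day-of-year convention: non-leap years use the ordinal day (1..365); in leap
years Feb 29 shares index 59 with Feb 28 and all later dates shift down by
one, so the codomain is exactly 1..365 and no day is discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("periclim.climatology")

DEFAULT_PERIOD = (1933, 1971)
DEFAULT_MIN_YEARS = 30
DEFAULT_MIN_DAYS_PER_YEAR = 180


class ClimatologyFitError(RuntimeError):
    """Raised when a station's day-of-year polynomial cannot be fitted."""


# ---------------------------------------------------------------------------
# basic record arithmetic
# ---------------------------------------------------------------------------

def daily_mean_temperature(tmin: float, tmax: float) -> float:
    """Daily mean temperature as the midpoint of the daily min and max (°C).

    A record with ``tmin > tmax`` is physically impossible and is rejected:
    a warning is logged and NaN is returned so the record drops out of any
    downstream aggregation.
    """
    if tmin > tmax:
        logger.warning("rejected record with tmin=%.2f > tmax=%.2f", tmin, tmax)
        return float("nan")
    return (tmin + tmax) / 2.0


def day_of_year_index(date) -> int:
    """Map a calendar date to a day-of-year index in 1..365.

    Feb 29 maps to 59 (shared with Feb 28); later dates in a leap year use
    ordinal - 1, so Dec 31 is always 365.
    """
    ts = pd.Timestamp(date)
    doy = ts.dayofyear
    if ts.is_leap_year and doy >= 60:
        doy -= 1
    return int(doy)


def _doy_array(dates) -> np.ndarray:
    """Vectorised :func:`day_of_year_index` for a datetime-like array."""
    idx = pd.DatetimeIndex(pd.to_datetime(np.asarray(dates)))
    doy = idx.dayofyear.to_numpy().astype(np.int64)
    leap = idx.is_leap_year
    return np.where(leap & (doy >= 60), doy - 1, doy)


def _rescale_doy(doy) -> np.ndarray:
    # affine map of 1..365 onto [-1, 1]; predictions are invariant to this,
    # it only conditions the Vandermonde matrix
    return (np.asarray(doy, dtype=float) - 183.0) / 182.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class StationSeries:
    """One station's daily temperature records plus its coordinates.

    ``records`` has columns ``date`` (datetime64), ``tmin``, ``tmax`` in °C,
    with unique dates.  Records violating ``tmin <= tmax`` may be present;
    they are treated as invalid wherever means are computed.
    """

    station_id: str
    lat: float
    lon: float
    records: pd.DataFrame

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(
                f"station {self.station_id}: invalid coordinates "
                f"({self.lat}, {self.lon})"
            )
        if self.records.duplicated("date").any():
            raise ValueError(f"station {self.station_id}: duplicate dates")

    def valid_mask(self) -> np.ndarray:
        r = self.records
        return (
            np.isfinite(r["tmin"].to_numpy())
            & np.isfinite(r["tmax"].to_numpy())
            & (r["tmin"].to_numpy() <= r["tmax"].to_numpy())
        )

    def daily_means(self) -> pd.Series:
        """Daily mean temperature per valid record, indexed by date."""
        r = self.records[self.valid_mask()]
        return pd.Series(
            (r["tmin"].to_numpy() + r["tmax"].to_numpy()) / 2.0,
            index=pd.DatetimeIndex(r["date"]),
            name="tmean",
        )


@dataclass
class ClimatologyModel:
    """Fitted degree-4 day-of-year expected-temperature curve for a station."""

    station_id: str
    coefficients: np.ndarray  # 5 coefficients, increasing powers of scaled doy
    fit_period: tuple[int, int]
    n_obs: int
    residual_sd: float

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise ValueError("climatology model requires exactly 5 coefficients")
        if self.n_obs <= 0:
            raise ValueError("climatology model requires n_obs > 0")

    def predict_doy(self, doy) -> np.ndarray:
        """Expected temperature (°C) for day-of-year index/indices 1..365."""
        x = _rescale_doy(doy)
        return np.polynomial.polynomial.polyval(x, self.coefficients)


@dataclass
class DeviationSeries:
    """Daily anomalies (observed mean - expected) for one station."""

    station_id: str
    entries: pd.Series = field(repr=False)  # DatetimeIndex -> deviation °C


# ---------------------------------------------------------------------------
# eligibility and fitting
# ---------------------------------------------------------------------------

def station_is_eligible(
    series: StationSeries,
    period: tuple[int, int] = DEFAULT_PERIOD,
    min_years: int = DEFAULT_MIN_YEARS,
    min_days_per_year: int = DEFAULT_MIN_DAYS_PER_YEAR,
) -> bool:
    """Whether a station reported enough data inside the reference period.

    A calendar year counts as covered when it holds at least
    ``min_days_per_year`` valid daily records; the station is eligible when
    at least ``min_years`` years are covered.
    """
    means = series.daily_means()
    years = means.index.year
    in_period = (years >= period[0]) & (years <= period[1])
    counts = pd.Series(1, index=years[in_period]).groupby(level=0).sum()
    return int((counts >= min_days_per_year).sum()) >= min_years


def fit_station_climatology(
    series: StationSeries,
    period: tuple[int, int] = DEFAULT_PERIOD,
    degree: int = 4,
) -> ClimatologyModel:
    """OLS fit of daily mean temperature on a degree-4 polynomial of day-of-year.

    The day index is affinely rescaled to [-1, 1] before powering purely for
    numerical conditioning; predictions are invariant to the rescaling.
    """
    means = series.daily_means()
    years = means.index.year
    means = means[(years >= period[0]) & (years <= period[1])]
    doy = _doy_array(means.index)
    if len(np.unique(doy)) < degree + 1:
        raise ClimatologyFitError(
            f"station {series.station_id}: fewer than {degree + 1} distinct "
            "day-of-year values; polynomial under-determined"
        )
    X = np.vander(_rescale_doy(doy), degree + 1, increasing=True)
    y = means.to_numpy()
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise ClimatologyFitError(
            f"station {series.station_id}: rank-deficient design (rank {rank})"
        )
    resid = y - X @ coef
    dof = max(len(y) - (degree + 1), 1)
    return ClimatologyModel(
        station_id=series.station_id,
        coefficients=coef,
        fit_period=tuple(period),
        n_obs=len(y),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
    )


def expected_temperature(model: ClimatologyModel, date) -> float:
    """Evaluate the fitted climatology at a date's day-of-year index (°C)."""
    return float(model.predict_doy(day_of_year_index(date)))


def compute_deviations(series: StationSeries, model: ClimatologyModel) -> DeviationSeries:
    """Observed daily mean minus climatological expectation, per valid record.

    Dates whose records were rejected (tmin > tmax or non-finite) are absent
    from the output.
    """
    if model.station_id != series.station_id:
        raise ValueError(
            f"model for station {model.station_id} applied to series "
            f"{series.station_id}"
        )
    means = series.daily_means()
    expected = model.predict_doy(_doy_array(means.index))
    return DeviationSeries(
        station_id=series.station_id,
        entries=pd.Series(means.to_numpy() - expected, index=means.index,
                          name="deviation"),
    )
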