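"""Synthetic station network and birth cohort with known ground truth.

The generator emulates the statistical structure the analysis assumes — a
seasonally and spatially structured station network, and a cohort whose
adult metabolic outcomes embed a known linear effect of the true
periconceptional anomaly — so every downstream stage can be tested without
any restricted data.

Weather model (daily mean at station s, day t):

    T_st = base + lat_gradient * (lat_s - lat0) + season(doy_t) + a_t + e_st

where ``a_t`` is a shared regional AR(1) anomaly (marginal SD ``weather_sd``,
lag-1 autocorrelation ``weather_ar1``), ``e_st`` is independent station
noise, and records are emitted as (tmin, tmax) = mean -/+ diurnal_range/2.
``season`` is the degree-4 polynomial (in the rescaled day-of-year basis
the climatology stage uses) that best approximates
``seasonal_amp * cos(2*pi*(doy - peak)/365)``; generating the seasonal truth
inside the climatology model class keeps the ground-truth anomaly exactly
``a_t + e_st``, so a noiseless world has identically zero anomalies.

Cohort model: participants are assigned a grid-cell area and a uniform
birthplace within it; conception dates follow an area-specific von-Mises-
style seasonal fertility weighting; gestation is Normal(266, gestation_sd)
rounded to whole days (truncated at +/-6 SD); outcomes are a sum of
intercept, area effect, smooth season-of-conception effect, sex effect,
birth-year trend, the causal term alpha * (true-window mean anomaly), and
noise.  Everything needed to score an estimator is kept in GroundTruth,
which is never consumed by inference.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .climatology import StationSeries, _doy_array, _rescale_doy
from .linkage import geodesic_distance_km

logger = logging.getLogger("periclim.synthetic")


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


#: Table-style means and SDs of the five continuous metabolic outcomes the
#: cohort emulates (BMI kg/m², waist cm, HbA1c mmol/mol, triglycerides and
#: total cholesterol mmol/l).
OUTCOME_PARAMS = {
    "bmi": (27.44, 4.789),
    "waist_circumference": (90.34, 13.512),
    "hba1c": (35.97, 6.519),
    "triglycerides": (1.755, 1.025),
    "cholesterol": (5.711, 1.144),
}


def _default_alpha():
    # effect sizes of 10% of an outcome SD per °C: scaled up relative to the
    # epidemiological scale so a desk-scale cohort has adequate power
    return {k: 0.1 * sd for k, (_, sd) in OUTCOME_PARAMS.items()}


def _default_noise():
    return {k: sd for k, (_, sd) in OUTCOME_PARAMS.items()}


def _default_means():
    return {k: mean for k, (mean, _) in OUTCOME_PARAMS.items()}


@dataclass
class SimConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    n_stations: int = 25
    bbox: tuple = (50.0, 55.5, -5.5, 1.5)   # lat_min, lat_max, lon_min, lon_max
    n_participants: int = 20_000
    n_areas: int = 25
    year_range: tuple = (1933, 1971)
    true_alpha: dict = dc_field(default_factory=_default_alpha)
    seasonal_amp: float = 7.0               # °C, half-range of the annual cycle
    seasonal_peak_doy: float = 197.0        # mid-July maximum
    base_temp: float = 9.5                  # °C at the bbox's central latitude
    lat_gradient: float = -0.6              # °C per degree latitude northward
    weather_sd: float = 2.0                 # marginal SD of the regional anomaly
    weather_ar1: float = 0.7
    station_noise_sd: float = 1.0
    diurnal_range: float = 8.0
    gestation_mean: int = 266
    gestation_sd: float = 10.0              # days; 0 disables DOC error
    fertility_season_strength: float = 0.5
    fertility_peak_doy: float = 355.0       # late-December conception peak
    outcome_noise_sd: dict = dc_field(default_factory=_default_noise)
    outcome_means: dict = dc_field(default_factory=_default_means)
    causal_window: str = "-2w;DOC"
    sex_effect_sd_frac: float = 0.25
    area_effect_sd_frac: float = 0.3
    year_trend_sd_frac: float = 0.005
    assessment_years: tuple = (2006, 2010)
    seed: int = 0

    def __post_init__(self):
        lat0, lat1, lon0, lon1 = self.bbox
        if self.n_stations <= 0:
            raise ConfigurationError("n_stations must be positive")
        if lat1 <= lat0 or lon1 <= lon0:
            raise ConfigurationError("bbox is empty")
        if self.n_areas < 2:
            raise ConfigurationError("n_areas must be >= 2")
        if not (0.0 <= self.weather_ar1 < 1.0):
            raise ConfigurationError("weather_ar1 must be in [0, 1)")
        for name in ("weather_sd", "station_noise_sd", "gestation_sd",
                     "seasonal_amp", "diurnal_range"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.outcome_noise_sd.values()):
            raise ConfigurationError("outcome noise SDs must be >= 0")
        if self.year_range[1] < self.year_range[0]:
            raise ConfigurationError("year_range is empty")


@dataclass
class StationNetwork:
    """Simulated stations plus the latent processes used to build them."""

    stations: list                       # list[StationSeries]
    dates: pd.DatetimeIndex
    regional_anomaly: np.ndarray         # the shared AR(1) path, °C
    seasonal_coef: np.ndarray            # degree-4 poly in rescaled doy basis
    station_offsets: np.ndarray          # per-station constant term, °C
    config: SimConfig

    def expected_mean(self, station_index: int, doy) -> np.ndarray:
        """Deterministic harmonic component for a station (no weather noise)."""
        return (self.station_offsets[station_index]
                + np.polynomial.polynomial.polyval(
                    _rescale_doy(doy), self.seasonal_coef))


@dataclass
class GroundTruth:
    """Simulation truth, stored for scoring only — never used by inference."""

    true_alpha: dict
    conception_date: np.ndarray          # datetime64[D] per participant
    true_window_anomaly: np.ndarray      # °C per participant
    causal_window: str
    fertility: pd.DataFrame              # area_id, peak_doy, kappa


def _seasonal_polynomial(config: SimConfig) -> np.ndarray:
    doy = np.arange(1, 366)
    target = config.seasonal_amp * np.cos(
        2.0 * np.pi * (doy - config.seasonal_peak_doy) / 365.0)
    X = np.vander(_rescale_doy(doy), 5, increasing=True)
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    return coef


def simulate_station_network(config: SimConfig) -> StationNetwork:
    """Simulate daily (tmin, tmax) records for a uniform station network."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    lat0, lat1, lon0, lon1 = config.bbox
    lats = rng.uniform(lat0, lat1, config.n_stations)
    lons = rng.uniform(lon0, lon1, config.n_stations)
    ids = [f"S{i:04d}" for i in range(config.n_stations)]

    dates = pd.date_range(f"{config.year_range[0]}-01-01",
                          f"{config.year_range[1]}-12-31", freq="D")
    T = len(dates)
    doy = _doy_array(dates)
    seasonal_coef = _seasonal_polynomial(config)
    season = np.polynomial.polynomial.polyval(_rescale_doy(doy), seasonal_coef)

    if config.weather_sd > 0:
        innov = rng.standard_normal(T) * config.weather_sd * np.sqrt(
            1.0 - config.weather_ar1 ** 2)
        innov[0] = rng.standard_normal() * config.weather_sd
        anomaly = lfilter([1.0], [1.0, -config.weather_ar1], innov)
    else:
        anomaly = np.zeros(T)

    lat_mid = 0.5 * (lat0 + lat1)
    offsets = config.base_temp + config.lat_gradient * (lats - lat_mid)
    half_range = config.diurnal_range / 2.0

    stations = []
    for i, sid in enumerate(ids):
        noise = (rng.standard_normal(T) * config.station_noise_sd
                 if config.station_noise_sd > 0 else np.zeros(T))
        mean = offsets[i] + season + anomaly + noise
        stations.append(StationSeries(
            station_id=sid, lat=float(lats[i]), lon=float(lons[i]),
            records=pd.DataFrame({
                "date": dates,
                "tmin": mean - half_range,
                "tmax": mean + half_range,
            }),
        ))
    return StationNetwork(stations=stations, dates=dates,
                          regional_anomaly=anomaly,
                          seasonal_coef=seasonal_coef,
                          station_offsets=offsets, config=config)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _area_grid(config: SimConfig):
    """Row-major rectangular partition of the bbox into n_areas cells."""
    lat0, lat1, lon0, lon1 = config.bbox
    nrows = max(int(np.floor(np.sqrt(config.n_areas))), 1)
    ncols = int(np.ceil(config.n_areas / nrows))
    cells = []
    dlat = (lat1 - lat0) / nrows
    dlon = (lon1 - lon0) / ncols
    for r in range(nrows):
        for c in range(ncols):
            if len(cells) == config.n_areas:
                break
            cells.append((lat0 + r * dlat, lat0 + (r + 1) * dlat,
                          lon0 + c * dlon, lon0 + (c + 1) * dlon))
    return cells


def simulate_cohort(config: SimConfig, network: StationNetwork,
                    check_radius_km: float = 200.0):
    """Draw a cohort over the simulated network; returns (cohort, truth)."""
    from .exposure import get_window

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])

    cells = _area_grid(config)
    st_lats = np.array([s.lat for s in network.stations])
    st_lons = np.array([s.lon for s in network.stations])
    uncovered = []
    for aid, (la0, la1, lo0, lo1) in enumerate(cells):
        centroid = (0.5 * (la0 + la1), 0.5 * (lo0 + lo1))
        d = np.atleast_1d(geodesic_distance_km(centroid, (st_lats, st_lons)))
        if (d > check_radius_km).all():
            uncovered.append(aid)
    if len(uncovered) == len(cells):
        raise ConfigurationError(
            f"no station within {check_radius_km:.0f} km of any area centroid"
        )
    if uncovered:
        logger.warning(
            "area(s) %s have no station within %.0f km of their centroid; "
            "their participants will carry missing exposures",
            uncovered, check_radius_km,
        )

    n = config.n_participants
    area = rng.integers(0, config.n_areas, n)
    cell_arr = np.array(cells)  # (n_areas, 4)
    u1, u2 = rng.random(n), rng.random(n)
    plat = cell_arr[area, 0] + u1 * (cell_arr[area, 1] - cell_arr[area, 0])
    plon = cell_arr[area, 2] + u2 * (cell_arr[area, 3] - cell_arr[area, 2])

    # area-specific seasonal fertility weighting over conception day-of-year
    peak = config.fertility_peak_doy + rng.uniform(-30, 30, config.n_areas)
    kappa = config.fertility_season_strength * rng.uniform(
        0.5, 1.5, config.n_areas)

    margin = int(np.ceil(6.0 * config.gestation_sd))
    t_first = 35 + margin
    t_last = len(network.dates) - (config.gestation_mean + margin + 1)
    if t_last <= t_first:
        raise ConfigurationError("year_range too short for gestation window")
    valid_t = np.arange(t_first, t_last + 1)
    valid_doy = _doy_array(network.dates[valid_t])

    conception_t = np.empty(n, dtype=int)
    for aid in range(config.n_areas):
        members = np.flatnonzero(area == aid)
        if members.size == 0:
            continue
        w = np.exp(kappa[aid] * np.cos(
            2.0 * np.pi * (valid_doy - peak[aid]) / 365.0))
        conception_t[members] = rng.choice(valid_t, size=members.size,
                                           p=w / w.sum())

    if config.gestation_sd > 0:
        gest = np.rint(rng.normal(config.gestation_mean, config.gestation_sd, n))
        gest = np.clip(gest, config.gestation_mean - margin,
                       config.gestation_mean + margin).astype(int)
    else:
        gest = np.full(n, config.gestation_mean, dtype=int)

    conception = network.dates[conception_t]
    birth = conception + pd.to_timedelta(gest, unit="D")
    sex = rng.integers(0, 2, n)  # 1 = female
    assess = rng.integers(config.assessment_years[0],
                          config.assessment_years[1] + 1, n)

    # true exposure: the shared regional anomaly averaged over the causal
    # window around the *true* conception date
    win = get_window(config.causal_window)
    csum = np.concatenate([[0.0], np.cumsum(network.regional_anomaly)])
    lo = conception_t + win.first_offset
    hi = conception_t + win.last_offset
    true_expo = (csum[hi + 1] - csum[lo]) / win.length

    byear = birth.year.to_numpy()
    bmonth = birth.month.to_numpy()
    year_mid = 0.5 * (config.year_range[0] + config.year_range[1])
    # season-of-birth outcome effect (classic month-of-birth confounder):
    # keyed to calendar birth month — the granularity the area-by-month
    # fixed effects are designed to absorb — and phased to peak 266 days
    # after the conception-season fertility peak
    birth_peak_doy = (config.fertility_peak_doy + config.gestation_mean - 1) % 365 + 1
    birth_peak_month = pd.Timestamp("1963-01-01") + pd.Timedelta(
        days=int(birth_peak_doy) - 1)
    season_shape = np.cos(2.0 * np.pi * (bmonth - birth_peak_month.month) / 12.0)

    cohort = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "birth_date": birth,
        "lat": plat,
        "lon": plon,
        "area_id": area,
        "sex": sex,
        "assessment_year": assess,
    })
    for name in OUTCOME_PARAMS:
        sd = config.outcome_noise_sd[name]
        area_eff = rng.normal(0.0, config.area_effect_sd_frac * sd,
                              config.n_areas)
        season_eff = config.fertility_season_strength * sd * season_shape
        cohort[name] = (
            config.outcome_means[name]
            + area_eff[area]
            + season_eff
            + config.sex_effect_sd_frac * sd * sex
            + config.year_trend_sd_frac * sd * (byear - year_mid)
            + config.true_alpha[name] * true_expo
            + rng.normal(0.0, sd, n)
        )

    truth = GroundTruth(
        true_alpha=dict(config.true_alpha),
        conception_date=conception.values.astype("datetime64[D]"),
        true_window_anomaly=true_expo,
        causal_window=config.causal_window,
        fertility=pd.DataFrame({"area_id": np.arange(config.n_areas),
                                "peak_doy": peak, "kappa": kappa}),
    )
    return cohort, truth
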