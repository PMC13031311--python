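"""Spatial linkage of birthplaces to the station anomaly field.

A birthplace receives a daily anomaly value from surrounding stations by
inverse-distance weighting (IDW) over all stations within a fixed geodesic
radius (default 200 km), with a nearest-neighbor alternative.  Distances are
inverse Vincenty geodesics on the WGS84 ellipsoid.

Weights are renormalized each day over the subset of in-radius stations that
actually report that day, so gaps at one station shift weight to the others
rather than biasing the interpolated value toward zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("periclim.linkage")

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_B = _A * (1.0 - _F)
_MEAN_RADIUS_KM = 6371.0088

_ZERO_DISTANCE_CLAMP_KM = 1e-6


@dataclass
class LinkageConfig:
    """Parameters of the station-to-birthplace linkage."""

    radius_km: float = 200.0
    idw_power: float = 1.0
    min_coverage: float = 0.8
    mode: str = "idw"  # "idw" or "nearest"

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")
        if self.idw_power <= 0:
            raise ValueError("idw_power must be positive")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.mode not in ("idw", "nearest"):
            raise ValueError(f"unknown linkage mode {self.mode!r}")


# ---------------------------------------------------------------------------
# geodesic distance
# ---------------------------------------------------------------------------

def _vincenty_inverse_m(lat1, lon1, lat2, lon2, tol=1e-12, max_iter=200):
    """Vectorised inverse Vincenty distance in metres on WGS84.

    Iterates the longitude-difference fixed point to |Δλ| < ``tol`` or
    ``max_iter`` iterations; pairs that fail to converge (near-antipodal)
    fall back to a great-circle evaluation on the mean Earth radius, with a
    logged warning.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    )
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1.0 - _F) * np.tan(phi1))
    U2 = np.arctan((1.0 - _F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    converged = np.zeros(lam.shape, dtype=bool)
    sinsig = np.zeros_like(lam)
    cossig = np.ones_like(lam)
    sig = np.zeros_like(lam)
    cos2a = np.ones_like(lam)
    cos2sigm = np.zeros_like(lam)

    for _ in range(max_iter):
        sinlam, coslam = np.sin(lam), np.cos(lam)
        sinsig = np.hypot(cosU2 * sinlam, cosU1 * sinU2 - sinU1 * cosU2 * coslam)
        cossig = sinU1 * sinU2 + cosU1 * cosU2 * coslam
        sig = np.arctan2(sinsig, cossig)
        with np.errstate(divide="ignore", invalid="ignore"):
            sina = np.where(sinsig == 0.0, 0.0, cosU1 * cosU2 * sinlam / sinsig)
            cos2a = 1.0 - sina ** 2
            cos2sigm = np.where(
                cos2a == 0.0, 0.0, cossig - 2.0 * sinU1 * sinU2 / np.where(cos2a == 0.0, 1.0, cos2a)
            )
        C = _F / 16.0 * cos2a * (4.0 + _F * (4.0 - 3.0 * cos2a))
        lam_new = L + (1.0 - C) * _F * sina * (
            sig + C * sinsig * (cos2sigm + C * cossig * (-1.0 + 2.0 * cos2sigm ** 2))
        )
        converged |= np.abs(lam_new - lam) < tol
        lam = lam_new
        if converged.all():
            break

    u2 = cos2a * (_A ** 2 - _B ** 2) / _B ** 2
    Acoef = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    Bcoef = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    dsig = Bcoef * sinsig * (
        cos2sigm
        + Bcoef / 4.0 * (
            cossig * (-1.0 + 2.0 * cos2sigm ** 2)
            - Bcoef / 6.0 * cos2sigm * (-3.0 + 4.0 * sinsig ** 2) * (-3.0 + 4.0 * cos2sigm ** 2)
        )
    )
    dist = _B * Acoef * (sig - dsig)

    if not converged.all():
        n_bad = int((~converged).sum())
        logger.warning(
            "Vincenty failed to converge for %d near-antipodal pair(s); "
            "using great-circle fallback", n_bad,
        )
        dphi = phi2 - phi1
        h = (np.sin(dphi / 2.0) ** 2
             + np.cos(phi1) * np.cos(phi2) * np.sin(L / 2.0) ** 2)
        gc = 2.0 * _MEAN_RADIUS_KM * 1000.0 * np.arcsin(np.sqrt(h))
        dist = np.where(converged, dist, gc)

    return np.where(sinsig == 0.0, 0.0, dist)


def geodesic_distance_km(p1, p2) -> float | np.ndarray:
    """Inverse Vincenty (WGS84) distance in km between (lat, lon) points.

    ``p1`` and ``p2`` are (lat, lon) pairs; either component may be an array
    (broadcast).  Symmetric, non-negative, zero for coincident points.
    """
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        la, lo = np.asarray(lat, dtype=float), np.asarray(lon, dtype=float)
        if (np.abs(la) > 90.0).any() or (np.abs(lo) > 180.0).any():
            raise ValueError("coordinates out of range: |lat|<=90, |lon|<=180")
        if not (np.isfinite(la).all() and np.isfinite(lo).all()):
            raise ValueError("coordinates must be finite")
    d = _vincenty_inverse_m(lat1, lon1, lat2, lon2) / 1000.0
    if np.ndim(d) == 0:
        return float(d)
    return d


# ---------------------------------------------------------------------------
# station selection and weights
# ---------------------------------------------------------------------------

def stations_within_radius(loc, stations, radius_km: float = 200.0):
    """Stations within ``radius_km`` (inclusive) of a (lat, lon) location.

    Returns ``[(station, distance_km), ...]`` sorted by ascending distance,
    ties broken by station id.  May be empty.
    """
    if not stations:
        return []
    lats = np.array([s.lat for s in stations])
    lons = np.array([s.lon for s in stations])
    d = geodesic_distance_km((float(loc[0]), float(loc[1])), (lats, lons))
    d = np.atleast_1d(d)
    hits = [
        (s, float(di)) for s, di in zip(stations, d) if di <= radius_km
    ]
    hits.sort(key=lambda t: (t[1], t[0].station_id))
    return hits


def idw_weights(distances, power: float = 1.0) -> np.ndarray:
    """Inverse-distance weights, normalized to sum to exactly 1.

    Distances are clamped below at 1e-6 km so a birthplace coinciding with a
    station effectively receives that station's value.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("idw_weights requires at least one distance")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    w = 1.0 / np.maximum(d, _ZERO_DISTANCE_CLAMP_KM) ** power
    return w / w.sum()


# ---------------------------------------------------------------------------
# anomaly field
# ---------------------------------------------------------------------------

class AnomalyField:
    """Daily station anomalies in matrix form, indexed by day offset.

    Rows are stations (sorted by station id), columns are days since
    ``origin``; missing station-days are NaN.  This is the in-memory source
    the exposure stage interpolates from.
    """

    def __init__(self, station_ids, lats, lons, origin, matrix):
        order = np.argsort(np.asarray(station_ids))
        self.station_ids = np.asarray(station_ids)[order]
        self.lats = np.asarray(lats, dtype=float)[order]
        self.lons = np.asarray(lons, dtype=float)[order]
        self.origin = np.datetime64(origin, "D")
        self.matrix = np.asarray(matrix, dtype=float)[order]

    @classmethod
    def from_deviations(cls, deviations, coords, origin=None, end=None):
        """Assemble a field from per-station :class:`DeviationSeries`.

        ``coords`` maps station_id -> (lat, lon).  ``origin``/``end`` default
        to the overall date range of the deviations.
        """
        if not deviations:
            raise ValueError("no deviation series supplied")
        starts = [d.entries.index.min() for d in deviations if len(d.entries)]
        stops = [d.entries.index.max() for d in deviations if len(d.entries)]
        origin = np.datetime64(origin or min(starts), "D")
        end = np.datetime64(end or max(stops), "D")
        T = int((end - origin) / np.timedelta64(1, "D")) + 1
        ids, lats, lons = [], [], []
        mat = np.full((len(deviations), T), np.nan)
        for i, dev in enumerate(deviations):
            lat, lon = coords[dev.station_id]
            ids.append(dev.station_id)
            lats.append(lat)
            lons.append(lon)
            if len(dev.entries):
                t = ((dev.entries.index.values.astype("datetime64[D]") - origin)
                     / np.timedelta64(1, "D")).astype(int)
                ok = (t >= 0) & (t < T)
                mat[i, t[ok]] = dev.entries.to_numpy()[ok]
        return cls(ids, lats, lons, origin, mat)

    @property
    def n_days(self) -> int:
        return self.matrix.shape[1]

    def day_index(self, date) -> int:
        return int((np.datetime64(pd.Timestamp(date).date(), "D") - self.origin)
                   / np.timedelta64(1, "D"))


def interpolate_daily_anomaly(loc, date, field: AnomalyField,
                              config: LinkageConfig | None = None):
    """Anomaly (°C) at a point location on one date, or None if unavailable.

    IDW mode: weights 1/d^p over in-radius stations reporting that date,
    renormalized over that subset.  Nearest mode: the value of the closest
    reporting in-radius station (ties to the smallest station id).  Returns
    None when no in-radius station reports the date.
    """
    config = config or LinkageConfig()
    t = field.day_index(date)
    if t < 0 or t >= field.n_days:
        return None
    d = np.atleast_1d(
        geodesic_distance_km((float(loc[0]), float(loc[1])),
                             (field.lats, field.lons))
    )
    vals = field.matrix[:, t]
    ok = (d <= config.radius_km) & np.isfinite(vals)
    if not ok.any():
        return None
    if config.mode == "nearest":
        # station ids are sorted, argmin returns the smallest id on ties
        i = np.flatnonzero(ok)[np.argmin(d[ok])]
        return float(vals[i])
    w = idw_weights(d[ok], config.idw_power)
    return float(w @ vals[ok])
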