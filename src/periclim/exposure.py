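"""Periconceptional exposure windows and mean anomaly computation.

The estimated date of conception (DOC) is the birth date minus 266 days,
the average human gestation length.  Mean temperature anomalies are computed
over five windows of days relative to the estimated DOC:

===========  ==================  ======
label        day offsets         length
===========  ==================  ======
DOC          {0}                     1
-2w;DOC      [-14, -1]              14
-3w;+1w      [-21, +6]              28
-4w;+2w      [-28, +13]             42
-5w;+3w      [-35, +20]             56
===========  ==================  ======

Windows are whole weeks, half-open at the DOC day ("till DOC" excludes the
conception day itself), which is the only convention under which a +1 °C
anomaly confined to the 14 pre-conception days averages to exactly +0.25 °C
over the 8-week window.  Days are equally weighted; days with no in-radius
reporting station are skipped and the mean renormalized, subject to a
minimum coverage fraction below which the exposure is set missing.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import AnomalyField, LinkageConfig, geodesic_distance_km, \
    interpolate_daily_anomaly

logger = logging.getLogger("periclim.exposure")

GESTATION_DAYS = 266

_WINDOW_OFFSETS = {
    "DOC": (0, 0),
    "-2w;DOC": (-14, -1),
    "-3w;+1w": (-21, 6),
    "-4w;+2w": (-28, 13),
    "-5w;+3w": (-35, 20),
}
WINDOW_LABELS = tuple(_WINDOW_OFFSETS)


@dataclass(frozen=True)
class ExposureWindow:
    """A contiguous range of days relative to the estimated DOC."""

    label: str
    first_offset: int
    last_offset: int

    @property
    def day_offsets(self) -> np.ndarray:
        return np.arange(self.first_offset, self.last_offset + 1)

    @property
    def length(self) -> int:
        return self.last_offset - self.first_offset + 1


def get_window(label: str) -> ExposureWindow:
    try:
        lo, hi = _WINDOW_OFFSETS[label]
    except KeyError:
        raise ValueError(
            f"unknown exposure window {label!r}; expected one of {WINDOW_LABELS}"
        ) from None
    return ExposureWindow(label, lo, hi)


def estimate_doc(birth_date):
    """Estimated date of conception: birth date minus 266 calendar days."""
    if isinstance(birth_date, (pd.Series, pd.DatetimeIndex, np.ndarray)):
        return pd.to_datetime(birth_date) - pd.Timedelta(days=GESTATION_DAYS)
    return pd.Timestamp(birth_date) - pd.Timedelta(days=GESTATION_DAYS)


def window_dates(window: ExposureWindow, doc) -> list:
    """The contiguous calendar dates a window covers around a DOC."""
    doc = pd.Timestamp(doc)
    return [doc + pd.Timedelta(days=int(k)) for k in window.day_offsets]


def mean_window_anomaly(loc, doc, window: ExposureWindow, field: AnomalyField,
                        config: LinkageConfig | None = None):
    """Equal-weight mean anomaly over a window at one birthplace.

    Returns ``(mean_or_nan, coverage)``: missing days are skipped, coverage
    is the reported fraction of the window, and the mean is NaN when
    coverage falls below ``config.min_coverage``.
    """
    config = config or LinkageConfig()
    vals = [interpolate_daily_anomaly(loc, d, field, config)
            for d in window_dates(window, doc)]
    present = [v for v in vals if v is not None]
    coverage = len(present) / window.length
    if not present or coverage < config.min_coverage:
        return float("nan"), coverage
    return float(np.mean(present)), coverage


# ---------------------------------------------------------------------------
# bulk computation
# ---------------------------------------------------------------------------

def _bulk_window_means(field: AnomalyField, lats, lons, doc_idx,
                       window: ExposureWindow, config: LinkageConfig,
                       chunk: int = 4000):
    """Vectorised equivalent of :func:`mean_window_anomaly` over a cohort.

    Identical, per participant, to looping interpolate_daily_anomaly over
    the window dates (a test asserts this); organized as chunked array
    arithmetic so large cohorts stay fast.
    """
    n = len(doc_idx)
    S, T = field.matrix.shape
    offsets = window.day_offsets
    L = window.length

    d = geodesic_distance_km(
        (np.asarray(lats, dtype=float)[:, None], np.asarray(lons, dtype=float)[:, None]),
        (field.lats[None, :], field.lons[None, :]),
    )  # (n, S)
    inrad = d <= config.radius_km
    raw_w = np.where(
        inrad, 1.0 / np.maximum(d, 1e-6) ** config.idw_power, 0.0
    )

    values = np.full(n, np.nan)
    coverage = np.zeros(n)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        idx = np.asarray(doc_idx[a:b])[:, None] + offsets[None, :]  # (nc, L)
        in_time = (idx >= 0) & (idx < T)
        ci = np.clip(idx, 0, T - 1)
        V = field.matrix[:, ci]  # (S, nc, L)
        M = np.isfinite(V) & in_time[None, :, :] & inrad[a:b].T[:, :, None]
        if config.mode == "nearest":
            dm = np.where(M, d[a:b].T[:, :, None], np.inf)
            best = np.argmin(dm, axis=0)  # (nc, L)
            day_ok = np.isfinite(np.min(dm, axis=0))
            day_val = np.take_along_axis(
                V, best[None, :, :], axis=0
            )[0]
        else:
            W = raw_w[a:b].T  # (S, nc)
            num = np.einsum("sn,snl->nl", W, np.where(M, V, 0.0))
            den = np.einsum("sn,snl->nl", W, M.astype(float))
            day_ok = den > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                day_val = num / den
        cnt = day_ok.sum(axis=1)
        cov = cnt / L
        with np.errstate(invalid="ignore"):
            means = np.where(
                cnt > 0,
                np.where(day_ok, day_val, 0.0).sum(axis=1) / np.maximum(cnt, 1),
                np.nan,
            )
        means = np.where(cov >= config.min_coverage, means, np.nan)
        values[a:b] = means
        coverage[a:b] = cov
    return values, coverage


def build_exposure_table(cohort: pd.DataFrame, field: AnomalyField,
                         windows=None, config: LinkageConfig | None = None
                         ) -> pd.DataFrame:
    """Per-participant mean anomaly and coverage for each exposure window.

    ``cohort`` needs columns participant_id, birth_date, lat, lon.  Output is
    long form: participant_id, window, exposure, coverage — one row per
    participant per window, deterministic given inputs.  Participants with no
    in-radius station keep their rows with missing exposure (coverage 0).
    """
    config = config or LinkageConfig()
    labels = list(windows) if windows is not None else list(WINDOW_LABELS)
    docs = estimate_doc(pd.to_datetime(cohort["birth_date"]))
    doc_idx = ((docs.values.astype("datetime64[D]") - field.origin)
               / np.timedelta64(1, "D")).astype(int)
    lats = cohort["lat"].to_numpy()
    lons = cohort["lon"].to_numpy()

    frames = []
    for label in labels:
        win = get_window(label) if isinstance(label, str) else label
        vals, cov = _bulk_window_means(field, lats, lons, doc_idx, win, config)
        frames.append(pd.DataFrame({
            "participant_id": cohort["participant_id"].to_numpy(),
            "window": win.label,
            "exposure": vals,
            "coverage": cov,
        }))
    out = pd.concat(frames, ignore_index=True)
    n_unlinked = int((out.groupby("participant_id")["coverage"].max() == 0).sum())
    if n_unlinked:
        logger.warning("%d participant(s) have no in-radius station on any "
                       "window day", n_unlinked)
    return out
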