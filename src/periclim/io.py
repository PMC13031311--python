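"""Readers, writers, run configuration and the end-to-end pipeline driver.

All interchange formats are plain delimited text with ISO-8601 dates:

* stations:   ``station_id,lat,lon,date,tmin,tmax``
* cohort:     ``participant_id,birth_date,lat,lon,area_id,sex,
  assessment_year,<outcomes...>[,unmappable,adopted]``
* deviations: ``station_id,date,deviation``
* exposures:  ``participant_id,window,exposure,coverage``
* results:    ``outcome,window,family,stratum,alpha,se,raw_p,holm_p,n,clusters``

The driver executes climatology -> deviations -> linkage -> exposure ->
inference -> scenarios, writes a machine-readable manifest (config, seed,
input checksums) and a human-readable run report, and is deterministic
given its seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climatology import (DEFAULT_MIN_DAYS_PER_YEAR, DEFAULT_MIN_YEARS,
                          DEFAULT_PERIOD, StationSeries, compute_deviations,
                          fit_station_climatology, station_is_eligible)
from .exposure import WINDOW_LABELS, build_exposure_table
from .inference import SuiteConfig, run_analysis_suite
from .linkage import AnomalyField, LinkageConfig
from .scenarios import ScenarioSpec, scenario_table

logger = logging.getLogger("periclim.io")

STATION_COLUMNS = ["station_id", "lat", "lon", "date", "tmin", "tmax"]
COHORT_REQUIRED = ["participant_id", "birth_date", "lat", "lon", "area_id",
                   "sex", "assessment_year"]


class SchemaError(ValueError):
    """An input file does not match its expected column schema."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_station_table(path) -> tuple[list[StationSeries], dict]:
    """Read daily station records; returns (stations, accounting).

    Malformed rows (unparseable dates or temperatures, tmin > tmax,
    duplicate station-dates — later row loses) are skipped with logged
    counts rather than aborting the run.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"station table {path} missing columns: {missing}")

    n0 = len(df)
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    for c in ("lat", "lon", "tmin", "tmax"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    parsed = df.dropna(subset=["date", "lat", "lon", "tmin", "tmax"])
    n_malformed = n0 - len(parsed)

    ok = parsed["tmin"] <= parsed["tmax"]
    n_inverted = int((~ok).sum())
    parsed = parsed[ok]

    dup = parsed.duplicated(["station_id", "date"], keep="first")
    n_dup = int(dup.sum())
    parsed = parsed[~dup]

    for name, count in (("malformed", n_malformed),
                        ("tmin>tmax", n_inverted),
                        ("duplicate station-date", n_dup)):
        if count:
            logger.warning("station table %s: skipped %d %s row(s)",
                           path, count, name)

    stations = []
    for sid, grp in parsed.groupby("station_id", sort=True):
        stations.append(StationSeries(
            station_id=str(sid),
            lat=float(grp["lat"].iloc[0]),
            lon=float(grp["lon"].iloc[0]),
            records=grp[["date", "tmin", "tmax"]].reset_index(drop=True),
        ))
    accounting = {"rows": n0, "malformed": n_malformed,
                  "tmin_gt_tmax": n_inverted, "duplicates": n_dup,
                  "stations": len(stations)}
    return stations, accounting


def sample_accounting(initial: int, exclusions: dict) -> dict:
    """Exclusion bookkeeping: retained = initial - sum(exclusions)."""
    retained = initial - sum(exclusions.values())
    out = {"initial": initial, **exclusions, "retained": retained}
    assert out["retained"] == initial - sum(exclusions.values())
    return out


def read_cohort_table(path) -> tuple[pd.DataFrame, dict]:
    """Read the cohort; apply exclusion flags and return (table, accounting).

    Rows flagged ``unmappable`` (birthplace could not be located) or
    ``adopted`` are removed and counted, mirroring the sample-construction
    arithmetic of observational birth-cohort studies.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table {path} missing columns: {missing}")

    n0 = len(df)
    df["birth_date"] = pd.to_datetime(df["birth_date"], errors="coerce")
    n_baddate = int(df["birth_date"].isna().sum())
    if n_baddate:
        logger.warning("cohort table %s: dropped %d row(s) with unparseable "
                       "birth dates", path, n_baddate)
    df = df.dropna(subset=["birth_date"])

    exclusions = {"unparseable_birth_date": n_baddate}
    for flag in ("unmappable", "adopted"):
        if flag in df.columns:
            flagged = df[flag].fillna(0).astype(int).astype(bool)
            exclusions[flag] = int(flagged.sum())
            df = df[~flagged].drop(columns=[flag])
        else:
            exclusions[flag] = 0
    acct = sample_accounting(n0, exclusions)
    if acct["retained"] == 0:
        logger.warning("cohort table %s: all rows excluded", path)
    return df.reset_index(drop=True), acct


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_station_table(stations, path) -> None:
    frames = []
    for s in stations:
        f = s.records.copy()
        f.insert(0, "station_id", s.station_id)
        f.insert(1, "lat", s.lat)
        f.insert(2, "lon", s.lon)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.4f")


def write_deviations(deviations, path) -> None:
    frames = []
    for dev in deviations:
        frames.append(pd.DataFrame({
            "station_id": dev.station_id,
            "date": dev.entries.index.strftime("%Y-%m-%d"),
            "deviation": dev.entries.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


def read_deviations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in ("station_id", "date", "deviation")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"deviations file {path} missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def anomaly_field_from_deviations_frame(df: pd.DataFrame,
                                        coords: dict) -> AnomalyField:
    """Assemble an :class:`AnomalyField` from a long deviations frame."""
    from .climatology import DeviationSeries
    devs = []
    for sid, grp in df.groupby("station_id", sort=True):
        devs.append(DeviationSeries(
            station_id=str(sid),
            entries=pd.Series(grp["deviation"].to_numpy(),
                              index=pd.DatetimeIndex(grp["date"])),
        ))
    return AnomalyField.from_deviations(devs, coords)


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["birth_date"] = pd.to_datetime(out["birth_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6f")


def write_ground_truth(truth, path_prefix) -> None:
    """Sidecar ground-truth files, clearly named as test-only artifacts."""
    prefix = Path(path_prefix)
    per_part = pd.DataFrame({
        "conception_date": pd.DatetimeIndex(truth.conception_date
                                            ).strftime("%Y-%m-%d"),
        "true_window_anomaly": truth.true_window_anomaly,
    })
    per_part.to_csv(f"{prefix}_ground_truth_test_only.csv", index=False,
                    float_format="%.6f")
    meta = {"true_alpha": truth.true_alpha,
            "causal_window": truth.causal_window}
    with open(f"{prefix}_ground_truth_test_only.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    truth.fertility.to_csv(f"{prefix}_fertility_ground_truth_test_only.csv",
                           index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    stations_path: str = "stations.csv"
    cohort_path: str = "cohort.csv"
    outdir: str = "periclim_out"
    linkage: LinkageConfig = dc_field(default_factory=LinkageConfig)
    windows: tuple = WINDOW_LABELS
    fit_period: tuple = DEFAULT_PERIOD
    min_years: int = DEFAULT_MIN_YEARS
    min_days_per_year: int = DEFAULT_MIN_DAYS_PER_YEAR
    suite: SuiteConfig = dc_field(default_factory=SuiteConfig)
    scenario: ScenarioSpec = dc_field(default_factory=ScenarioSpec)
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["suite"].pop("cutoffs", None)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "linkage" in d:
            d["linkage"] = LinkageConfig(**d["linkage"])
        if "suite" in d:
            d["suite"] = SuiteConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in d["suite"].items()})
        if "scenario" in d:
            d["scenario"] = ScenarioSpec(**d["scenario"])
        for key in ("windows", "fit_period", "year_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write its artifacts to ``outdir``.

    Stages: station ingest and eligibility -> per-station climatology and
    deviations -> anomaly field -> cohort ingest with exclusion accounting
    -> exposure table -> regression suite (Holm per window) -> scenario
    table.  A manifest (config + seed + input checksums + version) and a
    run report are written alongside the outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = []

    def stage(msg):
        logger.info(msg)
        report.append(msg)

    try:
        stations, st_acct = read_station_table(config.stations_path)
        stage(f"stations: read {st_acct['stations']} station(s), "
              f"{st_acct['rows']} rows "
              f"(skipped {st_acct['malformed']} malformed, "
              f"{st_acct['tmin_gt_tmax']} tmin>tmax, "
              f"{st_acct['duplicates']} duplicates)")
        eligible = [s for s in stations if station_is_eligible(
            s, config.fit_period, config.min_years, config.min_days_per_year)]
        stage(f"eligibility: {len(eligible)}/{len(stations)} stations have "
              f">= {config.min_years} year(s) of data in "
              f"{config.fit_period[0]}-{config.fit_period[1]}")
        if not eligible:
            raise RuntimeError("no eligible stations")

        models = [fit_station_climatology(s, config.fit_period)
                  for s in eligible]
        deviations = [compute_deviations(s, m)
                      for s, m in zip(eligible, models)]
        stage(f"climatology: fitted {len(models)} degree-4 models; "
              f"median residual SD "
              f"{np.median([m.residual_sd for m in models]):.2f} °C")
        write_deviations(deviations, outdir / "deviations.csv")

        coords = {s.station_id: (s.lat, s.lon) for s in eligible}
        field = AnomalyField.from_deviations(deviations, coords)
    except Exception as exc:
        raise RuntimeError(f"climatology stage failed: {exc}") from exc

    try:
        cohort, acct = read_cohort_table(config.cohort_path)
        stage(f"cohort: {acct['initial']} rows read, "
              f"{acct['retained']} retained after exclusions "
              f"({ {k: v for k, v in acct.items() if k not in ('initial', 'retained')} })")
    except Exception as exc:
        raise RuntimeError(f"cohort stage failed: {exc}") from exc

    try:
        exposures = build_exposure_table(cohort, field, config.windows,
                                         config.linkage)
        exposures.to_csv(outdir / "exposures.csv", index=False,
                         float_format="%.6f")
        n_missing = int(exposures["exposure"].isna().sum())
        stage(f"exposure: {len(exposures)} rows "
              f"({n_missing} below min coverage "
              f"{config.linkage.min_coverage:.2f}); mode={config.linkage.mode}")
    except Exception as exc:
        raise RuntimeError(f"exposure stage failed: {exc}") from exc

    try:
        results = run_analysis_suite(cohort, exposures, config.suite)
        results.to_csv(outdir / "results.csv", index=False,
                       float_format="%.6g")
        stage(f"inference: {len(results)} model(s) fitted, "
              f"{len(results.attrs.get('failures', []))} failure(s)")
    except Exception as exc:
        raise RuntimeError(f"inference stage failed: {exc}") from exc

    try:
        sds = {k: float(cohort[k].std(ddof=1)) for k in
               config.suite.continuous_outcomes if k in cohort.columns}
        scen = scenario_table(results, sds, config.scenario)
        scen.to_csv(outdir / "scenarios.csv", index=False,
                    float_format="%.6g")
        stage(f"scenarios: {len(scen)} row(s) at delta_t="
              f"{config.scenario.delta_t} °C")
    except Exception as exc:
        raise RuntimeError(f"scenario stage failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            "stations": {"path": str(config.stations_path),
                         "sha256": _checksum(config.stations_path)},
            "cohort": {"path": str(config.cohort_path),
                       "sha256": _checksum(config.cohort_path)},
        },
        "cohort_accounting": acct,
        "station_accounting": st_acct,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    (outdir / "report.txt").write_text("\n".join(report) + "\n")

    return {"results": results, "exposures": exposures, "scenarios": scen,
            "manifest": manifest, "field": field, "outdir": outdir}
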