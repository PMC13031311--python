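"""Fixed-effects regression of metabolic outcomes on periconceptional anomalies.

The core model regresses an adult metabolic outcome on the mean temperature
anomaly around estimated conception, absorbing area-by-birth-month fixed
effects and controlling for sex, year of birth, and year of assessment:

    y_irt = alpha * TempDev_irt + gamma_rm + x_irt' beta + e_irt

Linear models are estimated by OLS with the fixed effects absorbed via the
within transformation (numerically identical to dummy-variable OLS), with
CR1 cluster-robust standard errors at the administrative-area level and
p-values from a t distribution on (clusters - 1) degrees of freedom.
Binary risk indicators use maximum-likelihood logit with explicit fixed-effect
dummy columns and the analogous clustered sandwich.  Families of five
outcomes per exposure window are corrected with the Holm step-down.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

logger = logging.getLogger("periclim.inference")

CONTINUOUS_OUTCOMES = (
    "bmi", "waist_circumference", "hba1c", "triglycerides", "cholesterol",
)
BINARY_OUTCOMES = (
    "overweight", "high_wc", "high_hba1c", "high_triglycerides",
    "high_cholesterol",
)


class IdentificationError(RuntimeError):
    """The exposure coefficient is not identified in this design."""


class ClusterError(RuntimeError):
    """Clustered inference is not possible (fewer than two clusters)."""


# ---------------------------------------------------------------------------
# binary cutoffs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryCutoffs:
    """Risk thresholds (applied with >=) for the five metabolic outcomes.

    Overweight BMI >= 25 kg/m²; high waist circumference >= 94 cm (male) /
    >= 80 cm (female); high HbA1c >= 39 mmol/mol; high triglycerides
    >= 1.7 mmol/l; high cholesterol >= 5.2 mmol/l.
    """

    bmi: float = 25.0
    wc_male: float = 94.0
    wc_female: float = 80.0
    hba1c: float = 39.0
    triglycerides: float = 1.7
    cholesterol: float = 5.2


def binarize_outcomes(row, cutoffs: BinaryCutoffs | None = None) -> dict:
    """Five risk flags for one participant record (mapping-like).

    ``sex`` is 1 for female, 0 for male; it is required whenever a waist
    circumference value is present.  Missing values yield missing flags.
    """
    c = cutoffs or BinaryCutoffs()

    def flag(value, threshold):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return bool(value >= threshold)

    wc = row.get("waist_circumference")
    if wc is not None and not (isinstance(wc, float) and np.isnan(wc)):
        sex = row.get("sex")
        if sex is None or (isinstance(sex, float) and np.isnan(sex)):
            raise ValueError("sex is required to binarize waist circumference")
        wc_flag = bool(wc >= (c.wc_female if int(sex) == 1 else c.wc_male))
    else:
        wc_flag = None
    return {
        "overweight": flag(row.get("bmi"), c.bmi),
        "high_wc": wc_flag,
        "high_hba1c": flag(row.get("hba1c"), c.hba1c),
        "high_triglycerides": flag(row.get("triglycerides"), c.triglycerides),
        "high_cholesterol": flag(row.get("cholesterol"), c.cholesterol),
    }


def binarize_cohort(cohort: pd.DataFrame,
                    cutoffs: BinaryCutoffs | None = None) -> pd.DataFrame:
    """Vectorised :func:`binarize_outcomes`: adds the five flag columns."""
    c = cutoffs or BinaryCutoffs()
    out = cohort.copy()
    out["overweight"] = (cohort["bmi"] >= c.bmi).where(cohort["bmi"].notna())
    thr = np.where(cohort["sex"].to_numpy() == 1, c.wc_female, c.wc_male)
    out["high_wc"] = (cohort["waist_circumference"] >= thr).where(
        cohort["waist_circumference"].notna())
    out["high_hba1c"] = (cohort["hba1c"] >= c.hba1c).where(cohort["hba1c"].notna())
    out["high_triglycerides"] = (cohort["triglycerides"] >= c.triglycerides
                                 ).where(cohort["triglycerides"].notna())
    out["high_cholesterol"] = (cohort["cholesterol"] >= c.cholesterol
                               ).where(cohort["cholesterol"].notna())
    return out


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    outcome: str
    window: str
    family: str = "linear"           # "linear" or "logistic"
    fe: str = "area_by_month"        # or "month_by_year_plus_area"
    covariates: tuple = ("sex", "birth_year", "assessment_year")
    cluster: str = "area_id"


@dataclass
class DesignBundle:
    """Assembled regression inputs: response, regressors, FE and clusters."""

    y: np.ndarray
    X: np.ndarray                    # first column is the exposure
    colnames: list
    fe_codes: np.ndarray
    n_fe: int
    cluster_codes: np.ndarray
    n_clusters: int
    n_dropped: int
    spec: ModelSpec = None
    fe_labels: np.ndarray = dc_field(default=None, repr=False)


def build_design(cohort: pd.DataFrame, exposure_table: pd.DataFrame,
                 spec: ModelSpec) -> DesignBundle:
    """Merge exposure into the cohort and encode the regression design.

    Rows with a missing outcome, exposure, or covariate are dropped (and
    counted).  The fixed effect is encoded as integer cell codes for the
    within transformation; covariates enter as dummy columns with one
    reference level each.
    """
    expo = exposure_table[exposure_table["window"] == spec.window]
    df = cohort.merge(expo[["participant_id", "exposure"]], on="participant_id",
                      how="inner")
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["birth_year"] = df["birth_date"].dt.year
    df["birth_month"] = df["birth_date"].dt.month

    needed = [spec.outcome, "exposure", "area_id", "birth_month", "birth_year",
              "assessment_year", "sex"]
    n0 = len(df)
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    df = df.reset_index(drop=True)
    n_dropped = n0 - len(df)
    if len(df) == 0:
        raise ValueError("no usable rows after dropping missing values")

    if spec.fe == "area_by_month":
        fe_key = list(zip(df["area_id"].to_numpy(), df["birth_month"].to_numpy()))
        extra = []
    elif spec.fe == "month_by_year_plus_area":
        fe_key = list(zip(df["birth_month"].to_numpy(), df["birth_year"].to_numpy()))
        extra = [pd.get_dummies(df["area_id"], prefix="area",
                                drop_first=True, dtype=float)]
    else:
        raise ValueError(f"unknown FE scheme {spec.fe!r}")
    fe_codes, fe_labels = pd.factorize(pd.Series(fe_key))

    cols = [pd.Series(df["exposure"].to_numpy(), name="exposure")]
    if "sex" in spec.covariates:
        cols.append(pd.Series(df["sex"].to_numpy().astype(float), name="female"))
    if "birth_year" in spec.covariates and spec.fe != "month_by_year_plus_area":
        cols.append(pd.get_dummies(df["birth_year"], prefix="yob",
                                   drop_first=True, dtype=float))
    if "assessment_year" in spec.covariates:
        cols.append(pd.get_dummies(df["assessment_year"], prefix="yoa",
                                   drop_first=True, dtype=float))
    cols.extend(extra)
    Xdf = pd.concat(cols, axis=1)

    y = df[spec.outcome].to_numpy(dtype=float)
    cluster_codes, clusters = pd.factorize(df[spec.cluster])
    return DesignBundle(
        y=y,
        X=Xdf.to_numpy(dtype=float),
        colnames=list(Xdf.columns),
        fe_codes=np.asarray(fe_codes),
        n_fe=len(fe_labels),
        cluster_codes=np.asarray(cluster_codes),
        n_clusters=len(clusters),
        n_dropped=n_dropped,
        spec=spec,
        fe_labels=np.asarray(fe_labels, dtype=object),
    )


def _demean_by_group(a: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if a.ndim == 1:
        sums = np.bincount(codes, weights=a, minlength=n_groups)
        return a - (sums / counts)[codes]
    out = np.empty_like(a, dtype=float)
    for j in range(a.shape[1]):
        sums = np.bincount(codes, weights=a[:, j], minlength=n_groups)
        out[:, j] = a[:, j] - (sums / counts)[codes]
    return out


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    alpha: float                     # outcome units (or log-odds) per °C
    se_cluster: float
    raw_p: float
    holm_p: float | None
    n_obs: int
    n_clusters: int
    family: str
    window: str
    outcome: str
    params: np.ndarray = dc_field(default=None, repr=False)
    colnames: list = dc_field(default=None, repr=False)


# ---------------------------------------------------------------------------
# linear FE estimation
# ---------------------------------------------------------------------------

def cluster_robust_cov(X: np.ndarray, resid: np.ndarray, cluster_codes,
                       n_params: int | None = None) -> np.ndarray:
    """CR1 cluster-robust covariance of OLS coefficients.

    (X'X)^{-1} [ sum_g X_g' e_g e_g' X_g ] (X'X)^{-1} scaled by
    G/(G-1) * (N-1)/(N-K).  ``n_params`` is K; pass the full parameter count
    (including any absorbed fixed effects) so the small-sample correction
    matches the equivalent dummy-variable regression.
    """
    codes = np.asarray(cluster_codes)
    G = len(np.unique(codes))
    if G < 2:
        raise ClusterError(
            "cluster-robust errors need >= 2 clusters; with a single cluster "
            "fall back to heteroskedasticity-robust (HC1) errors"
        )
    N, k = X.shape
    K = n_params if n_params is not None else k
    Xe = X * resid[:, None]
    # sum over clusters of the score vectors, then outer products
    scores = np.zeros((G, k))
    codes_c = pd.factorize(codes)[0]
    for j in range(k):
        scores[:, j] = np.bincount(codes_c, weights=Xe[:, j], minlength=G)
    meat = scores.T @ scores
    bread = np.linalg.pinv(X.T @ X)
    scale = (G / (G - 1.0)) * ((N - 1.0) / (N - K))
    return scale * bread @ meat @ bread


def cluster_robust_se(X: np.ndarray, resid: np.ndarray, cluster_codes,
                      n_params: int | None = None) -> float:
    """CR1 standard error of the first (exposure) coefficient."""
    V = cluster_robust_cov(X, resid, cluster_codes, n_params)
    return float(np.sqrt(V[0, 0]))


def fit_linear_fe(design: DesignBundle) -> RegressionResult:
    """OLS with fixed effects absorbed by the within transformation.

    Numerically equal to dummy-variable OLS on the same data; standard
    errors are CR1-clustered, and the p-value uses a t distribution with
    (clusters - 1) degrees of freedom.
    """
    from scipy import stats

    yt = _demean_by_group(design.y, design.fe_codes, design.n_fe)
    Xt = _demean_by_group(design.X, design.fe_codes, design.n_fe)
    if np.std(Xt[:, 0]) < 1e-12:
        raise IdentificationError(
            "exposure is constant within every fixed-effect cell"
        )
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    K = design.X.shape[1] + design.n_fe
    V = cluster_robust_cov(Xt, resid, design.cluster_codes, n_params=K)
    se = float(np.sqrt(V[0, 0]))
    t = beta[0] / se
    p = 2.0 * stats.t.sf(abs(t), df=design.n_clusters - 1)
    spec = design.spec or ModelSpec("", "")
    return RegressionResult(
        alpha=float(beta[0]), se_cluster=se, raw_p=float(p), holm_p=None,
        n_obs=len(design.y), n_clusters=design.n_clusters, family="linear",
        window=spec.window, outcome=spec.outcome,
        params=beta, colnames=design.colnames,
    )


# ---------------------------------------------------------------------------
# logistic FE estimation
# ---------------------------------------------------------------------------

def fit_logistic_fe(design: DesignBundle) -> RegressionResult:
    """Maximum-likelihood logit with explicit fixed-effect dummy columns.

    Cells whose outcome is constant contribute nothing to the likelihood
    once their dummy is free, so their rows are dropped (with a logged
    count) before fitting.  Standard errors are cluster-robust sandwiches.
    """
    import statsmodels.api as sm

    y = design.y.astype(float)
    cell_mean = np.bincount(design.fe_codes, weights=y,
                            minlength=design.n_fe) / np.maximum(
        np.bincount(design.fe_codes, minlength=design.n_fe), 1)
    varying = (cell_mean > 0) & (cell_mean < 1)
    keep = varying[design.fe_codes]
    n_drop = int((~keep).sum())
    if not keep.any():
        raise IdentificationError("no fixed-effect cell has outcome variation")
    if n_drop:
        logger.info("logit: dropped %d row(s) in outcome-constant cells", n_drop)

    y = y[keep]
    X = design.X[keep]
    fe = pd.factorize(design.fe_codes[keep])[0]
    clusters = design.cluster_codes[keep]
    n_cells = fe.max() + 1
    avg_cell = len(y) / n_cells
    if avg_cell < 20:
        logger.warning(
            "logit: average FE cell size %.1f < 20; incidental-parameter "
            "bias may be non-negligible", avg_cell,
        )
    fe_dummies = np.zeros((len(y), n_cells - 1))
    pos = fe - 1
    rows = np.flatnonzero(pos >= 0)
    fe_dummies[rows, pos[rows]] = 1.0
    full = np.column_stack([X, fe_dummies, np.ones(len(y))])

    model = sm.Logit(y, full)
    try:
        res = model.fit(disp=0, method="newton", maxiter=100,
                        cov_type="cluster",
                        cov_kwds={"groups": clusters})
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("newton did not converge")
    except Exception:
        res = model.fit(disp=0, method="lbfgs", maxiter=500,
                        cov_type="cluster",
                        cov_kwds={"groups": clusters})
    spec = design.spec or ModelSpec("", "")
    return RegressionResult(
        alpha=float(res.params[0]), se_cluster=float(res.bse[0]),
        raw_p=float(res.pvalues[0]), holm_p=None, n_obs=int(len(y)),
        n_clusters=int(len(np.unique(clusters))), family="logistic",
        window=spec.window, outcome=spec.outcome,
        params=np.asarray(res.params), colnames=None,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def holm_correct(p_values) -> np.ndarray:
    """Holm (Bonferroni step-down) corrected p-values, input order preserved.

    Sorted ascending, p_(j) is multiplied by (m - j + 1), capped at 1, and a
    running maximum enforces monotonicity before mapping back.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        out[idx] = running
    return out


# ---------------------------------------------------------------------------
# analysis suite
# ---------------------------------------------------------------------------

@dataclass
class SuiteConfig:
    """What the full analysis run estimates beyond the core linear grid."""

    windows: tuple = ("DOC", "-2w;DOC", "-3w;+1w", "-4w;+2w", "-5w;+3w")
    continuous_outcomes: tuple = CONTINUOUS_OUTCOMES
    binary: bool = False
    strata: tuple = ()               # subset of {"female","male","winter","oct_dec","jan_mar"}
    alt_fe: bool = False
    n_negative_controls: int = 0
    seed: int = 0
    cutoffs: BinaryCutoffs = dc_field(default_factory=BinaryCutoffs)


_STRATA = {
    "female": lambda df: df["sex"] == 1,
    "male": lambda df: df["sex"] == 0,
    "winter": lambda df: df["doc_month"].isin([10, 11, 12, 1, 2, 3]),
    "oct_dec": lambda df: df["doc_month"].isin([10, 11, 12]),
    "jan_mar": lambda df: df["doc_month"].isin([1, 2, 3]),
}


def _result_row(res: RegressionResult, stratum: str) -> dict:
    return {
        "outcome": res.outcome, "window": res.window, "family": res.family,
        "stratum": stratum, "alpha": res.alpha, "se": res.se_cluster,
        "raw_p": res.raw_p, "holm_p": res.holm_p, "n": res.n_obs,
        "clusters": res.n_clusters,
    }


def run_analysis_suite(cohort: pd.DataFrame, exposure_table: pd.DataFrame,
                       config: SuiteConfig | None = None) -> pd.DataFrame:
    """Fit the full grid of models and return one tidy results table.

    Linear models for every window x continuous outcome (Holm-corrected per
    window across the five outcomes), optional logistic models for the
    binary indicators, optional strata, placebo (negative-control) outcomes,
    and an alternative fixed-effects scheme.  Per-model failures are
    recorded and the suite continues.
    """
    config = config or SuiteConfig()
    cohort = cohort.copy()
    from .exposure import estimate_doc
    cohort["doc_month"] = estimate_doc(
        pd.to_datetime(cohort["birth_date"])).dt.month
    if config.binary:
        cohort = binarize_cohort(cohort, config.cutoffs)
    if config.n_negative_controls:
        rng = np.random.default_rng(config.seed)
        for j in range(config.n_negative_controls):
            cohort[f"placebo_{j + 1}"] = rng.standard_normal(len(cohort))

    rows, failures = [], []

    def try_fit(outcome, window, family, stratum, data, fe="area_by_month"):
        spec = ModelSpec(outcome=outcome, window=window, family=family, fe=fe,
                         cluster="area_id")
        try:
            design = build_design(data, exposure_table, spec)
            res = (fit_linear_fe(design) if family == "linear"
                   else fit_logistic_fe(design))
            return res
        except Exception as exc:  # noqa: BLE001 - suite keeps going
            failures.append((outcome, window, family, stratum, str(exc)))
            logger.warning("fit failed (%s, %s, %s, %s): %s", outcome, window,
                           family, stratum, exc)
            return None

    for window in config.windows:
        for family, outcomes in (
            ("linear", config.continuous_outcomes),
            ("logistic", BINARY_OUTCOMES if config.binary else ()),
        ):
            fam_results = []
            for outcome in outcomes:
                res = try_fit(outcome, window, family, "all", cohort)
                if res is not None:
                    fam_results.append(res)
            if fam_results:
                corrected = holm_correct([r.raw_p for r in fam_results])
                for r, hp in zip(fam_results, corrected):
                    r.holm_p = float(hp)
                    rows.append(_result_row(r, "all"))

        for stratum in config.strata:
            sub = cohort[_STRATA[stratum](cohort)]
            for outcome in config.continuous_outcomes:
                res = try_fit(outcome, window, "linear", stratum, sub)
                if res is not None:
                    rows.append(_result_row(res, stratum))

        for j in range(config.n_negative_controls):
            res = try_fit(f"placebo_{j + 1}", window, "linear", "placebo",
                          cohort)
            if res is not None:
                rows.append(_result_row(res, "placebo"))

        if config.alt_fe:
            for outcome in config.continuous_outcomes:
                res = try_fit(outcome, window, "linear", "alt_fe", cohort,
                              fe="month_by_year_plus_area")
                if res is not None:
                    rows.append(_result_row(res, "alt_fe"))

    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    return table
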