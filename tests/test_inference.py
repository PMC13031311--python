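"""Fixed-effects estimation, clustered errors, binarization, Holm, suite."""
import numpy as np
import pandas as pd
import pytest

from periclim.inference import (BinaryCutoffs, ClusterError, DesignBundle,
                                IdentificationError, ModelSpec, SuiteConfig,
                                binarize_cohort, binarize_outcomes,
                                build_design, cluster_robust_cov,
                                cluster_robust_se, fit_linear_fe,
                                fit_logistic_fe, holm_correct,
                                run_analysis_suite)
from periclim.exposure import build_exposure_table


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def test_binarize_boundary_cases():
    row = {"bmi": 25.0, "waist_circumference": 93.9, "sex": 0,
           "hba1c": 38.999, "triglycerides": 1.7, "cholesterol": 5.19}
    flags = binarize_outcomes(row)
    assert flags["overweight"] is True          # >= rule at the boundary
    assert flags["high_wc"] is False            # male threshold 94
    assert flags["high_hba1c"] is False         # strictly below 39
    assert flags["high_triglycerides"] is True
    assert flags["high_cholesterol"] is False

    female = binarize_outcomes({"waist_circumference": 80.0, "sex": 1})
    assert female["high_wc"] is True
    assert female["overweight"] is None         # missing BMI -> missing flag

    with pytest.raises(ValueError, match="sex"):
        binarize_outcomes({"waist_circumference": 90.0})


def test_binarize_cohort_matches_rowwise():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "sex": rng.integers(0, 2, 50),
        "bmi": rng.normal(27, 5, 50),
        "waist_circumference": rng.normal(90, 13, 50),
        "hba1c": rng.normal(36, 6, 50),
        "triglycerides": rng.normal(1.8, 1, 50),
        "cholesterol": rng.normal(5.7, 1.1, 50),
    })
    out = binarize_cohort(df)
    for i in (0, 7, 23, 49):
        row_flags = binarize_outcomes(df.iloc[i].to_dict())
        for k, v in row_flags.items():
            assert bool(out[k].iloc[i]) == v


# ---------------------------------------------------------------------------
# design and linear FE
# ---------------------------------------------------------------------------

def _random_design(n=300, n_fe=12, n_cl=6, alpha=0.7, noise=1.0, seed=42):
    rng = np.random.default_rng(seed)
    fe = rng.integers(0, n_fe, n)
    cl = rng.integers(0, n_cl, n)
    x = rng.standard_normal(n) + 0.4 * fe
    sex = rng.integers(0, 2, n).astype(float)
    y = alpha * x + 0.3 * sex + 1.5 * fe + noise * rng.standard_normal(n)
    X = np.column_stack([x, sex])
    return DesignBundle(y=y, X=X, colnames=["exposure", "female"],
                        fe_codes=fe, n_fe=n_fe, cluster_codes=cl,
                        n_clusters=n_cl, n_dropped=0,
                        spec=ModelSpec("y", "w"))


def _dummy_ols(y, X, fe_codes, n_fe):
    """Brute-force dummy-variable OLS (independent of the within path)."""
    dummies = np.zeros((len(y), n_fe))
    dummies[np.arange(len(y)), fe_codes] = 1.0
    full = np.column_stack([X, dummies])
    beta, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ beta
    return beta, resid, full


def test_within_equals_dummy_ols():
    d = _random_design()
    res = fit_linear_fe(d)
    beta_dummy, resid_dummy, _ = _dummy_ols(d.y, d.X, d.fe_codes, d.n_fe)
    assert res.alpha == pytest.approx(beta_dummy[0], abs=1e-8)


def test_within_matches_statsmodels_cluster():
    import statsmodels.api as sm
    d = _random_design(seed=3)
    res = fit_linear_fe(d)
    _, _, full = _dummy_ols(d.y, d.X, d.fe_codes, d.n_fe)
    oracle = sm.OLS(d.y, full).fit(cov_type="cluster",
                                   cov_kwds={"groups": d.cluster_codes})
    assert res.alpha == pytest.approx(oracle.params[0], abs=1e-10)
    assert res.se_cluster == pytest.approx(oracle.bse[0], rel=1e-10)


def test_noiseless_recovery_is_exact():
    d = _random_design(alpha=0.5, noise=0.0)
    res = fit_linear_fe(d)
    assert res.alpha == pytest.approx(0.5, abs=1e-8)


def test_row_permutation_invariance():
    d = _random_design(seed=8)
    res = fit_linear_fe(d)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(d.y))
    d2 = DesignBundle(y=d.y[perm], X=d.X[perm], colnames=d.colnames,
                      fe_codes=d.fe_codes[perm], n_fe=d.n_fe,
                      cluster_codes=d.cluster_codes[perm],
                      n_clusters=d.n_clusters, n_dropped=0, spec=d.spec)
    res2 = fit_linear_fe(d2)
    assert res2.alpha == pytest.approx(res.alpha, abs=1e-10)
    assert res2.se_cluster == pytest.approx(res.se_cluster, rel=1e-10)


def test_fe_only_projection_oracle():
    """Demeaning y by cells equals residuals of dummy OLS without exposure."""
    d = _random_design(n=200, seed=5)
    beta, resid, _ = _dummy_ols(d.y, np.empty((len(d.y), 0)), d.fe_codes,
                                d.n_fe)
    from periclim.inference import _demean_by_group
    yt = _demean_by_group(d.y, d.fe_codes, d.n_fe)
    np.testing.assert_allclose(yt, resid, atol=1e-10)


def test_singleton_cell_self_absorbs():
    d = _random_design(seed=11)
    res = fit_linear_fe(d)
    # append one observation in a brand-new cell: its residual is absorbed
    d2 = DesignBundle(
        y=np.append(d.y, 99.0),
        X=np.vstack([d.X, [5.0, 1.0]]),
        colnames=d.colnames,
        fe_codes=np.append(d.fe_codes, d.n_fe),
        n_fe=d.n_fe + 1,
        cluster_codes=np.append(d.cluster_codes, 0),
        n_clusters=d.n_clusters, n_dropped=0, spec=d.spec)
    res2 = fit_linear_fe(d2)
    assert res2.alpha == pytest.approx(res.alpha, abs=1e-10)


def test_unidentified_exposure_raises():
    d = _random_design()
    d.X[:, 0] = d.fe_codes.astype(float)  # constant within every cell
    with pytest.raises(IdentificationError):
        fit_linear_fe(d)


def test_build_design_counts_cells(tiny_world):
    cohort = tiny_world["cohort"]
    expo = build_exposure_table(cohort, tiny_world["field"], ["-2w;DOC"])
    design = build_design(cohort, expo, ModelSpec("bmi", "-2w;DOC"))
    observed_cells = len({(a, m.month) for a, m in
                          zip(cohort["area_id"],
                              pd.to_datetime(cohort["birth_date"]))})
    assert design.n_fe == observed_cells
    assert design.X[:, 0].shape == design.y.shape
    assert design.colnames[0] == "exposure"


# ---------------------------------------------------------------------------
# cluster-robust sandwich
# ---------------------------------------------------------------------------

def _brute_force_cr1(X, resid, clusters, K):
    """Plain-loop evaluation of the CR1 sandwich formula."""
    N, k = X.shape
    G = len(set(clusters))
    XtX_inv = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for g in set(clusters):
        idx = [i for i in range(N) if clusters[i] == g]
        sg = sum(X[i] * resid[i] for i in idx)
        meat += np.outer(sg, sg)
    scale = (G / (G - 1)) * ((N - 1) / (N - K))
    return scale * XtX_inv @ meat @ XtX_inv


def test_hand_computed_two_cluster_example():
    X = np.array([[1.0, 1.0], [2.0, 1.0], [0.5, 1.0],
                  [-1.0, 1.0], [0.0, 1.0], [1.5, 1.0]])
    y = np.array([1.0, 2.5, 0.7, -0.8, 0.3, 2.0])
    clusters = np.array([0, 0, 0, 1, 1, 1])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    V = cluster_robust_cov(X, resid, clusters)
    V_brute = _brute_force_cr1(X, resid, clusters, K=2)
    np.testing.assert_allclose(V, V_brute, atol=1e-12)


def test_own_cluster_equals_hc1():
    import statsmodels.api as sm
    rng = np.random.default_rng(21)
    X = np.column_stack([rng.standard_normal(40), np.ones(40)])
    y = X @ [1.0, 0.5] + rng.standard_normal(40)
    fitted = sm.OLS(y, X).fit()
    resid = y - X @ fitted.params
    se = cluster_robust_se(X, resid, np.arange(40))
    assert se == pytest.approx(fitted.get_robustcov_results("HC1").bse[0],
                               abs=1e-10)


def test_duplicated_rows_match_brute_force():
    rng = np.random.default_rng(31)
    X = np.column_stack([rng.standard_normal(12), np.ones(12)])
    y = X @ [0.8, 0.1] + rng.standard_normal(12)
    clusters = np.repeat([0, 1, 2], 4)
    X2, y2, cl2 = np.vstack([X, X]), np.concatenate([y, y]), \
        np.concatenate([clusters, clusters])
    beta, *_ = np.linalg.lstsq(X2, y2, rcond=None)
    resid = y2 - X2 @ beta
    V = cluster_robust_cov(X2, resid, cl2)
    np.testing.assert_allclose(V, _brute_force_cr1(X2, resid, list(cl2), K=2),
                               atol=1e-12)


def test_single_cluster_raises_with_advice():
    X = np.ones((5, 1))
    with pytest.raises(ClusterError, match="HC1"):
        cluster_robust_se(X, np.ones(5), np.zeros(5))


# ---------------------------------------------------------------------------
# logistic FE
# ---------------------------------------------------------------------------

def test_logit_single_cell_reduces_to_contingency_log_odds():
    rng = np.random.default_rng(6)
    n = 400
    x = rng.integers(0, 2, n).astype(float)
    p = np.where(x == 1, 0.6, 0.35)
    y = (rng.random(n) < p).astype(float)
    d = DesignBundle(y=y, X=x[:, None], colnames=["exposure"],
                     fe_codes=np.zeros(n, dtype=int), n_fe=1,
                     cluster_codes=rng.integers(0, 8, n), n_clusters=8,
                     n_dropped=0, spec=ModelSpec("y", "w", family="logistic"))
    res = fit_logistic_fe(d)
    a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
    c = np.sum((x == 0) & (y == 1)); e = np.sum((x == 0) & (y == 0))
    log_or = np.log((a * e) / (b * c))
    assert res.alpha == pytest.approx(log_or, abs=1e-6)


def test_logit_doubling_leaves_estimate_unchanged():
    rng = np.random.default_rng(13)
    n = 300
    x = rng.standard_normal(n)
    fe = rng.integers(0, 4, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x + 0.3 * fe - 1)))).astype(float)
    d = DesignBundle(y=y, X=x[:, None], colnames=["exposure"], fe_codes=fe,
                     n_fe=4, cluster_codes=rng.integers(0, 6, n),
                     n_clusters=6, n_dropped=0,
                     spec=ModelSpec("y", "w", family="logistic"))
    res = fit_logistic_fe(d)
    d2 = DesignBundle(y=np.tile(y, 2), X=np.tile(x, 2)[:, None],
                      colnames=["exposure"], fe_codes=np.tile(fe, 2), n_fe=4,
                      cluster_codes=np.tile(d.cluster_codes, 2), n_clusters=6,
                      n_dropped=0, spec=d.spec)
    res2 = fit_logistic_fe(d2)
    assert res2.alpha == pytest.approx(res.alpha, abs=1e-6)


def test_logit_drops_outcome_constant_cells():
    rng = np.random.default_rng(14)
    n = 200
    x = rng.standard_normal(n)
    fe = rng.integers(0, 3, n)
    y = (rng.random(n) < 0.5).astype(float)
    y[fe == 2] = 1.0  # constant cell
    d = DesignBundle(y=y, X=x[:, None], colnames=["exposure"], fe_codes=fe,
                     n_fe=3, cluster_codes=rng.integers(0, 5, n),
                     n_clusters=5, n_dropped=0,
                     spec=ModelSpec("y", "w", family="logistic"))
    res = fit_logistic_fe(d)
    assert res.n_obs == int(np.sum(fe != 2))


# ---------------------------------------------------------------------------
# Holm correction
# ---------------------------------------------------------------------------

def test_holm_step_down_examples():
    np.testing.assert_allclose(
        holm_correct([0.01, 0.02, 0.03, 0.04, 0.05]),
        [0.05, 0.08, 0.09, 0.09, 0.09])
    np.testing.assert_allclose(holm_correct([0.2]), [0.2])
    np.testing.assert_allclose(holm_correct([0.5, 0.5]), [1.0, 1.0])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=12))
def test_holm_invariants(p):
    out = holm_correct(p)
    order = np.argsort(p, kind="stable")
    assert (out >= np.asarray(p) - 1e-12).all()
    assert (out <= 1.0 + 1e-15).all()
    # corrected values are monotone in raw-p rank
    assert (np.diff(out[order]) >= -1e-15).all()
    # the smallest raw p receives the Bonferroni factor
    i = order[0]
    assert out[i] == pytest.approx(min(1.0, len(p) * p[i]), abs=1e-12)


def test_holm_matches_statsmodels_and_properties():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(17)
    for _ in range(25):
        p = rng.random(5)
        ours = holm_correct(p)
        theirs = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= p - 1e-15).all() and (ours <= 1.0).all()
        # smallest p gets the full Bonferroni factor
        i = np.argmin(p)
        assert ours[i] == pytest.approx(min(1.0, 5 * p[i]))
    with pytest.raises(ValueError):
        holm_correct([0.5, 1.2])


# ---------------------------------------------------------------------------
# suite runner
# ---------------------------------------------------------------------------

def test_suite_produces_tidy_table_with_holm_per_window(tiny_world):
    cohort = tiny_world["cohort"]
    expo = build_exposure_table(cohort, tiny_world["field"],
                                ["DOC", "-2w;DOC"])
    suite = SuiteConfig(windows=("DOC", "-2w;DOC"), binary=True,
                        strata=("female",), n_negative_controls=1,
                        alt_fe=True, seed=9)
    table = run_analysis_suite(cohort, expo, suite)
    assert set(table.columns) == {"outcome", "window", "family", "stratum",
                                  "alpha", "se", "raw_p", "holm_p", "n",
                                  "clusters"}
    core = table[(table["stratum"] == "all")]
    for (window, family), grp in core.groupby(["window", "family"]):
        recomputed = holm_correct(grp["raw_p"].to_numpy())
        np.testing.assert_allclose(grp["holm_p"].to_numpy(), recomputed,
                                   atol=1e-12)
        assert (grp["holm_p"] >= grp["raw_p"] - 1e-15).all()
    assert (table[table["stratum"] == "female"]["n"]
            < core["n"].max()).all()
    assert "placebo" in set(table["stratum"])
    assert "alt_fe" in set(table["stratum"])
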