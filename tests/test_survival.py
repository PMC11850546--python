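"""Cox harness, model comparison, cutpoints, AFT grid, risk groups."""

import numpy as np
import pandas as pd
import pytest

from hlacompat.survival import (
    EVENT_COL,
    GBDT_DEPTH_GRID,
    GBDT_TREE_GRID,
    PIRCHE_RANK_GRID,
    SNOWBALL_GRID,
    SNOWFLAKE_GRID,
    TIME_COL,
    compare_models,
    fit_cox,
    fit_gbdt_aft,
    log_transform,
    optimal_cutpoints,
    optimize_thresholds,
    risk_quartiles,
    validate_cohort,
    variance_inflation,
)


def ph_cohort(n, betas, seed, censor_scale=8.0, base_rate=0.1):
    """Exponential PH simulation with independent censoring."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({name: gen(rng, n) for name, (gen, _b) in betas.items()})
    lp = sum(b * df[name].to_numpy() for name, (_g, b) in betas.items())
    T = rng.exponential(1.0 / (base_rate * np.exp(lp)))
    C = rng.exponential(censor_scale, n)
    df[TIME_COL] = np.minimum(T, C)
    df[EVENT_COL] = T <= C
    return df


def binary(rng, n):
    return rng.integers(0, 2, n).astype(float)


def normal(rng, n):
    return rng.normal(size=n)


def test_log_transform_values_and_order():
    assert log_transform(0.0) == 0.0
    assert log_transform(np.e - 1) == pytest.approx(1.0)
    x = np.array([0.0, 1.0, 5.0, 100.0])
    assert np.all(np.diff(log_transform(x)) > 0)
    with pytest.raises(ValueError):
        log_transform(-1.0)


def test_cox_recovers_hazard_ratio_two():
    df = ph_cohort(5000, {"x": (binary, np.log(2.0))}, seed=1)
    res = fit_cox(df, ["x"], seed=1)
    assert res.converged
    assert abs(res.coefficients["x"] - np.log(2.0)) < 3 * res.standard_errors["x"]
    assert res.iauc > 0.55


def test_null_covariate_iauc_near_half():
    iaucs = []
    for seed in range(10):
        df = ph_cohort(3000, {"z": (normal, 0.0)}, seed=100 + seed)
        iaucs.append(fit_cox(df, ["z"], seed=seed).iauc)
    assert abs(np.mean(iaucs) - 0.5) < 0.03


def test_duplicated_covariate_flags_collinearity():
    df = ph_cohort(800, {"x": (normal, 0.3)}, seed=2)
    df["x_copy"] = df["x"] + 1e-9 * np.random.default_rng(0).normal(size=len(df))
    vif = variance_inflation(df, ["x", "x_copy"])
    assert vif["x"] > 10 and vif["x_copy"] > 10


def test_fit_result_summary_and_bic_convention():
    df = ph_cohort(2000, {"x": (binary, 0.5)}, seed=3)
    res = fit_cox(df, ["x"], seed=3)
    k = 1
    assert res.bic == pytest.approx(k * np.log(res.n_events) - 2 * res.log_likelihood)
    assert res.aic == pytest.approx(2 * k - 2 * res.log_likelihood)
    table = res.summary()
    assert list(table.index) == ["x"]
    assert table.loc["x", "hr"] == pytest.approx(np.exp(res.coefficients["x"]))


def test_validate_cohort_drops_bad_rows():
    df = pd.DataFrame({
        TIME_COL: [1.0, -1.0, 2.0, np.nan],
        EVENT_COL: [True, False, True, True],
        "x": [1.0, 1.0, np.nan, 1.0],
    })
    out = validate_cohort(df, ["x"])
    assert len(out) == 1


def test_compare_models_prefers_parsimonious_truth():
    df = ph_cohort(5000, {"x": (binary, 0.7), "noise": (normal, 0.0)}, seed=5)
    ranking = compare_models(df, {"true": ["x"], "bloated": ["x", "noise"]},
                             n_repeats=6, seed=5)
    assert ranking.iloc[0]["model_id"] == "true"


def test_compare_models_identical_specs_tie_stable():
    df = ph_cohort(1500, {"x": (binary, 0.5)}, seed=6)
    ranking = compare_models(df, {"a": ["x"], "b": ["x"]}, n_repeats=3, seed=6)
    assert list(ranking["model_id"]) == ["a", "b"]
    assert ranking["median_scaled_bic"].tolist() == [0.0, 0.0]


def test_compare_models_true_spec_wins_most_repeats():
    df = ph_cohort(5000, {"x": (binary, 0.7), "z": (normal, 0.0)}, seed=7)
    ranking = compare_models(df, {"true": ["x"], "null": ["z"]}, n_repeats=10, seed=7)
    rows = {r["model_id"]: r["scaled_bic"] for _i, r in ranking.iterrows()}
    wins = sum(t < n for t, n in zip(rows["true"], rows["null"]))
    assert wins >= 8


def test_default_grids_match_protocol():
    assert PIRCHE_RANK_GRID == (5, 10, 15, 20, 30, 40, 50, 75, 100, 150, 200, 250, 300, 400, 500)
    assert len(PIRCHE_RANK_GRID) == 15
    assert GBDT_TREE_GRID == (16, 32, 64, 128, 256, 512)
    assert GBDT_DEPTH_GRID == tuple(range(2, 13))
    assert SNOWFLAKE_GRID[0] == 0.0 and SNOWFLAKE_GRID[-1] == 1.0
    assert all(round(x, 2) in SNOWFLAKE_GRID for x in np.arange(0.20, 0.701, 0.02))
    assert all(round(x, 2) in SNOWBALL_GRID for x in np.arange(0.30, 0.801, 0.02))
    assert len(SNOWFLAKE_GRID) == 31 and len(SNOWBALL_GRID) == 31


class _ArrayBackend:
    """Threshold-free stand-in: scores precomputed per pair."""

    def __init__(self, snow_fn, pirche_fn=None):
        self._snow, self._pirche = snow_fn, pirche_fn

    def snow_vector(self, pairs, sf, sb):
        return self._snow(sf, sb)

    def pirche_vector(self, pairs, rank):
        return self._pirche(rank)


def test_single_point_grid_reduces_to_fit_cox():
    rng = np.random.default_rng(8)
    n = 1200
    snow = rng.poisson(10.0, n).astype(float)
    df = ph_cohort(n, {"dummy": (normal, 0.0)}, seed=8).drop(columns=["dummy"])
    backend = _ArrayBackend(lambda sf, sb: snow)
    best, surface = optimize_thresholds(
        df, [None] * n, backend, snowflake_grid=[0.3], snowball_grid=[0.5],
        train_fraction=0.7, seed=42,
    )
    df2 = df.copy()
    df2["snow_log"] = log_transform(snow)
    ref = fit_cox(df2, ["snow_log"], train_fraction=0.7, seed=42, compute_auc=False)
    assert (best.snowflake, best.snowball) == (0.3, 0.5)
    assert surface["AIC"].iloc[0] == pytest.approx(ref.aic)


def test_threshold_surface_is_total():
    rng = np.random.default_rng(9)
    n = 800
    df = ph_cohort(n, {"dummy": (normal, 0.0)}, seed=9).drop(columns=["dummy"])
    backend = _ArrayBackend(
        lambda sf, sb: rng.poisson(8.0, n).astype(float),
        lambda r: rng.poisson(5.0, n).astype(float),
    )
    _best, surface = optimize_thresholds(
        df, [None] * n, backend, snowflake_grid=[0.0, 0.5], snowball_grid=[0.0, 0.5],
        rank_grid=[100, 300], seed=0,
    )
    assert len(surface) == 2 * 2 * 2


def test_cutpoint_recovers_hazard_jump():
    rng = np.random.default_rng(10)
    n = 5000
    score = rng.uniform(0, 100, n)
    lam = 0.05 * np.exp(0.9 * (score > 40))
    T = rng.exponential(1.0 / lam)
    C = rng.exponential(10.0, n)
    df = pd.DataFrame({TIME_COL: np.minimum(T, C), EVENT_COL: T <= C})
    res = optimal_cutpoints(df, score, k=3, stability_bootstraps=10, seed=0)
    assert abs(res.primary - 40.0) <= 5.0
    assert len(res.cutpoints) == 3
    assert res.stability is not None and res.stability >= 0.5


def test_cutpoint_null_score_is_unstable():
    rng = np.random.default_rng(11)
    n = 2000
    score = rng.uniform(0, 100, n)
    T = rng.exponential(10.0, n)
    C = rng.exponential(10.0, n)
    df = pd.DataFrame({TIME_COL: np.minimum(T, C), EVENT_COL: T <= C})
    res = optimal_cutpoints(df, score, k=1, stability_bootstraps=20, seed=1)
    assert res.stability < 0.5


def test_cutpoint_two_group_score_exact():
    rng = np.random.default_rng(12)
    n = 3000
    score = rng.choice([10.0, 50.0], n)
    lam = 0.05 * np.exp(1.0 * (score > 10))
    T = rng.exponential(1.0 / lam)
    df = pd.DataFrame({TIME_COL: T, EVENT_COL: np.ones(n, bool)})
    with pytest.raises(ValueError, match="distinct"):
        optimal_cutpoints(df, score, k=3)
    res = optimal_cutpoints(df, score, k=1, quantile_range=(0.0, 1.0))
    assert res.cutpoints == [10.0]


def test_gbdt_importance_beats_random_control():
    df = ph_cohort(900, {"x": (binary, 1.2), "z": (normal, 0.0)}, seed=13)
    res = fit_gbdt_aft(df, ["x", "z"], tree_grid=(16, 32), depth_grid=(2, 3), seed=13)
    assert res.importances["x"] > res.importances["random_control"]
    assert set(res.results.columns) >= {"n_trees", "max_depth", "iauc", "cindex"}
    assert len(res.results) == 4


def test_gbdt_ensemble_at_least_median_single():
    df = ph_cohort(900, {"x": (binary, 1.0)}, seed=14)
    res = fit_gbdt_aft(df, ["x"], tree_grid=(16, 32), depth_grid=(2, 3), seed=14,
                       add_random_control=False)
    assert res.ensemble_iauc >= res.results["iauc"].median() - 0.02


def test_risk_quartiles_groups_and_ordering():
    rng = np.random.default_rng(15)
    n = 4000
    risk = rng.normal(size=n)
    T = rng.exponential(np.exp(-risk))
    df = pd.DataFrame({TIME_COL: T, EVENT_COL: np.ones(n, bool)})
    groups, summaries = risk_quartiles(df, risk)
    sizes = [s.n for s in summaries]
    assert sizes == [1000, 1000, 1000, 1000]
    medians = [s.km_median for s in summaries]
    assert medians == sorted(medians, reverse=True)  # higher risk, shorter survival


def test_risk_quartiles_coarse_score_ties_lower_group():
    score = np.array([0.0] * 70 + [1.0] * 20 + [2.0] * 10)
    rng = np.random.default_rng(16)
    df = pd.DataFrame({TIME_COL: rng.exponential(5.0, 100),
                       EVENT_COL: np.ones(100, bool)})
    groups, summaries = risk_quartiles(df, score)
    assert (groups[score == 0.0] == 1).all()  # ties share the lower group
    assert len({s.group for s in summaries}) < 4 or \
        [s.n for s in summaries] != [25, 25, 25, 25]
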