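"""Classification pipeline: dataset assembly, CV engine, explanation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import train_test_split

from penkit import ValidationError
from penkit.classify import (
    CVConfig,
    Dataset,
    DatasetSpec,
    build_dataset,
    correlation_filter,
    fit_final_model,
    importance_ranking,
    misclassification_profiles,
    run_cv,
)
from penkit._resample import SAMPLERS, resample
from penkit._shapley import shapley_values
from penkit.indicators import INDICATOR_NAMES

SMALL_CFG = CVConfig(repeats=4, search_draws=8, models=("svc", "random_forest"),
                     samplers=("none", "smote", "random_under"), k_grid=(5, 10))


def make_matrix(n_per=40, d=12, n_inf=3, effect=1.5, seed=0, y=None):
    r = np.random.default_rng(seed)
    X0 = r.normal(0, 1, (n_per, d))
    X1 = r.normal(0, 1, (n_per, d))
    X1[:, :n_inf] += effect
    X = np.vstack([X1, X0])
    if y is None:
        y = np.r_[np.ones(n_per, int), np.zeros(n_per, int)]
    cols = [f"ind_{i:02d}" for i in range(d)]
    Xdf = pd.DataFrame(X, columns=cols, index=[f"s{i}/test" for i in range(len(X))])
    return Dataset(X=Xdf, y=np.asarray(y), ids=list(Xdf.index), spec=DatasetSpec())


# ---------------------------------------------------------------------------
# correlation filter + dataset assembly
# ---------------------------------------------------------------------------


def test_correlation_filter_drops_later_of_redundant_pair(rng):
    X = pd.DataFrame(rng.normal(0, 1, (200, 12)),
                     columns=[f"c{i:02d}" for i in range(12)])
    X["c07"] = X["c03"] + rng.normal(0, 0.05, 200)  # r ~ 0.998 with c03
    keep = correlation_filter(X, 0.9)
    assert "c03" in keep and "c07" not in keep
    assert len(keep) == 11


def test_correlation_filter_no_pair_above_threshold_keeps_all(rng):
    X = pd.DataFrame(rng.normal(0, 1, (500, 8)))
    assert len(correlation_filter(X, 0.9)) == 8


def test_correlation_filter_removes_duplicate_column(rng):
    X = pd.DataFrame(rng.normal(0, 1, (100, 3)), columns=["a", "b", "c"])
    X["c"] = X["a"]
    assert correlation_filter(X, 0.9) == ["a", "b"]


def _indicator_table(group, n_subj, seed, tasks=("list", "text"), allograph="cursive"):
    r = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        for task in tasks:
            row = {"subject": f"{group}{i}", "session": "test", "task": task,
                   "allograph": allograph}
            for name in INDICATOR_NAMES[:6]:
                row[name] = r.normal(0, 1)
            rows.append(row)
    return pd.DataFrame(rows)


def test_build_dataset_filters_and_combines():
    mci = _indicator_table("m", 15, 0)
    hc = _indicator_table("h", 15, 1)
    ds = build_dataset(mci, hc, DatasetSpec(tasks="L", allograph="cursive"))
    assert ds.X.shape[0] == 30
    ds_lt = build_dataset(mci, hc, DatasetSpec(tasks="L+T", allograph="cursive"))
    assert ds_lt.X.shape[0] == 30
    assert any(c.endswith("_L") for c in ds_lt.feature_names)
    assert any(c.endswith("_T") for c in ds_lt.feature_names)


def test_build_dataset_requires_both_tasks_for_combined():
    mci = _indicator_table("m", 15, 0)
    hc = _indicator_table("h", 15, 1, tasks=("list",))  # no text rows
    with pytest.raises(ValidationError, match="rejected"):
        build_dataset(mci, hc, DatasetSpec(tasks="L+T"))


def test_build_dataset_rejects_small_class():
    mci = _indicator_table("m", 5, 0)
    hc = _indicator_table("h", 15, 1)
    with pytest.raises(ValidationError, match="rejected"):
        build_dataset(mci, hc, DatasetSpec(tasks="L"))


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", sorted(SAMPLERS))
def test_samplers_preserve_labels_and_improve_balance(name, rng):
    r = np.random.default_rng(7)
    X = np.vstack([r.normal(0, 1, (40, 4)), r.normal(2, 1, (15, 4))])
    y = np.r_[np.zeros(40, int), np.ones(15, int)]
    Xr, yr = resample(name, X, y, np.random.default_rng(1))
    assert set(np.unique(yr)) == {0, 1}
    assert len(Xr) == len(yr)
    n0, n1 = np.sum(yr == 0), np.sum(yr == 1)
    if name != "none":
        assert abs(n0 - n1) <= abs(40 - 15)
    if name in ("smote", "borderline_smote", "svm_smote", "adasyn"):
        assert n1 >= 15  # oversampling never discards minority samples


def test_oversamplers_interpolate_within_minority_hull(rng):
    r = np.random.default_rng(9)
    X = np.vstack([r.normal(0, 1, (30, 2)), r.uniform(5, 6, (10, 2))])
    y = np.r_[np.zeros(30, int), np.ones(10, int)]
    Xr, yr = resample("smote", X, y, np.random.default_rng(2))
    new = Xr[len(X):]
    assert np.all(new >= 5.0 - 1e-9) and np.all(new <= 6.0 + 1e-9)


# ---------------------------------------------------------------------------
# CV engine
# ---------------------------------------------------------------------------


def test_run_cv_reports_five_metrics_and_is_deterministic():
    ds = make_matrix(n_per=30, d=8, n_inf=2, effect=1.5, seed=1)
    rep1 = run_cv(ds, SMALL_CFG, seed=5)
    rep2 = run_cv(ds, SMALL_CFG, seed=5)
    assert set(rep1.metrics) == {"accuracy", "recall", "precision", "f1", "pr_auc"}
    for name, (mean, sd) in rep1.metrics.items():
        assert 0.0 <= mean <= 1.0 and sd >= 0.0
    assert rep1.metrics == rep2.metrics
    assert len(rep1.per_repeat) == SMALL_CFG.repeats


def test_full_model_zoo_smoke():
    """Every model family fits, predicts and scores on a small matrix."""
    from penkit.classify import _draw_config, _fit_candidate, _impute, _scores

    ds = make_matrix(n_per=25, d=8, n_inf=2, effect=1.5, seed=10)
    (X,) = _impute(ds.X.to_numpy(float))
    rng = np.random.default_rng(0)
    cfg = CVConfig()
    seen = set()
    guard = 0
    while seen != set(cfg.models) and guard < 400:
        guard += 1
        config = _draw_config(cfg, rng)
        if config["model"] in seen:
            continue
        pipe, _ = _fit_candidate(config, X, ds.y, seed=1, rng=rng)
        pred = pipe.predict(X)
        assert set(np.unique(pred)) <= {0, 1}
        scores = _scores(pipe, X)
        assert np.all(np.isfinite(scores))
        seen.add(config["model"])
    assert seen == set(cfg.models)


def test_run_cv_learns_planted_effect():
    ds = make_matrix(n_per=40, d=12, n_inf=4, effect=1.8, seed=2)
    rep = run_cv(ds, SMALL_CFG, seed=6)
    assert rep.metrics["f1"][0] >= 0.85


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


def test_shapley_local_accuracy_for_additive_model(rng):
    w = np.array([1.0, -2.0, 0.5, 0.0])
    f = lambda X: X @ w + 3.0
    X = rng.normal(0, 1, (20, 4))
    bg = np.median(X, axis=0)
    phi = shapley_values(f, X, bg, np.random.default_rng(0), n_permutations=8)
    np.testing.assert_allclose(phi.sum(axis=1), f(X) - f(bg[None, :]), atol=1e-6)
    # additive model: phi_j = w_j * (x_j - bg_j) exactly
    np.testing.assert_allclose(phi, w[None, :] * (X - bg[None, :]), atol=1e-8)


def test_zero_variance_feature_gets_no_attribution():
    ds = make_matrix(n_per=30, d=6, n_inf=2, effect=2.0, seed=3)
    ds.X["ind_05"] = 1.0  # constant column
    fitted = fit_final_model(
        ds, {"model": "random_forest",
             "params": {"n_estimators": 100, "max_depth": 5, "max_features": "sqrt"},
             "sampler": "none", "k": None}, seed=0)
    ranking = importance_ranking(fitted, ds, seed=0, top=6)
    by_name = {r["indicator"]: r["mean_abs_shap"] for r in ranking}
    assert by_name.get("ind_05", 0.0) == pytest.approx(0.0, abs=1e-12)


def test_single_informative_feature_ranked_first():
    hits = 0
    for seed in range(3):
        ds = make_matrix(n_per=30, d=21, n_inf=1, effect=2.5, seed=seed)
        fitted = fit_final_model(
            ds, {"model": "random_forest",
                 "params": {"n_estimators": 100, "max_depth": 5, "max_features": "sqrt"},
                 "sampler": "none", "k": None}, seed=seed)
        ranking = importance_ranking(fitted, ds, seed=seed)
        if ranking and ranking[0]["indicator"] == "ind_00":
            assert ranking[0]["direction"] == "+"
            hits += 1
    assert hits == 3


# ---------------------------------------------------------------------------
# radar profiles
# ---------------------------------------------------------------------------


def test_radar_profiles_normalized_and_consistent():
    ds = make_matrix(n_per=25, d=8, n_inf=2, effect=1.0, seed=4)
    rep = run_cv(ds, SMALL_CFG, seed=7)
    top5 = list(ds.feature_names[:5])
    profiles = misclassification_profiles(rep, ds, top5)
    assert profiles, "expected at least one misclassification at modest effect"
    for p in profiles:
        for attr in ("values", "mci_median", "hc_median", "mci_q25", "mci_q75",
                     "hc_q25", "hc_q75"):
            vals = np.asarray(getattr(p, attr))
            assert np.all(vals >= 0.0) and np.all(vals <= 1.0)
        assert p.indicators == top5
    # pooled min -> 0 and max -> 1 for every indicator
    lo = ds.X[top5].min().to_numpy()
    hi = ds.X[top5].max().to_numpy()
    span = hi - lo
    norm = (ds.X[top5].to_numpy() - lo) / span
    assert np.allclose(norm.min(axis=0), 0.0) and np.allclose(norm.max(axis=0), 1.0)


def test_sample_at_hc_median_coincides_with_hc_polygon():
    ds = make_matrix(n_per=25, d=5, n_inf=1, effect=1.0, seed=8)
    top5 = list(ds.feature_names)
    hc_median = ds.X[np.asarray(ds.y) == 0].median()
    ds.X.iloc[0] = hc_median  # plant a sample exactly at the HC median
    # fake a single-misclassification report for that sample
    rep = run_cv(ds, SMALL_CFG, seed=9)
    rep.per_repeat = [{
        "repeat": 0, "config": {}, "metrics": {},
        "test_ids": [ds.ids[0]], "y_true": [1], "y_pred": [0],
    }]
    prof = misclassification_profiles(rep, ds, top5)[0]
    np.testing.assert_allclose(prof.values, prof.hc_median, atol=1e-9)


def test_radar_plot_writes_file(tmp_path):
    from penkit.viz import plot_radar

    ds = make_matrix(n_per=25, d=8, n_inf=2, effect=1.0, seed=4)
    rep = run_cv(ds, SMALL_CFG, seed=7)
    profiles = misclassification_profiles(rep, ds, list(ds.feature_names[:5]))
    out = plot_radar(profiles[0], str(tmp_path / "radar.png"))
    assert (tmp_path / "radar.png").stat().st_size > 0
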