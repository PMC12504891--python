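"""MCI-vs-HC classification on unconstrained-task handwriting indicators.

The evaluation protocol is Monte-Carlo cross-validation: a number of seeded
stratified 70/15/15 train/validation/test splits. Inside each repeat,
everything that learns from data — the redundancy (|r|>0.9) filter, the
imbalance sampler, univariate feature selection and the randomized
hyperparameter search over a model zoo — is fitted on the training split
only (a compatibility flag reproduces the looser variant that also resamples
the validation split, with a leakage warning). The search draws random
(model, sampler, feature-selection, hyperparameter) configurations, selects
by validation F1 with a deterministic tie-break (fewer features, then
lexicographically smaller configuration, then first seen), refits the winner
on train+validation and scores it on the held-out test split. Metrics
(accuracy, recall, precision, F1, PR-AUC) are averaged over repeats.

Explanation: Shapley attributions of the winning model against a
training-median background rank the indicators; misclassified test samples
are profiled on the top-5 indicators against the group median and
interquartile bands, min-max normalized over the pooled dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._resample import resample
from ._shapley import score_function, shapley_values
from .errors import ValidationError

__all__ = [
    "DatasetSpec",
    "Dataset",
    "CVConfig",
    "ClassificationReport",
    "RadarProfile",
    "correlation_filter",
    "build_dataset",
    "run_cv",
    "fit_final_model",
    "importance_ranking",
    "misclassification_profiles",
]

ID_COLS = ("subject", "session", "task", "allograph")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class DatasetSpec:
    """Which rows enter the model matrix."""

    tasks: str = "L"  # "L" | "T" | "L+T"
    allograph: str = "pooled"  # "cursive" | "block" | "pooled"
    corr_threshold: float = 0.9


@dataclass
class Dataset:
    X: pd.DataFrame
    y: np.ndarray  # 1 = MCI, 0 = HC
    ids: list[str]
    spec: DatasetSpec

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def correlation_filter(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy redundancy filter in column order.

    A column is retained unless its absolute pairwise correlation with an
    already-retained column exceeds the threshold (so of a redundant pair the
    *later* column is dropped).
    """
    cols = list(X.columns)
    corr = X.corr().abs().to_numpy()
    keep: list[int] = []
    for j in range(len(cols)):
        if all(not (corr[j, i] > threshold) for i in keep):  # NaN-safe
            keep.append(j)
    return [cols[j] for j in keep]


def _task_rows(df: pd.DataFrame, task: str, allograph: str) -> pd.DataFrame:
    out = df[df["task"] == task]
    if allograph != "pooled":
        out = out[out["allograph"] == allograph]
    else:
        pass  # pooled keeps every allograph including "na"
    return out


def build_dataset(
    mci: pd.DataFrame, hc: pd.DataFrame, spec: DatasetSpec | None = None
) -> Dataset:
    """Assemble the model matrix from MCI and HC indicator tables.

    Rows are (subject, session) executions; only handwriting indicators are
    features (clinical scores and age never enter). For the combined "L+T"
    dataset a row requires both the list and text execution of a (subject,
    session) pair, and features are suffixed ``_L`` / ``_T``.
    """
    spec = spec or DatasetSpec()
    frames = []
    for label, df in ((1, mci), (0, hc)):
        if spec.tasks in ("L", "T"):
            task = "list" if spec.tasks == "L" else "text"
            rows = _task_rows(df, task, spec.allograph).copy()
            feat_cols = [c for c in rows.columns if c not in ID_COLS]
            rows["_id"] = rows["subject"].astype(str) + "/" + rows["session"].astype(str)
            part = rows[["_id"] + feat_cols].set_index("_id")
        else:  # L+T
            l_rows = _task_rows(df, "list", spec.allograph)
            t_rows = _task_rows(df, "text", spec.allograph)
            feat_cols = [c for c in df.columns if c not in ID_COLS]
            l = l_rows.set_index(["subject", "session"])[feat_cols].add_suffix("_L")
            t = t_rows.set_index(["subject", "session"])[feat_cols].add_suffix("_T")
            part = l.join(t, how="inner")
            part.index = [f"{s}/{sess}" for s, sess in part.index]
        part = part.assign(_y=label)
        frames.append(part)
    allrows = pd.concat(frames)
    y = allrows.pop("_y").to_numpy()
    X = allrows
    keep = correlation_filter(X, spec.corr_threshold)
    X = X[keep]
    n_mci, n_hc = int((y == 1).sum()), int((y == 0).sum())
    if min(n_mci, n_hc) < 10:
        raise ValidationError(
            f"dataset rejected: {n_mci} MCI / {n_hc} HC rows after filtering "
            f"(need >= 10 per class; tasks={spec.tasks}, allograph={spec.allograph})"
        )
    return Dataset(X=X, y=y, ids=list(X.index), spec=spec)


# ---------------------------------------------------------------------------
# configuration search space
# ---------------------------------------------------------------------------


@dataclass
class CVConfig:
    repeats: int = 10
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    search_draws: int = 30
    samplers: tuple[str, ...] = (
        "none", "random_under", "near_miss", "edited_nn",
        "smote", "svm_smote", "borderline_smote", "adasyn",
    )
    k_grid: tuple[int, ...] = (10, 20, 30, 40, 50)
    models: tuple[str, ...] = (
        "svc", "random_forest", "adaboost", "gradient_boosting",
        "xgb", "lgbm", "hist_gb",
    )
    optimize: str = "f1"
    resample_validation: bool = False  # compatibility flag; leaks, see run_cv
    refit_corr_filter: bool = True
    corr_threshold: float = 0.9
    shap_permutations: int = 32

    def validate(self) -> "CVConfig":
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValidationError("split ratios must sum to 1")
        if self.repeats < 2:
            raise ValidationError("need at least 2 repeats")
        return self


def _param_space(model: str, rng: np.random.Generator) -> dict:
    log_u = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if model == "svc":
        return {"C": log_u(0.01, 100.0), "gamma": log_u(1e-4, 1.0)}
    if model == "random_forest":
        return {
            "n_estimators": int(rng.choice([50, 100, 200])),
            "max_depth": int(rng.choice([3, 5, 10, 0])) or None,
            "max_features": str(rng.choice(["sqrt", "log2"])),
        }
    if model == "adaboost":
        return {"n_estimators": int(rng.choice([50, 100, 200])),
                "learning_rate": log_u(0.01, 1.0)}
    if model in ("gradient_boosting", "xgb", "lgbm"):
        return {
            "n_estimators": int(rng.choice([50, 100, 200])),
            "learning_rate": log_u(0.01, 0.3),
            "max_depth": int(rng.choice([2, 3, 4])),
        }
    if model == "hist_gb":
        return {"max_iter": int(rng.choice([50, 100, 200])),
                "learning_rate": log_u(0.01, 0.3),
                "max_depth": int(rng.choice([2, 3, 4]))}
    raise ValidationError(f"unknown model {model!r}")


def _make_estimator(model: str, params: dict, seed: int):
    if model == "svc":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", random_state=seed, **params)),
        ])
    if model == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if model == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if model == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if model == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", verbosity=0, **params,
        )
    if model == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
            force_row_wise=True, **params,
        )
    if model == "hist_gb":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    raise ValidationError(f"unknown model {model!r}")


def _draw_config(cfg: CVConfig, rng: np.random.Generator) -> dict:
    model = str(rng.choice(cfg.models))
    sampler = str(rng.choice(cfg.samplers))
    k = int(rng.choice(cfg.k_grid)) if rng.random() < 0.5 else None
    return {"model": model, "sampler": sampler, "k": k,
            "params": _param_space(model, rng)}


def _complexity_key(config: dict) -> str:
    return json.dumps(config, sort_keys=True)


# ---------------------------------------------------------------------------
# the CV engine
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    metrics: dict[str, tuple[float, float]]  # name -> (mean, sd)
    per_repeat: list[dict]
    best: dict
    feature_names: list[str]
    n_rows: int

    def to_dict(self) -> dict:
        return {
            "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
            "best": self.best,
            "n_rows": self.n_rows,
            "feature_names": self.feature_names,
            "per_repeat": self.per_repeat,
        }


METRICS = ("accuracy", "recall", "precision", "f1", "pr_auc")


def _impute(train: np.ndarray, *others: np.ndarray):
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)

    def fill(a):
        a = a.copy()
        bad = ~np.isfinite(a)
        a[bad] = np.broadcast_to(med, a.shape)[bad]
        return a

    return (fill(train),) + tuple(fill(o) for o in others)


def _fit_candidate(config, Xtr, ytr, seed, rng):
    Xres, yres = resample(config["sampler"], Xtr, ytr, rng)
    steps = []
    if config["k"] is not None:
        k = min(config["k"], Xres.shape[1])
        steps.append(("fs", SelectKBest(f_classif, k=k)))
    steps.append(("est", _make_estimator(config["model"], config["params"], seed)))
    pipe = Pipeline(steps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features under f_classif
        pipe.fit(Xres, yres)
    n_feat = k if config["k"] is not None else Xres.shape[1]
    return pipe, n_feat


def _scores(pipe, X):
    est = pipe.named_steps["est"]
    target = pipe
    if hasattr(est, "predict_proba") or (
        isinstance(est, Pipeline) and hasattr(est.named_steps["clf"], "predict_proba")
    ):
        try:
            return target.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    return np.asarray(target.decision_function(X), float)


def run_cv(dataset: Dataset, cfg: CVConfig | None = None, seed: int = 0) -> ClassificationReport:
    """Monte-Carlo cross-validated model selection and evaluation."""
    cfg = (cfg or CVConfig()).validate()
    X_all = dataset.X.to_numpy(float)
    y_all = dataset.y
    ids = np.asarray(dataset.ids)
    names = np.asarray(dataset.feature_names)
    if cfg.resample_validation:
        warnings.warn(
            "resample_validation=True resamples the validation split too; "
            "model selection may leak synthetic minority structure",
            stacklevel=2,
        )

    per_repeat = []
    counter = 0
    for rep in range(cfg.repeats):
        # derived seeds; re-drawn on degenerate splits
        while True:
            split_seed = (seed * 1_000_003 + counter) % (2**31 - 1)
            counter += 1
            idx = np.arange(len(y_all))
            trval, test = train_test_split(
                idx, test_size=cfg.ratios[2], stratify=y_all, random_state=split_seed
            )
            val_frac = cfg.ratios[1] / (cfg.ratios[0] + cfg.ratios[1])
            train, val = train_test_split(
                trval, test_size=val_frac, stratify=y_all[trval],
                random_state=split_seed + 1,
            )
            parts = [y_all[p] for p in (train, val, test)]
            if all(len(np.unique(p)) == 2 for p in parts):
                break
            warnings.warn(f"repeat {rep}: degenerate split re-drawn", stacklevel=2)

        Xtr, Xval, Xte = _impute(X_all[train], X_all[val], X_all[test])
        ytr, yval, yte = y_all[train], y_all[val], y_all[test]

        if cfg.refit_corr_filter:
            keep_names = correlation_filter(
                pd.DataFrame(Xtr, columns=names), cfg.corr_threshold
            )
            keep = [list(names).index(c) for c in keep_names]
            Xtr, Xval, Xte = Xtr[:, keep], Xval[:, keep], Xte[:, keep]

        rng = np.random.default_rng(split_seed + 2)
        if cfg.resample_validation:
            Xval_sel, yval_sel = resample("smote", Xval, yval, rng)
        else:
            Xval_sel, yval_sel = Xval, yval

        best = None  # (neg criteria tuple, config, pipe)
        for draw in range(cfg.search_draws):
            config = _draw_config(cfg, rng)
            try:
                pipe, n_feat = _fit_candidate(
                    config, Xtr, ytr, seed=int(rng.integers(2**31 - 1)), rng=rng
                )
            except Exception as exc:  # a pathological draw must not kill the run
                warnings.warn(f"draw {draw} failed: {exc}", stacklevel=2)
                continue
            val_f1 = f1_score(yval_sel, pipe.predict(Xval_sel), zero_division=0)
            key = (-val_f1, n_feat, _complexity_key(config), draw)
            if best is None or key < best[0]:
                best = (key, config, None)
        if best is None:
            raise ValidationError("every search draw failed")
        _, config, _ = best

        # winner refit on train+validation, scored on test
        Xtrval = np.vstack([Xtr, Xval])
        ytrval = np.r_[ytr, yval]
        refit_rng = np.random.default_rng(split_seed + 3)
        pipe, _ = _fit_candidate(
            config, Xtrval, ytrval, seed=split_seed % (2**31 - 1), rng=refit_rng
        )
        y_pred = pipe.predict(Xte)
        sc = _scores(pipe, Xte)
        rep_metrics = {
            "accuracy": accuracy_score(yte, y_pred),
            "recall": recall_score(yte, y_pred, zero_division=0),
            "precision": precision_score(yte, y_pred, zero_division=0),
            "f1": f1_score(yte, y_pred, zero_division=0),
            "pr_auc": average_precision_score(yte, sc),
        }
        per_repeat.append({
            "repeat": rep,
            "config": config,
            "metrics": {k: float(v) for k, v in rep_metrics.items()},
            "test_ids": ids[test].tolist(),
            "y_true": yte.tolist(),
            "y_pred": np.asarray(y_pred).tolist(),
        })

    metrics = {
        m: (
            float(np.mean([r["metrics"][m] for r in per_repeat])),
            float(np.std([r["metrics"][m] for r in per_repeat])),
        )
        for m in METRICS
    }
    # modal winning configuration (model, sampler, feature selection)
    keys = [
        (r["config"]["model"], r["config"]["sampler"], r["config"]["k"])
        for r in per_repeat
    ]
    uniq, counts = np.unique([json.dumps(k) for k in keys], return_counts=True)
    model, sampler, k = json.loads(uniq[np.argmax(counts)])
    best = {"model": model, "sampler": sampler, "fs_k": k}
    return ClassificationReport(
        metrics=metrics, per_repeat=per_repeat, best=best,
        feature_names=dataset.feature_names, n_rows=len(y_all),
    )


# ---------------------------------------------------------------------------
# explanation
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """A configuration refit on the whole dataset, for explanation."""

    pipe: Pipeline
    feature_names: list[str]
    medians: np.ndarray  # imputation values AND Shapley background
    keep: list[int]


def fit_final_model(dataset: Dataset, config: dict, seed: int = 0) -> FittedModel:
    """Refit a winning (model, sampler, k, params) configuration on all rows."""
    X = dataset.X.to_numpy(float)
    names = list(dataset.feature_names)
    (Xi,) = _impute(X)
    keep = list(range(len(names)))
    rng = np.random.default_rng(seed)
    full = dict(config)
    full.setdefault("params", _param_space(config["model"], rng))
    full.setdefault("k", None)
    pipe, _ = _fit_candidate(full, Xi, dataset.y, seed=seed, rng=rng)
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    return FittedModel(pipe=pipe, feature_names=names, medians=med, keep=keep)


def importance_ranking(
    fitted: FittedModel,
    dataset: Dataset,
    seed: int = 0,
    top: int = 5,
    n_permutations: int = 32,
) -> list[dict]:
    """Rank indicators by mean |Shapley attribution|, with signed direction.

    The direction is the sign of the association between the feature's value
    and its attribution to the MCI-class score: ``+`` means high values push
    the model toward MCI.
    """
    X = dataset.X.to_numpy(float)
    (Xi,) = _impute(X)
    f = score_function(fitted.pipe)
    out_scores = f(Xi)
    if np.ptp(out_scores) < 1e-12:
        warnings.warn("degenerate model (constant output): empty ranking", stacklevel=2)
        return []
    rng = np.random.default_rng(seed)
    phi = shapley_values(f, Xi, fitted.medians, rng, n_permutations=n_permutations)
    mean_abs = np.mean(np.abs(phi), axis=0)
    order = np.argsort(-mean_abs, kind="stable")[:top]
    ranking = []
    for j in order:
        xj, pj = Xi[:, j], phi[:, j]
        if np.ptp(xj) > 0 and np.ptp(pj) > 0:
            direction = "+" if np.corrcoef(xj, pj)[0, 1] >= 0 else "-"
        elif np.ptp(xj) > 0:
            direction = "+" if np.corrcoef(xj, out_scores)[0, 1] >= 0 else "-"
        else:
            direction = "+"
        ranking.append({
            "indicator": fitted.feature_names[j],
            "mean_abs_shap": float(mean_abs[j]),
            "direction": direction,
        })
    return ranking


@dataclass
class RadarProfile:
    """Min-max-normalized top-indicator profile of one misclassified sample.

    Indicators are ordered by decreasing relevance starting at the top radar
    position, proceeding counterclockwise.
    """

    sample_id: str
    repeat: int
    true_label: int
    pred_label: int
    indicators: list[str]
    values: list[float]
    mci_median: list[float]
    mci_q25: list[float]
    mci_q75: list[float]
    hc_median: list[float]
    hc_q25: list[float]
    hc_q75: list[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def misclassification_profiles(
    report: ClassificationReport, dataset: Dataset, top5: list[str]
) -> list[RadarProfile]:
    """Profile every misclassified test sample on the top indicators."""
    X = dataset.X
    lo = X[top5].min()
    hi = X[top5].max()
    span = (hi - lo).replace(0, 1.0)

    def norm(values: pd.Series | pd.DataFrame):
        return ((values - lo) / span).clip(0.0, 1.0)

    id_index = {sid: i for i, sid in enumerate(dataset.ids)}
    mci = norm(X.loc[np.asarray(dataset.y) == 1, top5])
    hc = norm(X.loc[np.asarray(dataset.y) == 0, top5])
    bands = {
        "mci_median": mci.median(), "mci_q25": mci.quantile(0.25), "mci_q75": mci.quantile(0.75),
        "hc_median": hc.median(), "hc_q25": hc.quantile(0.25), "hc_q75": hc.quantile(0.75),
    }
    profiles = []
    for rep in report.per_repeat:
        for sid, yt, yp in zip(rep["test_ids"], rep["y_true"], rep["y_pred"]):
            if yt == yp:
                continue
            row = norm(X.iloc[id_index[sid]][top5])
            profiles.append(RadarProfile(
                sample_id=sid, repeat=rep["repeat"], true_label=int(yt),
                pred_label=int(yp), indicators=list(top5),
                values=[float(v) for v in row],
                **{k: [float(x) for x in v[top5]] for k, v in bands.items()},
            ))
    return profiles
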