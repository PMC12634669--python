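"""Feature selection, base regressors, ridge-stacked ensemble and metrics.

Four base learners predict plot AGB from the selected features: a random
forest (300 trees, 6 candidate features per split), extreme gradient
boosting (500 rounds, depth 3, learning rate 0.01), a second
gradient-boosting machine (600 rounds, depth 6, learning rate 0.01, LightGBM
backend) and an RBF support-vector machine (C=10, gamma=0.01, standardized
inputs). Their out-of-fold predictions over a 5-fold split form a 4-column
meta-feature matrix on which a ridge regression (the meta-model) is fitted;
L2 shrinkage stabilises the meta-weights because tree-based base predictions
are strongly collinear. Per-fold base models are retained so every
prediction can also be made five times (once per fold ensemble), whose
population standard deviation is the fold-spread uncertainty.

Model evaluation uses two protocols: repeated 5-fold cross-validation (CV)
on the modelling plots, and external verification (EV) on plots withheld
from all training and tuning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .errors import ConfigurationError, DataError, SchemaError

# LightGBM invents "Column_i" feature names even for array input, which makes
# sklearn warn on every array predict; all fits here use arrays consistently.
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)

MODEL_NAMES = ["rf", "xgb", "gbm", "svm"]

#: tuned defaults of the four base learners
DEFAULT_SPECS = {
    "rf": {"n_estimators": 300, "max_features": 6},
    "xgb": {"n_estimators": 500, "max_depth": 3, "learning_rate": 0.01},
    "gbm": {"n_estimators": 600, "max_depth": 6, "learning_rate": 0.01},
    "svm": {"C": 10.0, "gamma": 0.01},
}

RIDGE_ALPHA_GRID = np.logspace(-3, 3, 13)


def make_model(name: str, params: dict | None = None, seed: int = 0, n_features: int | None = None):
    """Instantiate a base learner by name with tuned defaults overridable."""
    if name not in MODEL_NAMES:
        raise ConfigurationError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    p = dict(DEFAULT_SPECS[name])
    if params:
        p.update(params)
    try:
        if name == "rf":
            if n_features is not None and isinstance(p.get("max_features"), int):
                p["max_features"] = min(p["max_features"], n_features)
            return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
        if name == "xgb":
            return XGBRegressor(
                random_state=seed, n_jobs=1, verbosity=0, objective="reg:squarederror", **p
            )
        if name == "gbm":
            return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **p)
        return Pipeline(
            [("scale", StandardScaler()), ("svr", SVR(kernel="rbf", **p))]
        )
    except TypeError as exc:
        raise ConfigurationError(f"invalid parameters for {name}: {p}") from exc


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(y, y_hat) -> dict:
    """R², MAE, RMSE and RMSE% of predictions against observations.

    R² is one minus the ratio of residual to total sum of squares (so a
    constant mean predictor scores 0 and worse-than-mean scores negative);
    RMSE% is 100·RMSE/ȳ and requires a non-zero mean observation.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise DataError("evaluate needs two equal-length vectors of size >= 2")
    ybar = y.mean()
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    mae = float(np.mean(np.abs(y - y_hat)))
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    if ybar == 0:
        raise DataError("RMSE%% undefined: mean observation is zero")
    return {"r2": r2, "mae": mae, "rmse": rmse, "rmse_pct": 100.0 * rmse / ybar}


def fold_uncertainty(fold_predictions, expected_n: int = 5):
    """Population standard deviation of per-fold predictions (divide by n).

    ``fold_predictions`` is an array whose FIRST axis indexes the folds;
    its length must equal ``expected_n`` (override to relax).
    """
    p = np.asarray(fold_predictions, dtype=float)
    if p.shape[0] != expected_n:
        raise ConfigurationError(
            f"expected {expected_n} fold predictions, got {p.shape[0]}"
        )
    return np.sqrt(np.mean((p - p.mean(axis=0)) ** 2, axis=0))


# ---------------------------------------------------------------------------
# feature screening and selection
# ---------------------------------------------------------------------------

def pearson_screen(table: pd.DataFrame, feature_names, target_col: str = "agb") -> pd.DataFrame:
    """Pearson correlation of each feature with the target.

    Constant features have undefined correlation; they are reported as 0
    with ``constant=True``.
    """
    if len(table) < 3:
        raise DataError("need at least 3 rows for a correlation screen")
    y = table[target_col].to_numpy(dtype=float)
    rows = []
    for name in feature_names:
        x = table[name].to_numpy(dtype=float)
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            rows.append({"feature": name, "r": 0.0, "constant": True})
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"feature": name, "r": r, "constant": False})
    return pd.DataFrame(rows).set_index("feature")


def _cv_r2(X: np.ndarray, y: np.ndarray, name: str, params, cv_folds: int, seed: int) -> float:
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        model = make_model(name, params, seed=seed, n_features=X.shape[1])
        model.fit(X[tr], y[tr])
        scores.append(evaluate(y[te], model.predict(X[te]))["r2"])
    return float(np.mean(scores))


def _importances(model, name: str, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """Model-native importance for tree learners; permutation for the SVM."""
    if name in ("rf", "xgb", "gbm"):
        return np.asarray(model.feature_importances_, dtype=float)
    res = permutation_importance(model, X, y, n_repeats=5, random_state=seed, n_jobs=1)
    return np.asarray(res.importances_mean, dtype=float)


def rfecv_select(
    table: pd.DataFrame,
    feature_names,
    target_col: str = "agb",
    model_name: str = "rf",
    params: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    min_features: int = 1,
) -> dict:
    """Recursive feature elimination with cross-validated scoring.

    Starting from all features, the least important feature (model-native
    importance for tree learners, permutation importance for the SVM) is
    removed one at a time; the mean 5-fold CV R² is recorded at each step
    and the feature set with the best score wins, ties broken toward fewer
    features.

    Returns ``{"selected": [...], "ranking": {feature: rank}, "trace": [...]}``
    where a larger rank means the feature survived longer.
    """
    feats = list(feature_names)
    if len(feats) < 2:
        raise DataError("RFECV needs at least 2 features")
    y = table[target_col].to_numpy(dtype=float)
    if y.std() == 0:
        raise DataError("target has zero variance")
    ranking, trace, sets = {}, [], {}
    step = 0
    while len(feats) >= max(min_features, 1):
        X = table[feats].to_numpy(dtype=float)
        score = _cv_r2(X, y, model_name, params, cv_folds, seed)
        trace.append((len(feats), score))
        sets[len(feats)] = list(feats)
        if len(feats) == max(min_features, 1):
            break
        model = make_model(model_name, params, seed=seed, n_features=len(feats))
        model.fit(X, y)
        imp = _importances(model, model_name, X, y, seed)
        drop_idx = int(np.lexsort((np.arange(len(feats)), imp))[0])  # ties: first name
        ranking[feats[drop_idx]] = step
        step += 1
        feats.pop(drop_idx)
    # survivors: rank above all eliminated, ordered by final-step importance
    X = table[feats].to_numpy(dtype=float)
    model = make_model(model_name, params, seed=seed, n_features=len(feats))
    model.fit(X, y)
    imp = _importances(model, model_name, X, y, seed)
    for order, idx in enumerate(np.argsort(imp)):
        ranking[feats[idx]] = step + order
    best_score = max(s for _, s in trace)
    best_size = min(n for n, s in trace if s >= best_score - 1e-12)
    return {"selected": sets[best_size], "ranking": ranking, "trace": trace}


def consensus_features(per_model_selected: dict, per_model_ranking: dict, target_size: int = 20):
    """Features common to all models, adjusted to ``target_size`` by mean rank.

    The intersection of the per-model selections is taken first; if it is
    smaller than ``target_size`` the best non-common features (largest mean
    normalised rank over models) are appended, if larger the worst-ranked
    common features are removed. Returns ``(features, log)``.
    """
    lists = list(per_model_selected.values())
    if not lists:
        raise DataError("no per-model selections given")
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)

    def mean_rank(feature):
        vals = []
        for ranking in per_model_ranking.values():
            if ranking:
                top = max(ranking.values())
                vals.append(ranking.get(feature, -1) / max(top, 1))
        return float(np.mean(vals)) if vals else 0.0

    all_feats = sorted({f for lst in lists for f in lst} | {f for r in per_model_ranking.values() for f in r})
    if not common and not all_feats:
        raise DataError("empty intersection and no rankings to adjust from")
    ordered_common = sorted(common, key=lambda f: (-mean_rank(f), f))
    log = {"intersection_size": len(common), "added": [], "removed": []}
    selected = list(ordered_common)
    if len(selected) > target_size:
        log["removed"] = selected[target_size:]
        selected = selected[:target_size]
    elif len(selected) < target_size:
        candidates = [f for f in sorted(all_feats, key=lambda f: (-mean_rank(f), f)) if f not in common]
        add = candidates[: target_size - len(selected)]
        log["added"] = add
        selected = selected + add
    return selected, log


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass
class TunedModelSpec:
    """A model name, the grid searched, the chosen values and the CV trace."""

    model_name: str
    grid: dict
    chosen: dict
    cv_trace: list = field(default_factory=list)  # (params, mean CV RMSE)


def _complexity_key(params: dict):
    return tuple(
        (k, v if isinstance(v, (int, float)) else str(v)) for k, v in sorted(params.items())
    )


def grid_search_tune(
    table: pd.DataFrame,
    feature_names,
    target_col: str,
    model_name: str,
    grid: dict,
    cv_folds: int = 5,
    seed: int = 0,
) -> TunedModelSpec:
    """Exhaustive grid search scored by mean 5-fold CV RMSE.

    Ties are broken toward the smaller parameter values (fewer trees,
    shallower depth, smaller cost).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("empty hyperparameter grid")
    X = table[feature_names].to_numpy(dtype=float)
    y = table[target_col].to_numpy(dtype=float)
    keys = sorted(grid.keys())
    trace = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        rmses = []
        for tr, te in kf.split(X):
            model = make_model(model_name, params, seed=seed, n_features=X.shape[1])
            try:
                model.fit(X[tr], y[tr])
            except Exception as exc:  # backends raise their own error types
                raise ConfigurationError(
                    f"grid value failed for {model_name}: {params}: {exc}"
                ) from exc
            rmses.append(evaluate(y[te], model.predict(X[te]))["rmse"])
        trace.append((params, float(np.mean(rmses))))
    best = min(trace, key=lambda t: (round(t[1], 12), _complexity_key(t[0])))
    return TunedModelSpec(model_name=model_name, grid=grid, chosen=best[0], cv_trace=trace)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

@dataclass
class StackedModel:
    """Fold-wise base models, full-data base models and the ridge meta-model."""

    feature_names: list
    specs: dict  # model name -> params
    fold_ids: np.ndarray  # training-row fold assignment
    fold_models: list  # fold -> {model name: fitted estimator trained off-fold}
    full_models: dict  # model name -> estimator fitted on all training rows
    meta: Ridge
    oof: pd.DataFrame  # out-of-fold base predictions used to fit the meta-model
    scenario: str = ""
    cv_folds: int = 5

    @property
    def meta_coefficients(self) -> dict:
        return dict(zip(self.specs.keys(), self.meta.coef_.tolist()))

    @property
    def meta_intercept(self) -> float:
        return float(self.meta.intercept_)

    def _features(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in features.columns]
            if missing:
                raise SchemaError(f"missing features: {missing}")
            return features[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def base_predictions(self, features, models: dict | None = None) -> np.ndarray:
        X = self._features(features)
        models = self.full_models if models is None else models
        return np.column_stack([models[name].predict(X) for name in self.specs])

    def predict(self, features):
        """Stacked AGB prediction (Mg/ha), floored at 0 with a flag array."""
        meta_X = self.base_predictions(features)
        raw = self.meta.predict(meta_X)
        floored = raw < 0
        return np.maximum(raw, 0.0), floored

    def predict_foldwise(self, features) -> np.ndarray:
        """(cv_folds, n) stacked predictions, one per fold's base ensemble."""
        return np.stack(
            [
                self.meta.predict(self.base_predictions(features, models=fm))
                for fm in self.fold_models
            ]
        )


def fit_stacked(
    table: pd.DataFrame,
    feature_names,
    target_col: str,
    specs: dict | None = None,
    cv_folds: int = 5,
    ridge_alpha: float | None = None,
    seed: int = 0,
    scenario: str = "",
) -> StackedModel:
    """Fit the four base models and the ridge meta-model by stacking.

    The base models are trained per fold and predict their held-out fold;
    these strictly out-of-fold predictions form the n x 4 meta-feature
    matrix on which the ridge (with intercept) is fitted against the target.
    The ridge penalty is chosen by internal cross-validation over a log grid
    unless ``ridge_alpha`` pins it. Per-fold base models are kept for
    uncertainty mapping and full-data base models for deployment prediction.
    """
    specs = dict(DEFAULT_SPECS) if specs is None else specs
    feature_names = list(feature_names)
    X = table[feature_names].to_numpy(dtype=float)
    y = table[target_col].to_numpy(dtype=float)
    if len(y) < cv_folds:
        raise DataError(f"need at least {cv_folds} rows, got {len(y)}")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_ids = np.empty(len(y), dtype=int)
    oof = np.full((len(y), len(specs)), np.nan)
    fold_models = []
    for fold, (tr, te) in enumerate(kf.split(X)):
        fold_ids[te] = fold
        models = {}
        for j, (name, params) in enumerate(specs.items()):
            model = make_model(name, params, seed=seed, n_features=X.shape[1])
            model.fit(X[tr], y[tr])
            models[name] = model
            oof[te, j] = model.predict(X[te])
        fold_models.append(models)
    full_models = {}
    for name, params in specs.items():
        model = make_model(name, params, seed=seed, n_features=X.shape[1])
        model.fit(X, y)
        full_models[name] = model
    if ridge_alpha is None:
        chooser = RidgeCV(alphas=RIDGE_ALPHA_GRID)
        chooser.fit(oof, y)
        ridge_alpha = float(chooser.alpha_)
    meta = Ridge(alpha=ridge_alpha)
    meta.fit(oof, y)
    return StackedModel(
        feature_names=feature_names,
        specs=specs,
        fold_ids=fold_ids,
        fold_models=fold_models,
        full_models=full_models,
        meta=meta,
        oof=pd.DataFrame(oof, columns=list(specs.keys()), index=table.index),
        scenario=scenario,
        cv_folds=cv_folds,
    )


def predict_stacked(model: StackedModel, features):
    """Module-level convenience wrapper around :meth:`StackedModel.predict`."""
    return model.predict(features)


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def ev_split(n: int, ev_fraction: float, seed: int) -> np.ndarray:
    """Boolean mask of the external-verification rows (plot-level hold-out)."""
    if not 0.0 < ev_fraction <= 0.5:
        raise ConfigurationError("ev_fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n_ev = max(int(round(ev_fraction * n)), 1)
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:n_ev]] = True
    return mask


def run_protocols(
    table: pd.DataFrame,
    feature_names,
    target_col: str,
    specs: dict | None = None,
    ev_fraction: float = 0.2,
    cv_folds: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    scenario: str = "",
    compute_importance: bool = False,
) -> dict:
    """Run the CV and EV protocols for the base models and the stack.

    Plots are split once (seeded) into a modelling set and an external set;
    CV metrics come from repeated 5-fold cross-validation on the modelling
    set (mean and interquartile range over repetitions; the stacked CV
    prediction for a fold uses a ridge fitted on the other folds'
    out-of-fold predictions), EV metrics from the final models on the
    external set. Permutation importances (signed by the Pearson
    correlation with the target) are aggregated over repetitions on request.

    Returns a dict with ``cv`` and ``ev`` metric tables, the fitted
    :class:`StackedModel`, and optionally ``importance``.
    """
    if repetitions < 1:
        raise ConfigurationError("repetitions must be >= 1")
    specs = dict(DEFAULT_SPECS) if specs is None else specs
    feature_names = list(feature_names)
    mask_ev = ev_split(len(table), ev_fraction, seed)
    modelling = table.loc[~mask_ev]
    external = table.loc[mask_ev]
    y_mod = modelling[target_col].to_numpy(dtype=float)
    y_ev = external[target_col].to_numpy(dtype=float)

    # --- EV: one final fit on the modelling set, scored on withheld plots
    stacked = fit_stacked(
        modelling, feature_names, target_col, specs=specs, cv_folds=cv_folds,
        seed=seed, scenario=scenario,
    )
    ev_rows = []
    base_ev = stacked.base_predictions(external)
    for j, name in enumerate(specs):
        ev_rows.append({"model": name, **evaluate(y_ev, base_ev[:, j])})
    ev_rows.append({"model": "stacked", **evaluate(y_ev, stacked.predict(external)[0])})
    ev_table = pd.DataFrame(ev_rows).set_index("model")

    # --- CV: repeated k-fold on the modelling set
    rep_seeds = np.random.SeedSequence(seed).spawn(repetitions)
    per_rep = {name: [] for name in list(specs) + ["stacked"]}
    importances = {name: [] for name in specs} if compute_importance else None
    X_mod = modelling[feature_names].to_numpy(dtype=float)
    for rep, rep_seed in enumerate(rep_seeds):
        rep_int = int(rep_seed.generate_state(1)[0] % (2**31 - 1))
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=rep_int)
        oof = np.full((len(y_mod), len(specs)), np.nan)
        folds = list(kf.split(X_mod))
        for fold, (tr, te) in enumerate(folds):
            for j, (name, params) in enumerate(specs.items()):
                model = make_model(name, params, seed=rep_int, n_features=X_mod.shape[1])
                model.fit(X_mod[tr], y_mod[tr])
                oof[te, j] = model.predict(X_mod[te])
                if compute_importance:
                    res = permutation_importance(
                        model, X_mod[te], y_mod[te], n_repeats=3,
                        random_state=rep_int, n_jobs=1,
                    )
                    importances[name].append(res.importances_mean)
        for j, name in enumerate(specs):
            per_rep[name].append(evaluate(y_mod, oof[:, j]))
        stacked_oof = np.empty(len(y_mod))
        for fold, (tr, te) in enumerate(folds):
            chooser = RidgeCV(alphas=RIDGE_ALPHA_GRID)
            chooser.fit(oof[tr], y_mod[tr])
            stacked_oof[te] = chooser.predict(oof[te])
        per_rep["stacked"].append(evaluate(y_mod, stacked_oof))

    cv_rows = []
    for name, reps in per_rep.items():
        for metric in ("r2", "mae", "rmse", "rmse_pct"):
            vals = np.array([r[metric] for r in reps])
            q1, q3 = np.percentile(vals, [25, 75])
            cv_rows.append(
                {"model": name, "metric": metric, "mean": float(vals.mean()),
                 "q1": float(q1), "q3": float(q3)}
            )
    cv_table = pd.DataFrame(cv_rows).set_index(["model", "metric"])

    out = {"cv": cv_table, "ev": ev_table, "stacked_model": stacked,
           "ev_mask": mask_ev, "scenario": scenario}
    if compute_importance:
        screen = pearson_screen(modelling, feature_names, target_col)
        imp_rows = []
        for name, mats in importances.items():
            mean_imp = np.clip(np.mean(mats, axis=0), 0.0, None)
            total = mean_imp.sum() or 1.0
            for f, v in zip(feature_names, mean_imp):
                imp_rows.append(
                    {"model": name, "feature": f,
                     "importance_pct": 100.0 * float(v) / total,
                     "sign": float(np.sign(screen.loc[f, "r"]))}
                )
        out["importance"] = pd.DataFrame(imp_rows)
    return out
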