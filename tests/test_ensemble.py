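import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from agbstack.ensemble import (
    StackedModel,
    consensus_features,
    ev_split,
    evaluate,
    fit_stacked,
    fold_uncertainty,
    grid_search_tune,
    make_model,
    pearson_screen,
    rfecv_select,
    run_protocols,
)
from agbstack.errors import ConfigurationError, DataError, SchemaError

from conftest import FAST_SPECS


# --- metrics ----------------------------------------------------------------

def test_evaluate_identity_and_closed_form():
    y = np.array([1.0, 2.0, 3.0])
    perfect = evaluate(y, y)
    assert perfect == {"r2": 1.0, "mae": 0.0, "rmse": 0.0, "rmse_pct": 0.0}
    m = evaluate(y, np.array([2.0, 2.0, 2.0]))
    assert m["r2"] == pytest.approx(0.0)
    assert m["mae"] == pytest.approx(2 / 3)
    assert m["rmse"] == pytest.approx(np.sqrt(2 / 3))
    assert m["rmse_pct"] == pytest.approx(100 * np.sqrt(2 / 3) / 2)


def test_evaluate_identities_against_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(25):
        y = rng.normal(50, 20, 40)
        y_hat = y + rng.normal(0, 5, 40)
        m = evaluate(y, y_hat)
        # brute-force scalar formulations
        ss_res = sum((a - b) ** 2 for a, b in zip(y, y_hat))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        assert m["r2"] == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert m["mae"] == pytest.approx(sum(abs(a - b) for a, b in zip(y, y_hat)) / 40, abs=1e-10)
        assert m["rmse"] == pytest.approx(np.sqrt(ss_res / 40), abs=1e-10)
        assert m["rmse"] >= m["mae"]
        assert m["rmse_pct"] == pytest.approx(100 * m["rmse"] / y.mean(), abs=1e-10)
        # a constant mean predictor scores exactly zero
        assert evaluate(y, np.full(40, y.mean()))["r2"] == pytest.approx(0.0, abs=1e-12)


def test_evaluate_errors():
    with pytest.raises(DataError):
        evaluate([1.0], [1.0])
    with pytest.raises(DataError):
        evaluate([1.0, -1.0], [1.0, 0.0])  # mean zero -> RMSE% undefined


def test_fold_uncertainty_examples_and_oracle():
    assert fold_uncertainty([1, 2, 3, 4, 5]) == pytest.approx(np.sqrt(2))
    assert fold_uncertainty([7, 7, 7, 7, 7]) == 0.0
    p = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert fold_uncertainty(p + 100.0) == pytest.approx(fold_uncertainty(p))
    rng = np.random.default_rng(1)
    m = rng.normal(size=(5, 30))
    oracle = np.array([np.sqrt(np.mean((m[:, j] - m[:, j].mean()) ** 2)) for j in range(30)])
    np.testing.assert_allclose(fold_uncertainty(m), oracle, atol=1e-12)
    with pytest.raises(ConfigurationError):
        fold_uncertainty([1, 2, 3])


# --- screening / selection --------------------------------------------------

def test_pearson_screen():
    t = pd.DataFrame(
        {"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0], "c": [5.0, 5.0, 5.0],
         "agb": [2.0, 4.0, 6.0]}
    )
    screen = pearson_screen(t, ["a", "b", "c"])
    assert screen.loc["a", "r"] == pytest.approx(1.0)
    assert screen.loc["b", "r"] == pytest.approx(-1.0)
    assert screen.loc["c", "r"] == 0.0 and screen.loc["c", "constant"]


def test_rfecv_keeps_informative_feature(small_feature_table):
    """One informative + five noise features: the signal survives selection."""
    for seed in (0, 1, 2):
        res = rfecv_select(
            small_feature_table,
            ["signal", "noise0", "noise1", "noise2", "noise3", "noise4"],
            model_name="rf", params={"n_estimators": 40, "max_features": 2},
            seed=seed,
        )
        assert "signal" in res["selected"]
        assert res["ranking"]["signal"] == max(res["ranking"].values())


def test_rfecv_determinism_and_degenerate_target(small_feature_table):
    args = dict(model_name="rf", params={"n_estimators": 30}, seed=5)
    feats = ["signal", "noise0", "noise1"]
    a = rfecv_select(small_feature_table, feats, **args)
    b = rfecv_select(small_feature_table, feats, **args)
    assert a["selected"] == b["selected"] and a["trace"] == b["trace"]
    flat = small_feature_table.copy()
    flat["agb"] = 1.0
    with pytest.raises(DataError):
        rfecv_select(flat, feats, **args)


def test_rfecv_redundant_copies_collapse():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 1, 150)
    t = pd.DataFrame({"c1": x, "c2": x, "c3": x, "agb": 10 + 5 * x + rng.normal(0, 0.1, 150)})
    res = rfecv_select(t, ["c1", "c2", "c3"], model_name="rf",
                       params={"n_estimators": 30}, seed=0)
    assert len(res["selected"]) == 1


def test_consensus_rules():
    twenty = [f"f{i}" for i in range(20)]
    ranks = {m: {f: i for i, f in enumerate(twenty)} for m in "abcd"}
    same = {m: list(twenty) for m in "abcd"}
    sel, log = consensus_features(same, ranks, target_size=20)
    assert set(sel) == set(twenty) and log["intersection_size"] == 20

    # 18-feature intersection: the two best-ranked extras are appended
    lists = {m: twenty[:18] + [f"x{m}", "shared_extra"] for m in "abcd"}
    lists["a"] = twenty[:18] + ["xa", "xb"]
    ranks2 = {m: {f: i for i, f in enumerate(lst)} for m, lst in lists.items()}
    sel2, log2 = consensus_features(lists, ranks2, target_size=20)
    assert len(sel2) == 20 and set(twenty[:18]) <= set(sel2)
    assert len(log2["added"]) == 2

    # disjoint singletons, target 1: deterministic best-mean-rank choice
    singles = {m: [f] for m, f in zip("abcd", ["p", "q", "r", "s"])}
    ranks3 = {"a": {"p": 3}, "b": {"q": 2}, "c": {"r": 1}, "d": {"s": 0}}
    sel3, _ = consensus_features(singles, ranks3, target_size=1)
    assert len(sel3) == 1 and sel3[0] in {"p", "q", "r", "s"}
    sel3b, _ = consensus_features(singles, ranks3, target_size=1)
    assert sel3 == sel3b  # deterministic


# --- tuning -----------------------------------------------------------------

def test_grid_search_singleton_and_argmin(small_feature_table):
    feats = ["signal", "noise0"]
    spec = grid_search_tune(
        small_feature_table, feats, "agb", "rf",
        {"n_estimators": [25], "max_features": [1]}, seed=0,
    )
    assert spec.chosen == {"n_estimators": 25, "max_features": 1}
    spec2 = grid_search_tune(
        small_feature_table, feats, "agb", "rf",
        {"n_estimators": [10, 40], "max_features": [1, 2]}, seed=0,
    )
    best_rmse = min(r for _, r in spec2.cv_trace)
    chosen_rmse = dict((tuple(sorted(p.items())), r) for p, r in spec2.cv_trace)[
        tuple(sorted(spec2.chosen.items()))
    ]
    assert chosen_rmse == best_rmse
    assert all(spec2.chosen[k] in v for k, v in {"n_estimators": [10, 40], "max_features": [1, 2]}.items())
    # determinism
    spec3 = grid_search_tune(
        small_feature_table, feats, "agb", "rf",
        {"n_estimators": [10, 40], "max_features": [1, 2]}, seed=0,
    )
    assert spec3.chosen == spec2.chosen


def test_grid_search_invalid_values(small_feature_table):
    with pytest.raises(ConfigurationError):
        grid_search_tune(small_feature_table, ["signal"], "agb", "rf", {})
    with pytest.raises(ConfigurationError):
        grid_search_tune(
            small_feature_table, ["signal", "noise0"], "agb", "rf",
            {"n_estimators": [-5]}, seed=0,
        )


# --- stacking ---------------------------------------------------------------

class _Const:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def _stub_stack(weights, intercept, base_values):
    meta = Ridge(alpha=1.0)
    meta.fit(np.eye(4), np.zeros(4))
    meta.coef_ = np.asarray(weights, dtype=float)
    meta.intercept_ = float(intercept)
    full = {n: _Const(v) for n, v in zip(["rf", "xgb", "gbm", "svm"], base_values)}
    return StackedModel(
        feature_names=["f1"], specs={n: {} for n in full}, fold_ids=np.zeros(4, int),
        fold_models=[full] * 5, full_models=full, meta=meta,
        oof=pd.DataFrame(np.zeros((4, 4))),
    )


def test_stacked_prediction_dot_product():
    model = _stub_stack([0.25] * 4, 0.0, [40, 44, 48, 52])
    pred, floored = model.predict(pd.DataFrame({"f1": [1.0]}))
    assert pred[0] == pytest.approx(46.0) and not floored.any()
    # intercept-only meta-model predicts a constant
    const = _stub_stack([0.0] * 4, 33.0, [1, 2, 3, 4])
    pred2, _ = const.predict(pd.DataFrame({"f1": [0.0, 9.0]}))
    assert np.allclose(pred2, 33.0)
    # negative raw predictions are floored and flagged
    neg = _stub_stack([0.25] * 4, -100.0, [1, 2, 3, 4])
    pred3, floored3 = neg.predict(pd.DataFrame({"f1": [1.0]}))
    assert pred3[0] == 0.0 and floored3.all()


def test_stacked_missing_feature_raises():
    model = _stub_stack([0.25] * 4, 0.0, [1, 2, 3, 4])
    with pytest.raises(SchemaError):
        model.predict(pd.DataFrame({"wrong": [1.0]}))


def test_fit_stacked_oof_hygiene_and_determinism(small_feature_table):
    feats = ["signal", "noise0", "noise1", "noise2", "noise3", "noise4"]
    m1 = fit_stacked(small_feature_table, feats, "agb", specs=FAST_SPECS, seed=4)
    m2 = fit_stacked(small_feature_table, feats, "agb", specs=FAST_SPECS, seed=4)
    np.testing.assert_array_equal(m1.fold_ids, m2.fold_ids)
    np.testing.assert_allclose(m1.meta.coef_, m2.meta.coef_)
    pd.testing.assert_frame_equal(m1.oof, m2.oof)
    # fold partition is near-equal and disjoint by construction
    counts = np.bincount(m1.fold_ids)
    assert counts.sum() == len(small_feature_table) and counts.max() - counts.min() <= 1
    # out-of-fold hygiene: the stored fold models reproduce the OOF columns,
    # i.e. each row was predicted by models that never saw it
    X = small_feature_table[feats].to_numpy()
    for fold, models in enumerate(m1.fold_models):
        rows = m1.fold_ids == fold
        for j, name in enumerate(m1.specs):
            np.testing.assert_allclose(
                models[name].predict(X[rows]), m1.oof.to_numpy()[rows, j]
            )


def test_noisy_base_model_weight_shrinks():
    """A pure-noise base model gets a near-zero ridge weight."""
    rng = np.random.default_rng(9)
    n = 400
    y = rng.normal(100, 30, n)
    oof = np.column_stack([y + rng.normal(0, 2, n)] * 3 + [rng.normal(100, 30, n)])
    meta = Ridge(alpha=1e-6).fit(oof, y)
    assert abs(meta.coef_[3]) < 0.05
    assert sum(meta.coef_) == pytest.approx(1.0, abs=0.05)


def test_run_protocols_ev_independent_of_repetitions(small_feature_table):
    feats = ["signal", "noise0", "noise1"]
    fast = {"rf": {"n_estimators": 20, "max_features": 2}, "svm": {"C": 10.0, "gamma": 0.1}}
    r1 = run_protocols(small_feature_table, feats, "agb", specs=fast,
                       repetitions=1, seed=2)
    r2 = run_protocols(small_feature_table, feats, "agb", specs=fast,
                       repetitions=3, seed=2)
    pd.testing.assert_frame_equal(r1["ev"], r2["ev"])
    assert set(r1["cv"].index.get_level_values("model")) == {"rf", "svm", "stacked"}
    with pytest.raises(ConfigurationError):
        run_protocols(small_feature_table, feats, "agb", specs=fast, repetitions=0)
    with pytest.raises(ConfigurationError):
        ev_split(100, 0.7, 0)


def test_perfectly_learnable_signal_gives_high_ev_r2(small_feature_table):
    """A strong linear signal is learnable by every model family."""
    t = small_feature_table.copy()
    t["agb"] = 100.0 - 60.0 * t["signal"]  # noise-free
    res = run_protocols(t, ["signal", "noise0"], "agb", specs=FAST_SPECS,
                        repetitions=1, seed=0)
    assert (res["ev"]["r2"] > 0.9).all()
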