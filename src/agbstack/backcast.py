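"""Back-casting of under-threshold tree diameters from two inventory cycles.

The national inventory protocol measures only stems with DBH >= 5 cm, so
small trees present at the first cycle are invisible until they cross the
threshold. Trees measured in both cycles ("preserved" trees) yield annual
diameter increments; these are averaged within (plot, species, DBH class)
groups and subtracted from the later-cycle DBH of "entered" trees to
estimate their first-cycle diameter. A random 80/20 hold-out of preserved
trees validates the group-mean model before it is applied.

"Growth rate" here is the absolute annual increment in cm·yr⁻¹ — the group
rate is *subtracted* times the elapsed years, which is only dimensionally
coherent for an increment. A relative (multiplicative) mode is available via
``rate_mode="relative"`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, TemporalError

#: DBH classes partitioning (5, inf): (5,10], (10,15], (15,20], (20,inf)
DBH_CLASS_LABELS = ["C5_10", "C10_15", "C15_20", "C20_plus"]
_CLASS_EDGES = [10.0, 15.0, 20.0]

#: fallback hierarchy, most local first
FALLBACK_LEVELS = [
    ("plot_id", "species", "dbh_class"),
    ("plot_id", "dbh_class"),
    ("species", "dbh_class"),
    ("dbh_class",),
]

#: floor applied to non-physical back-cast diameters, cm
CLAMP_FLOOR_CM = 0.1

#: measurement threshold of the inventory protocol, cm
DBH_THRESHOLD_CM = 5.0


def classify_dbh(dbh_cm):
    """Map DBH (cm) to its class label.

    Diameters at or below 5 cm are assigned the lowest class ``C5_10`` — an
    entered tree's first-cycle class does not exist in the grouping, so its
    later-cycle class (normally (5,10]) is used instead.
    """
    arr = np.asarray(dbh_cm, dtype=float)
    idx = np.searchsorted(_CLASS_EDGES, arr, side="left")
    labels = np.asarray(DBH_CLASS_LABELS, dtype=object)[idx]
    return str(labels) if arr.ndim == 0 else labels


def tree_growth_rate(d1: float, d2: float, y1: int, y2: int) -> float:
    """Annual DBH increment (d2 - d1) / (y2 - y1), cm·yr⁻¹.

    Negative values (shrinkage or measurement error) are returned as-is;
    callers flag them rather than discard.
    """
    if y2 <= y1:
        raise TemporalError(f"second survey year {y2} must be after first {y1}")
    if d1 <= 0 or d2 <= 0:
        raise DataError("DBH values must be positive")
    return (d2 - d1) / (y2 - y1)


def pair_preserved(cycle1: pd.DataFrame, cycle2: pd.DataFrame) -> pd.DataFrame:
    """Match preserved trees across cycles by (plot_id, tree_id).

    Returns one row per tree with columns ``plot_id, tree_id, species,
    d1, y1, d2, y2, rate, negative_rate, dbh_class`` (class of cycle-1 DBH).
    """
    c1 = cycle1.loc[cycle1["measure_type"] == "measured"]
    c2 = cycle2.loc[cycle2["measure_type"] == "preserved"]
    merged = c1.merge(
        c2, on=["plot_id", "tree_id"], suffixes=("_1", "_2"), how="inner"
    )
    if len(merged) == 0:
        raise DataError("no preserved trees in common between the two cycles")
    out = pd.DataFrame(
        {
            "plot_id": merged["plot_id"],
            "tree_id": merged["tree_id"],
            "species": merged["species_1"],
            "d1": merged["dbh_cm_1"].astype(float),
            "y1": merged["year_1"].astype(int),
            "d2": merged["dbh_cm_2"].astype(float),
            "y2": merged["year_2"].astype(int),
        }
    )
    if (out["y2"] <= out["y1"]).any():
        raise TemporalError("preserved pair with non-increasing survey years")
    out["rate"] = (out["d2"] - out["d1"]) / (out["y2"] - out["y1"])
    out["negative_rate"] = out["rate"] < 0
    out["dbh_class"] = classify_dbh(out["d1"].to_numpy())
    return out


@dataclass
class GrowthRateTable:
    """Mean annual DBH increments keyed by (plot, species, class) with fallbacks.

    ``levels[k]`` maps a key tuple at fallback depth ``k`` (see
    :data:`FALLBACK_LEVELS`) to ``(mean rate, n_trees)``; depth 4 is the
    global mean over all training trees, used only when a class was never
    observed.
    """

    levels: list = field(default_factory=list)
    global_mean: float = 0.0
    global_n: int = 0
    rate_mode: str = "absolute"

    def rate_for(self, plot_id, species, dbh_class):
        """Resolve a group rate, returning ``(rate, depth)``.

        Depth 0 is the full (plot, species, class) group; deeper levels drop
        the most local keys first; depth 4 is the global mean.
        """
        keys = [
            (plot_id, species, dbh_class),
            (plot_id, dbh_class),
            (species, dbh_class),
            (dbh_class,),
        ]
        for depth, key in enumerate(keys):
            hit = self.levels[depth].get(key)
            if hit is not None:
                return hit[0], depth
        return self.global_mean, 4


def build_growth_table(
    pairs: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    rate_mode: str = "absolute",
):
    """Split preserved pairs 80/20 and average training rates per group.

    The split is random by tree, stratified by (species, DBH class) whenever
    the stratum holds at least two trees (singleton strata go to training).
    Negative individual rates are retained in group means; trimming them
    would bias the means downward.

    Returns ``(GrowthRateTable, holdout)`` with the hold-out rows untouched.
    """
    if len(pairs) == 0:
        raise DataError("zero preserved pairs")
    if not 0.0 < train_fraction < 1.0:
        raise DataError(f"train_fraction must be in (0,1), got {train_fraction}")
    rng = np.random.default_rng(seed)

    train_mask = np.zeros(len(pairs), dtype=bool)
    pairs = pairs.reset_index(drop=True)
    for _, idx in pairs.groupby(["species", "dbh_class"], sort=True).indices.items():
        idx = np.sort(idx)
        if len(idx) < 2:
            train_mask[idx] = True
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx))
        train_mask[idx[perm[:n_train]]] = True

    if train_mask.all() and len(pairs) >= 2:
        # tiny strata can exhaust the holdout; keep one tree aside
        train_mask[int(rng.integers(len(pairs)))] = False

    train = pairs.loc[train_mask]
    holdout = pairs.loc[~train_mask].reset_index(drop=True)

    if rate_mode == "absolute":
        rates = train["rate"]
    elif rate_mode == "relative":
        rates = (train["d2"] / train["d1"]) ** (1.0 / (train["y2"] - train["y1"])) - 1.0
    else:
        raise DataError(f"unknown rate_mode {rate_mode!r}")
    train = train.assign(_rate=rates.to_numpy())

    levels = []
    for keys in FALLBACK_LEVELS:
        grouped = train.groupby(list(keys), sort=True)["_rate"].agg(["mean", "size"])
        levels.append(
            {
                (k if isinstance(k, tuple) else (k,)): (float(m), int(n))
                for k, (m, n) in grouped.iterrows()
            }
        )
    table = GrowthRateTable(
        levels=levels,
        global_mean=float(train["_rate"].mean()),
        global_n=int(len(train)),
        rate_mode=rate_mode,
    )
    return table, holdout


def _apply_rate_back(table: GrowthRateTable, d2, rate, delta_t):
    if table.rate_mode == "relative":
        return d2 / (1.0 + rate) ** delta_t
    return d2 - rate * delta_t


def validate_holdout(table: GrowthRateTable, holdout: pd.DataFrame) -> dict:
    """Estimate cycle-1 DBH of hold-out preserved trees and score the model.

    The group is the tree's own (plot, species, class of measured cycle-1
    DBH) — known for hold-out trees — resolved through the fallback
    hierarchy. Returns R², RMSE (cm) and the scatter pairs.
    """
    from .ensemble import evaluate  # deferred: keeps this module import-light

    if len(holdout) == 0:
        raise DataError("empty holdout")
    est, depths = [], []
    for row in holdout.itertuples(index=False):
        rate, depth = table.rate_for(row.plot_id, row.species, row.dbh_class)
        est.append(_apply_rate_back(table, row.d2, rate, row.y2 - row.y1))
        depths.append(depth)
    est = np.asarray(est, dtype=float)
    measured = holdout["d1"].to_numpy(dtype=float)
    metrics = evaluate(measured, est)
    pairs = holdout.assign(estimated_d1=est, fallback_depth=depths)
    return {"r2": metrics["r2"], "rmse_cm": metrics["rmse"], "pairs": pairs}


@dataclass
class BackcastResult:
    """Estimated first-cycle diameters of entered trees plus flags."""

    records: pd.DataFrame  # inventory-schema rows, measure_type == "backcast"
    detail: pd.DataFrame  # per-tree estimate, fallback depth, flags
    summary: dict


def backcast_entered(
    table: GrowthRateTable,
    entered: pd.DataFrame,
    cycle1_year: int = 2017,
) -> BackcastResult:
    """Back-cast entered trees' DBH to the first survey year.

    ``D_first = D_later - rate(plot, species, class(D_later)) * delta_t``
    with the fallback hierarchy; estimates below 0.1 cm are clamped to 0.1
    and flagged ``clamped``; estimates >= 5 cm are kept and flagged
    ``over_threshold`` (boundary or recording errors in the field data).
    """
    if not table.levels or all(len(lv) == 0 for lv in table.levels):
        raise DataError("empty growth-rate table")
    entered = entered.loc[entered["measure_type"] == "entered"].reset_index(drop=True)
    cls = classify_dbh(entered["dbh_cm"].to_numpy(dtype=float))
    est = np.empty(len(entered))
    depths = np.empty(len(entered), dtype=int)
    for i, row in enumerate(entered.itertuples(index=False)):
        rate, depth = table.rate_for(row.plot_id, row.species, cls[i])
        delta_t = int(row.year) - cycle1_year
        if delta_t <= 0:
            raise TemporalError(
                f"entered tree surveyed in {row.year}, not after cycle-1 year {cycle1_year}"
            )
        est[i] = _apply_rate_back(table, float(row.dbh_cm), rate, delta_t)
        depths[i] = depth
    clamped = est < CLAMP_FLOOR_CM
    est = np.where(clamped, CLAMP_FLOOR_CM, est)
    over = est >= DBH_THRESHOLD_CM

    records = pd.DataFrame(
        {
            "plot_id": entered["plot_id"],
            "tree_id": entered["tree_id"],
            "species": entered["species"],
            "dbh_cm": est,
            "year": cycle1_year,
            "measure_type": "backcast",
        }
    )
    detail = entered.assign(
        dbh_backcast_cm=est,
        fallback_depth=depths,
        clamped=clamped,
        over_threshold=over,
    )
    q = np.percentile(est, [25, 50, 75]) if len(est) else [np.nan] * 3
    summary = {
        "count": int(len(est)),
        "mean_cm": float(np.mean(est)) if len(est) else float("nan"),
        "median_cm": float(q[1]),
        "q1_cm": float(q[0]),
        "q3_cm": float(q[2]),
        "n_clamped": int(clamped.sum()),
        "n_over_threshold": int(over.sum()),
    }
    return BackcastResult(records=records, detail=detail, summary=summary)
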