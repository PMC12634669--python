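"""Allometric tree and plot above-ground biomass.

Per tree, AGB = 0.3 · rho · D^(7/3) kg, with rho the basic wood density
(g·cm⁻³) and D the DBH (cm); the 7/3 exponent is the theoretical value of
the underlying average allometric relationship and 0.3·rho its coefficient.
Plot AGB is the sum over trees, converted to Mg·ha⁻¹ with the plot area.

Two scenarios are carried through the pipeline: *including* back-cast
under-threshold trees and *excluding* them (field-measured stems only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .inventory import DEFAULT_PLOT_AREA_HA

AGB_COEF = 0.3
AGB_EXP = 7.0 / 3.0


def tree_agb(rho, dbh_cm):
    """Above-ground biomass of a single stem, kg: 0.3 · rho · D^(7/3)."""
    rho = np.asarray(rho, dtype=float)
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(rho <= 0) or np.any(dbh <= 0):
        raise DataError("rho and DBH must be positive")
    out = AGB_COEF * rho * dbh**AGB_EXP
    return float(out) if out.ndim == 0 else out


def plot_agb(
    trees: pd.DataFrame,
    area_ha: float = DEFAULT_PLOT_AREA_HA,
    include_backcast: bool = True,
):
    """Plot-level AGB in Mg·ha⁻¹ for one plot.

    ``trees`` needs ``dbh_cm``, ``rho_g_cm3`` and ``measure_type`` columns;
    rows with ``measure_type == "backcast"`` are kept or dropped according
    to ``include_backcast``. Returns ``(agb_mg_ha, n_trees, empty_flag)``.
    """
    if area_ha <= 0:
        raise DataError(f"plot area must be positive, got {area_ha}")
    if not include_backcast:
        trees = trees.loc[trees["measure_type"] != "backcast"]
    if len(trees) == 0:
        return 0.0, 0, True
    total_kg = float(
        np.sum(tree_agb(trees["rho_g_cm3"].to_numpy(), trees["dbh_cm"].to_numpy()))
    )
    return total_kg / 1000.0 / area_ha, int(len(trees)), False


def scenario_table(
    trees: pd.DataFrame,
    areas_ha: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-plot AGB under both scenarios plus six-number summaries.

    ``trees`` holds first-cycle stems of all plots (measured + backcast) with
    densities attached; ``areas_ha`` optionally maps plot_id to area
    (default: the nominal 0.0667 ha everywhere).

    Returns ``(per_plot, summary)``; ``per_plot`` has columns ``plot_id,
    agb_incl, agb_excl, n_trees_incl, n_trees_excl, delta_pct``; ``summary``
    carries min/Q1/median/mean/Q3/max per scenario and the share of plots
    whose increment exceeds 10%.
    """
    rows = []
    for plot_id, sub in trees.groupby("plot_id", sort=True):
        area = DEFAULT_PLOT_AREA_HA if areas_ha is None else areas_ha[plot_id]
        incl, n_incl, _ = plot_agb(sub, area, include_backcast=True)
        excl, n_excl, _ = plot_agb(sub, area, include_backcast=False)
        delta = 100.0 * (incl - excl) / excl if excl > 0 else 0.0
        rows.append(
            {
                "plot_id": plot_id,
                "agb_incl": incl,
                "agb_excl": excl,
                "n_trees_incl": n_incl,
                "n_trees_excl": n_excl,
                "delta_pct": delta,
            }
        )
    per_plot = pd.DataFrame(rows)

    def six(values):
        v = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {
            "min": float(v.min()),
            "q1": float(q1),
            "median": float(med),
            "mean": float(v.mean()),
            "q3": float(q3),
            "max": float(v.max()),
        }

    summary = {
        "including_under_threshold": six(per_plot["agb_incl"]),
        "excluding_under_threshold": six(per_plot["agb_excl"]),
        "share_delta_over_10pct": float((per_plot["delta_pct"] > 10).mean()),
        "n_plots": int(len(per_plot)),
    }
    return per_plot, summary
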