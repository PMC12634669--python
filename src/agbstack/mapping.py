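"""Wall-to-wall AGB and fold-spread uncertainty maps from a stacked model.

Every valid pixel gets (a) the stacked prediction from the full-data base
models through the ridge meta-model and (b) the population standard
deviation of the five fold-wise stacked predictions (each fold's base
ensemble passed through the same meta-model) — the per-pixel uncertainty.
Processing is tiled to bound memory and is exactly invariant to tile size.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .ensemble import StackedModel, fold_uncertainty
from .errors import GeometryError, SchemaError, SummaryError
from .rasters import RasterGrid, Transform


@dataclass
class PredictionMap:
    """AGB grid (Mg/ha), uncertainty grid (Mg/ha) and provenance."""

    agb: RasterGrid
    uncertainty: RasterGrid
    provenance: dict = field(default_factory=dict)
    n_floored: int = 0


def predict_map(
    model: StackedModel,
    feature_grids: dict,
    transform: Transform,
    crs: str = "EPSG:32648",
    mask: np.ndarray | None = None,
    tile_size: int = 256,
) -> PredictionMap:
    """Predict AGB and fold-spread uncertainty over a grid of feature layers.

    ``feature_grids`` maps feature name to a 2-D array (or
    :class:`RasterGrid`) on one shared geometry; every feature the model was
    trained on must be present. Pixels where any feature is nodata — or the
    optional boolean ``mask`` is False — are nodata in both outputs.
    Negative stacked predictions are floored at 0 and counted.
    """
    arrays = {}
    for name in model.feature_names:
        if name not in feature_grids:
            raise SchemaError(f"missing feature grid: {name}")
        g = feature_grids[name]
        arrays[name] = g.data if isinstance(g, RasterGrid) else np.asarray(g, dtype=float)
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise GeometryError(f"feature grids differ in shape: {sorted(shapes)}")
    shape = shapes.pop()
    if mask is not None and mask.shape != shape:
        raise GeometryError("mask shape does not match feature grids")

    agb = np.full(shape, np.nan)
    unc = np.full(shape, np.nan)
    n_floored = 0
    n_feat = len(model.feature_names)
    for r0 in range(0, shape[0], tile_size):
        r1 = min(r0 + tile_size, shape[0])
        tile = np.empty((r1 - r0, shape[1], n_feat))
        for j, name in enumerate(model.feature_names):
            tile[:, :, j] = arrays[name][r0:r1]
        valid = ~np.isnan(tile).any(axis=2)
        if mask is not None:
            valid &= mask[r0:r1]
        if not valid.any():
            continue
        X = tile[valid]
        pred, floored = model.predict(X)
        n_floored += int(floored.sum())
        folds = model.predict_foldwise(X)  # (cv_folds, n)
        sd = fold_uncertainty(folds, expected_n=model.cv_folds)
        tile_agb = np.full(valid.shape, np.nan)
        tile_unc = np.full(valid.shape, np.nan)
        tile_agb[valid] = pred
        tile_unc[valid] = sd
        agb[r0:r1] = tile_agb
        unc[r0:r1] = tile_unc

    provenance = {
        "model": "ridge-stacked ensemble (" + ", ".join(model.specs) + ")",
        "scenario": model.scenario,
        "features": list(model.feature_names),
        "date": datetime.date.today().isoformat(),
        "tile_size": tile_size,
        "masked": mask is not None,
    }
    return PredictionMap(
        agb=RasterGrid(agb, transform, crs),
        uncertainty=RasterGrid(unc, transform, crs),
        provenance=provenance,
        n_floored=n_floored,
    )


def map_summary(pmap: PredictionMap, pixel_area_ha: float) -> dict:
    """Mean AGB density over valid pixels and the total stock they carry.

    ``total_mg = sum(valid pixel AGB) * pixel_area_ha``; also reports the
    mean uncertainty and the valid area.
    """
    values = pmap.agb.data
    valid = ~np.isnan(values)
    if not valid.any():
        raise SummaryError("no valid pixels to summarise")
    mean_agb = float(values[valid].mean())
    total_mg = float(values[valid].sum() * pixel_area_ha)
    unc = pmap.uncertainty.data[valid]
    return {
        "mean_agb_mg_ha": mean_agb,
        "total_agb_mg": total_mg,
        "mean_uncertainty_mg_ha": float(np.nanmean(unc)),
        "valid_area_ha": float(valid.sum() * pixel_area_ha),
        "n_valid_pixels": int(valid.sum()),
        "n_floored": pmap.n_floored,
    }
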