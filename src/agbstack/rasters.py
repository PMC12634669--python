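"""Raster stacks, spectral/topographic feature grids, and plot extraction.

Grids are plain 2-D float arrays with ``numpy.nan`` as the in-memory nodata
value; on disk every layer is a float32 TIFF (nodata −9999) with a JSON
sidecar carrying the geotransform and CRS, so that all layers of a stack
share one grid geometry. Coordinates follow the usual north-up raster
convention: x grows with columns, y shrinks with rows, and the pixel-center
of (row, col) is ``(x0 + (col+0.5)·dx, y0 − (row+0.5)·dy)``.

Feature grids cover the canonical 40-name predictor set: 12 reflectance
bands, 16 vegetation indices computed exactly as specified from those bands,
5 optional externally-supplied biophysical layers, and 7 DEM derivatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy import ndimage

from .errors import ConfigurationError, GeometryError
from .inventory import PlotGeometry

NODATA = -9999.0

BAND_NAMES = ["B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B9", "B11", "B12"]
VEG_INDEX_NAMES = [
    "BRI", "Chlgreen", "Chlrededge", "CIgreen", "CIrededge", "CVI", "GNDVI",
    "MCARI", "MSI", "MTCI", "MVI", "NDII", "NDSI", "NDVI", "SR", "TM5",
]
BIOPHYSICAL_NAMES = ["Cab", "CWC", "FAPAR", "Fcover", "LAI"]
TOPO_NAMES = ["Aspect", "Curvature", "Elevation", "Roughness", "Slope", "TPI", "TWI"]

#: the canonical 40 candidate predictors
CANONICAL_FEATURES = BAND_NAMES + VEG_INDEX_NAMES + BIOPHYSICAL_NAMES + TOPO_NAMES


@dataclass(frozen=True)
class Transform:
    """North-up affine geotransform (no rotation)."""

    x0: float  # x of the top-left corner
    y0: float  # y of the top-left corner
    dx: float  # pixel width (> 0)
    dy: float  # pixel height (> 0); y decreases down rows

    def pixel_center(self, row, col):
        return self.x0 + (np.asarray(col) + 0.5) * self.dx, self.y0 - (
            np.asarray(row) + 0.5
        ) * self.dy

    def index_of(self, x, y):
        """Fractional (row, col) of map coordinates (pixel centers at .0)."""
        col = (np.asarray(x) - self.x0) / self.dx - 0.5
        row = (self.y0 - np.asarray(y)) / self.dy - 0.5
        return row, col

    def bounds(self, shape):
        rows, cols = shape
        return (self.x0, self.y0 - rows * self.dy, self.x0 + cols * self.dx, self.y0)


@dataclass
class RasterGrid:
    """One named 2-D layer on a shared grid geometry."""

    data: np.ndarray  # float array, nan == nodata
    transform: Transform
    crs: str = "EPSG:32648"

    @property
    def shape(self):
        return self.data.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.transform == other.transform and self.crs == other.crs


def write_raster(grid: RasterGrid, path) -> None:
    """Write float32 TIFF + JSON geotransform sidecar (nodata −9999)."""
    path = Path(path)
    data = np.where(np.isnan(grid.data), NODATA, grid.data).astype(np.float32)
    tifffile.imwrite(path, data)
    t = grid.transform
    sidecar = {"x0": t.x0, "y0": t.y0, "dx": t.dx, "dy": t.dy, "crs": grid.crs, "nodata": NODATA}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raster(path) -> RasterGrid:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data[data == meta["nodata"]] = np.nan
    return RasterGrid(
        data=data,
        transform=Transform(meta["x0"], meta["y0"], meta["dx"], meta["dy"]),
        crs=meta["crs"],
    )


def validate_stack(stack: dict) -> None:
    """Check all layers share shape, transform and CRS."""
    grids = list(stack.values())
    for g in grids[1:]:
        if not grids[0].same_grid(g):
            raise GeometryError("raster stack layers differ in shape/transform/CRS")


# ---------------------------------------------------------------------------
# vegetation indices (computed exactly as specified from band reflectances)
# ---------------------------------------------------------------------------

def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / den
    return np.where(den == 0, np.nan, out)


_VEG_FORMULAS = {
    "BRI": lambda b: _safe_div(_safe_div(1.0, b["B3"]) - _safe_div(1.0, b["B5"]), b["B9"]),
    "Chlgreen": lambda b: _safe_div(b["B3"], b["B7"]),
    "Chlrededge": lambda b: _safe_div(b["B9"], b["B5"]) - 1.0,
    "CIgreen": lambda b: _safe_div(b["B9"], b["B3"]) - 1.0,
    "CIrededge": lambda b: _safe_div(b["B5"], b["B7"]),
    "CVI": lambda b: _safe_div(b["B9"] * b["B5"], b["B3"] ** 2),
    "GNDVI": lambda b: _safe_div(b["B7"] - b["B3"], b["B7"] + b["B3"]),
    "MCARI": lambda b: ((b["B5"] - b["B4"]) - 0.2 * (b["B5"] - b["B3"])) * (b["B5"] - b["B4"]),
    "MSI": lambda b: _safe_div(b["B11"], b["B8"]),
    "MTCI": lambda b: _safe_div(b["B6"] - b["B5"], b["B5"] - b["B4"]),
    "MVI": lambda b: _safe_div(b["B9"], b["B11"]),
    "NDII": lambda b: _safe_div(b["B8"] - b["B11"], b["B8"] + b["B11"]),
    "NDSI": lambda b: _safe_div(b["B11"] - b["B12"], b["B11"] + b["B12"]),
    "NDVI": lambda b: _safe_div(b["B8"] - b["B4"], b["B8"] + b["B4"]),
    "SR": lambda b: _safe_div(b["B8"], b["B11"]),
    "TM5": lambda b: _safe_div(b["B11"], b["B12"]),
}

_VEG_REQUIRED = {
    "BRI": ("B3", "B5", "B9"), "Chlgreen": ("B3", "B7"), "Chlrededge": ("B5", "B9"),
    "CIgreen": ("B3", "B9"), "CIrededge": ("B5", "B7"), "CVI": ("B3", "B5", "B9"),
    "GNDVI": ("B3", "B7"), "MCARI": ("B3", "B4", "B5"), "MSI": ("B8", "B11"),
    "MTCI": ("B4", "B5", "B6"), "MVI": ("B9", "B11"), "NDII": ("B8", "B11"),
    "NDSI": ("B11", "B12"), "NDVI": ("B4", "B8"), "SR": ("B8", "B11"),
    "TM5": ("B11", "B12"),
}


def vegetation_indices(bands: dict, names=None) -> dict:
    """Compute the 16 vegetation-index grids from band arrays.

    ``bands`` maps band name to array (grids or per-plot vectors — the
    formulas are elementwise). Division by zero yields nodata (nan) at that
    element; nan inputs propagate.

    Raises :class:`ConfigurationError` naming the first missing band.
    """
    names = VEG_INDEX_NAMES if names is None else names
    out = {}
    for name in names:
        for band in _VEG_REQUIRED[name]:
            if band not in bands:
                raise ConfigurationError(f"index {name} requires missing band {band}")
        out[name] = _VEG_FORMULAS[name]({k: np.asarray(v, dtype=float) for k, v in bands.items()})
    return out


# ---------------------------------------------------------------------------
# topographic indices
# ---------------------------------------------------------------------------

def _neighbor_stack(dem: np.ndarray):
    """3x3 neighborhood as a (8, rows, cols) stack, nan beyond the border."""
    padded = np.pad(dem.astype(float), 1, constant_values=np.nan)
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    r, c = dem.shape
    return np.stack([padded[1 + dr : 1 + dr + r, 1 + dc : 1 + dc + c] for dr, dc in shifts])


def _horn_gradients(dem: np.ndarray, cell_size: float):
    """Horn's 3x3 finite differences (edge cells use replicated borders)."""
    z = np.pad(dem.astype(float), 1, mode="edge")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell_size)  # +y = north (up rows)
    return dz_dx, dz_dy


def border_mask(shape) -> np.ndarray:
    """True on the 1-cell border, where 3x3 windows are shrunken."""
    m = np.zeros(shape, dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def _d8_flow_accumulation(dem: np.ndarray) -> np.ndarray:
    """D8 upslope cell counts (each cell contributes itself).

    Every cell drains to its steepest-descent neighbor (drop divided by
    horizontal distance); cells are processed from highest to lowest so each
    accumulation is complete before being passed on. Pits/flats keep their
    own accumulation.
    """
    rows, cols = dem.shape
    flat = np.where(np.isnan(dem), -np.inf, dem).ravel()
    order = np.argsort(flat, kind="stable")[::-1]  # high to low
    acc = np.ones(rows * cols)
    acc[np.isnan(dem).ravel()] = np.nan
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    dists = [np.hypot(dr, dc) for dr, dc in offsets]
    for idx in order:
        z = flat[idx]
        if not np.isfinite(z):
            continue
        r, c = divmod(idx, cols)
        best, target = 0.0, -1
        for (dr, dc), dist in zip(offsets, dists):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                zn = flat[rr * cols + cc]
                if np.isfinite(zn):
                    drop = (z - zn) / dist
                    if drop > best:
                        best, target = drop, rr * cols + cc
        if target >= 0:
            acc[target] += acc[idx]
    return acc.reshape(rows, cols)


#: slope floor (radians) applied inside TWI so flats stay finite
TWI_SLOPE_FLOOR_RAD = 0.001


def topographic_indices(dem: np.ndarray, cell_size: float) -> dict:
    """Seven DEM derivatives on the DEM's own grid.

    Elevation (pass-through), Slope (degrees, Horn), Aspect (degrees
    clockwise from north, 0 on flats), Curvature (Zevenbergen–Thorne total,
    per 100 length units), Roughness (3x3 max−min including the center),
    TPI (center − mean of the 8 neighbors) and TWI
    (``ln(Ac / tan(slope))`` with Ac the D8 upslope area in m², slope
    floored at 0.001 rad). Border cells use shrunken windows — see
    :func:`border_mask`.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ConfigurationError("DEM must be at least 3x3")
    neigh = _neighbor_stack(dem)
    dz_dx, dz_dy = _horn_gradients(dem, cell_size)

    slope_rad = np.arctan(np.hypot(dz_dx, dz_dy))
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    aspect = np.where(slope_rad == 0, 0.0, aspect)

    # Zevenbergen–Thorne: D, E from the 4-neighbor cross
    z = np.pad(dem, 1, mode="edge")
    z_n, z_s = z[:-2, 1:-1], z[2:, 1:-1]
    z_w, z_e = z[1:-1, :-2], z[1:-1, 2:]
    dd = ((z_w + z_e) / 2.0 - dem) / cell_size**2
    ee = ((z_n + z_s) / 2.0 - dem) / cell_size**2
    curvature = -2.0 * (dd + ee) * 100.0

    with np.errstate(invalid="ignore"):
        roughness = np.fmax(np.nanmax(neigh, axis=0), dem) - np.fmin(
            np.nanmin(neigh, axis=0), dem
        )
        tpi = dem - np.nanmean(neigh, axis=0)

    acc = _d8_flow_accumulation(dem)
    area_m2 = acc * cell_size**2
    twi = np.log(area_m2 / np.tan(np.maximum(slope_rad, TWI_SLOPE_FLOOR_RAD)))

    nanmask = np.isnan(dem)
    out = {
        "Elevation": dem.copy(),
        "Slope": np.degrees(slope_rad),
        "Aspect": aspect,
        "Curvature": curvature,
        "Roughness": roughness,
        "TPI": tpi,
        "TWI": twi,
    }
    for name, grid in out.items():
        grid[nanmask] = np.nan
    return out


def aspect_encoding(aspect_deg: np.ndarray) -> dict:
    """Optional circular encoding of aspect for modelling."""
    rad = np.radians(aspect_deg)
    return {"Aspect_cos": np.cos(rad), "Aspect_sin": np.sin(rad)}


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_grid(
    grid: RasterGrid,
    target_transform: Transform,
    target_shape,
    method: str = "bilinear",
) -> RasterGrid:
    """Resample onto a target grid (bilinear for continuous layers, nearest
    for masks), nodata-aware. Source and target must share a CRS."""
    if method not in ("bilinear", "nearest"):
        raise ConfigurationError(f"unknown resampling method {method!r}")
    rows, cols = np.mgrid[0 : target_shape[0], 0 : target_shape[1]]
    x, y = target_transform.pixel_center(rows, cols)
    src_r, src_c = grid.transform.index_of(x, y)
    coords = np.stack([src_r, src_c])
    order = 1 if method == "bilinear" else 0
    valid = np.isfinite(grid.data).astype(float)
    filled = np.where(np.isfinite(grid.data), grid.data, 0.0)
    num = ndimage.map_coordinates(filled, coords, order=order, mode="nearest")
    wgt = ndimage.map_coordinates(valid, coords, order=order, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        data = np.where(wgt > 0.999, num / np.maximum(wgt, 1e-12), np.nan)
    inside = (src_r > -0.5) & (src_r < grid.shape[0] - 0.5) & (src_c > -0.5) & (
        src_c < grid.shape[1] - 0.5
    )
    data = np.where(inside, data, np.nan)
    return RasterGrid(data=data, transform=target_transform, crs=grid.crs)


# ---------------------------------------------------------------------------
# feature grids and plot extraction
# ---------------------------------------------------------------------------

def compute_feature_grids(stack: dict) -> dict:
    """Derive every available canonical feature grid from a raster stack.

    ``stack`` maps layer name to :class:`RasterGrid`: the 12 bands (required
    for the indices they feed), optional biophysical layers, and
    ``Elevation`` (the DEM) for the 7 terrain derivatives. Returns a dict of
    plain arrays on the shared grid.
    """
    validate_stack(stack)
    grids = {name: g.data for name, g in stack.items()}
    out = {name: grids[name] for name in BAND_NAMES if name in grids}
    band_arrays = {name: grids[name] for name in BAND_NAMES if name in grids}
    available = [
        n for n in VEG_INDEX_NAMES if all(b in band_arrays for b in _VEG_REQUIRED[n])
    ]
    out.update(vegetation_indices(band_arrays, names=available))
    for name in BIOPHYSICAL_NAMES:
        if name in grids:
            out[name] = grids[name]
    if "Elevation" in grids:
        any_grid = next(iter(stack.values()))
        out.update(topographic_indices(grids["Elevation"], cell_size=any_grid.transform.dx))
    return out


def extract_plot_features(
    feature_grids: dict,
    transform: Transform,
    footprints: list[PlotGeometry],
) -> tuple[pd.DataFrame, dict]:
    """Mean of pixels whose centers fall inside each footprint, per feature.

    Plots covering zero pixel centers or containing nodata in any feature
    are dropped and reported. Returns ``(table, report)`` with the table
    indexed by ``plot_id``.
    """
    names = list(feature_grids.keys())
    sample = next(iter(feature_grids.values()))
    xmin, ymin, xmax, ymax = transform.bounds(sample.shape)
    rows_out, dropped = [], {"outside_extent": [], "no_pixels": [], "nodata": []}
    for geom in footprints:
        gx0, gy0, gx1, gy1 = geom.footprint.bounds
        if gx1 < xmin or gx0 > xmax or gy1 < ymin or gy0 > ymax:
            raise GeometryError(f"footprint {geom.plot_id} fully outside raster extent")
        r0, c1 = transform.index_of(gx0, gy0)  # lower-left -> max row, min col
        r1, c0 = transform.index_of(gx1, gy1)
        r_lo = max(int(np.floor(r1)), 0)
        r_hi = min(int(np.ceil(r0)) + 1, sample.shape[0])
        c_lo = max(int(np.floor(c1)), 0)
        c_hi = min(int(np.ceil(c0)) + 1, sample.shape[1])
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        if rr.size == 0:
            dropped["no_pixels"].append(geom.plot_id)
            continue
        px, py = transform.pixel_center(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(geom.footprint, px, py)
        if not inside.any():
            dropped["no_pixels"].append(geom.plot_id)
            continue
        sel_r, sel_c = rr.ravel()[inside], cc.ravel()[inside]
        row = {"plot_id": geom.plot_id, "n_pixels": int(inside.sum())}
        has_nodata = False
        for name in names:
            vals = feature_grids[name][sel_r, sel_c]
            if np.isnan(vals).any():
                has_nodata = True
                break
            row[name] = float(vals.mean())
        if has_nodata:
            dropped["nodata"].append(geom.plot_id)
            continue
        rows_out.append(row)
    table = pd.DataFrame(rows_out)
    if len(table):
        table = table.set_index("plot_id")
    report = {k: v for k, v in dropped.items()}
    report["n_kept"] = len(rows_out)
    return table, report


def feature_schema(names) -> dict:
    """Sidecar schema: feature name -> formula/source description."""
    desc = {}
    for n in names:
        if n in BAND_NAMES:
            desc[n] = "surface reflectance band (pass-through)"
        elif n in BIOPHYSICAL_NAMES:
            desc[n] = "biophysical layer (externally supplied, pass-through)"
        elif n in TOPO_NAMES:
            desc[n] = "DEM derivative"
        else:
            desc[n] = f"vegetation index of bands {', '.join(_VEG_REQUIRED[n])}"
    return desc
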