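import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from agbstack.errors import ConfigurationError, GeometryError
from agbstack.inventory import PlotGeometry
from agbstack.rasters import (
    BAND_NAMES,
    VEG_INDEX_NAMES,
    RasterGrid,
    Transform,
    _d8_flow_accumulation,
    extract_plot_features,
    read_raster,
    resample_to_grid,
    topographic_indices,
    vegetation_indices,
    write_raster,
)
from agbstack.synthetic import generate_feature_table, generate_rasters

from conftest import exact_config

# independent scalar formulations of every index, straight from the table
SCALAR_ORACLES = {
    "BRI": lambda b: (1 / b["B3"] - 1 / b["B5"]) / b["B9"],
    "Chlgreen": lambda b: b["B3"] / b["B7"],
    "Chlrededge": lambda b: b["B9"] / b["B5"] - 1,
    "CIgreen": lambda b: b["B9"] / b["B3"] - 1,
    "CIrededge": lambda b: b["B5"] / b["B7"],
    "CVI": lambda b: b["B9"] * b["B5"] / b["B3"] ** 2,
    "GNDVI": lambda b: (b["B7"] - b["B3"]) / (b["B7"] + b["B3"]),
    "MCARI": lambda b: ((b["B5"] - b["B4"]) - 0.2 * (b["B5"] - b["B3"])) * (b["B5"] - b["B4"]),
    "MSI": lambda b: b["B11"] / b["B8"],
    "MTCI": lambda b: (b["B6"] - b["B5"]) / (b["B5"] - b["B4"]),
    "MVI": lambda b: b["B9"] / b["B11"],
    "NDII": lambda b: (b["B8"] - b["B11"]) / (b["B8"] + b["B11"]),
    "NDSI": lambda b: (b["B11"] - b["B12"]) / (b["B11"] + b["B12"]),
    "NDVI": lambda b: (b["B8"] - b["B4"]) / (b["B8"] + b["B4"]),
    "SR": lambda b: b["B8"] / b["B11"],
    "TM5": lambda b: b["B11"] / b["B12"],
}


def test_vegetation_indices_match_scalar_oracle():
    rng = np.random.default_rng(1)
    bands = {name: rng.uniform(0.01, 0.5, (16, 16)) for name in BAND_NAMES}
    out = vegetation_indices(bands)
    assert set(out) == set(VEG_INDEX_NAMES)
    for name, grid in out.items():
        for r in range(16):
            for c in range(16):
                pixel = {b: bands[b][r, c] for b in BAND_NAMES}
                assert grid[r, c] == pytest.approx(SCALAR_ORACLES[name](pixel), abs=1e-10)


def test_index_examples_and_zero_division():
    b = {n: np.full((2, 2), 0.2) for n in BAND_NAMES}
    assert vegetation_indices(b, names=["NDVI"])["NDVI"] == pytest.approx(0.0)  # B8 == B4
    b["B8"] = np.full((2, 2), 0.4)
    b["B4"] = np.full((2, 2), 0.1)
    assert vegetation_indices(b, names=["NDVI"])["NDVI"][0, 0] == pytest.approx(0.6)
    b["B5"], b["B4"], b["B3"] = (np.full((2, 2), v) for v in (0.2, 0.1, 0.15))
    assert vegetation_indices(b, names=["MCARI"])["MCARI"][0, 0] == pytest.approx(0.009)
    # zero denominator and nan inputs both yield nodata
    b["B4"] = np.array([[0.1, 0.1], [0.1, np.nan]])
    b["B8"] = np.array([[-0.1, 0.4], [0.4, 0.4]])
    ndvi = vegetation_indices(b, names=["NDVI"])["NDVI"]
    assert np.isnan(ndvi[0, 0]) and np.isnan(ndvi[1, 1]) and np.isfinite(ndvi[0, 1])


def test_missing_band_is_named():
    with pytest.raises(ConfigurationError, match="B11"):
        vegetation_indices({"B8": np.ones((2, 2))}, names=["MSI"])


def test_topographic_constants_and_window_example():
    flat = topographic_indices(np.full((5, 5), 100.0), cell_size=10.0)
    assert np.allclose(flat["Roughness"], 0) and np.allclose(flat["TPI"], 0)
    assert np.allclose(flat["Slope"], 0)
    assert np.isfinite(flat["TWI"]).all()  # slope floor keeps flats finite

    dem = np.array([[1.0, 2.0, 3.0], [4.0, 9.0, 5.0], [6.0, 7.0, 8.0]])
    out = topographic_indices(dem, cell_size=10.0)
    assert out["TPI"][1, 1] == pytest.approx(9 - 4.5)
    assert out["Roughness"][1, 1] == pytest.approx(8.0)


def test_tpi_roughness_match_brute_force_windows():
    rng = np.random.default_rng(2)
    dem = rng.uniform(0, 100, (12, 12))
    out = topographic_indices(dem, cell_size=10.0)
    for r in range(1, 11):
        for c in range(1, 11):
            window = dem[r - 1 : r + 2, c - 1 : c + 2]
            neighbors = np.delete(window.ravel(), 4)
            assert out["TPI"][r, c] == pytest.approx(dem[r, c] - neighbors.mean(), abs=1e-10)
            assert out["Roughness"][r, c] == pytest.approx(window.max() - window.min(), abs=1e-10)


def test_d8_accumulation_and_twi_formula():
    # columns descend west->east; every cell drains due east
    dem = np.array([[3.0, 2.0, 1.0]] * 3)
    acc = _d8_flow_accumulation(dem)
    np.testing.assert_allclose(acc, [[1, 2, 3]] * 3)
    out = topographic_indices(dem, cell_size=10.0)
    # interior column: Ac = 2 cells * 100 m2, Horn slope on a uniform ramp
    slope = math.atan(0.1 / 10.0 * 10)  # dz/dx = 1 m per 10 m
    assert out["TWI"][1, 1] == pytest.approx(math.log(200.0 / math.tan(slope)))


def test_aspect_convention():
    rows = np.arange(5)[:, None] * np.ones((1, 5))
    south_up = topographic_indices(rows * 1.0, cell_size=1.0)  # z grows southward
    assert np.allclose(south_up["Aspect"][2, 2], 0.0)  # faces north
    east_down = topographic_indices(-np.arange(5)[None, :] * np.ones((5, 1)), 1.0)
    assert np.allclose(east_down["Aspect"][2, 2], 90.0)  # faces east


def _grid(data, x0=0.0, y0=100.0, d=10.0):
    return RasterGrid(np.asarray(data, dtype=float), Transform(x0, y0, d, d))


def test_resample_identity_and_constant():
    rng = np.random.default_rng(3)
    g = _grid(rng.uniform(size=(8, 8)))
    same = resample_to_grid(g, g.transform, g.shape, method="bilinear")
    np.testing.assert_array_equal(same.data, g.data)
    const = _grid(np.full((6, 6), 4.2))
    fine = resample_to_grid(const, Transform(0.0, 60.0, 5.0, 5.0), (12, 12))
    assert np.allclose(fine.data[np.isfinite(fine.data)], 4.2)


def test_resample_bilinear_bounds():
    rng = np.random.default_rng(4)
    coarse = _grid(rng.uniform(10, 20, (10, 10)), d=30.0)  # 30 m DEM
    fine = resample_to_grid(coarse, Transform(0.0, 300.0, 10.0, 10.0), (30, 30))
    valid = fine.data[np.isfinite(fine.data)]
    assert valid.min() >= coarse.data.min() - 1e-9
    assert valid.max() <= coarse.data.max() + 1e-9


def test_raster_io_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    data = rng.uniform(size=(9, 9)).astype(np.float32).astype(float)
    data[0, 0] = np.nan
    g = _grid(data)
    write_raster(g, tmp_path / "x.tif")
    back = read_raster(tmp_path / "x.tif")
    assert back.transform == g.transform
    np.testing.assert_array_equal(np.isnan(back.data), np.isnan(g.data))
    np.testing.assert_allclose(back.data[1:], g.data[1:], rtol=1e-7)


def test_extract_mean_of_covered_pixels():
    data = np.array([[1.0, 2.0], [3.0, 4.0]])
    transform = Transform(0.0, 20.0, 10.0, 10.0)
    footprint = PlotGeometry("P1", Polygon([(0, 0), (20, 0), (20, 20), (0, 20)]))
    table, report = extract_plot_features({"f": data}, transform, [footprint])
    assert table.loc["P1", "f"] == pytest.approx(2.5)
    assert table.loc["P1", "n_pixels"] == 4
    assert report["n_kept"] == 1


def test_extract_drops_nodata_and_errors_outside():
    data = np.array([[1.0, np.nan], [3.0, 4.0]])
    transform = Transform(0.0, 20.0, 10.0, 10.0)
    inside = PlotGeometry("P1", Polygon([(0, 0), (20, 0), (20, 20), (0, 20)]))
    table, report = extract_plot_features({"f": data}, transform, [inside])
    assert len(table) == 0 and report["nodata"] == ["P1"]
    outside = PlotGeometry("P2", Polygon([(100, 100), (120, 100), (120, 120), (100, 120)]))
    with pytest.raises(GeometryError):
        extract_plot_features({"f": data}, transform, [outside])


def test_generated_rasters_shape_and_transform():
    cfg = exact_config()
    stack, footprints = generate_rasters(cfg, {g.plot_id: 80.0 for g in footprints_of(cfg)})
    band = stack["B4"]
    assert band.shape == cfg.raster_shape
    assert band.transform.dx == cfg.pixel_size_m
    assert len(stack) == 18  # 12 bands + 5 biophysical + DEM


def footprints_of(cfg):
    from agbstack.synthetic import generate_footprints

    return generate_footprints(cfg)


def test_identity_signal_band_is_affine_in_agb():
    """With zero noise and a one-band signal, the painted band is an exact
    affine transform of the supplied plot AGB."""
    cfg = exact_config(signal_coefficients={"B8": 2.0}, signal_intercept=10.0)
    agb = {g.plot_id: 50.0 + 3.0 * i for i, g in enumerate(footprints_of(cfg))}
    stack, footprints = generate_rasters(cfg, agb)
    table, _ = extract_plot_features(
        {"B8": stack["B8"].data}, stack["B8"].transform, footprints
    )
    expected = (np.array([agb[p] for p in table.index]) - 10.0) / 2.0
    np.testing.assert_allclose(table["B8"].to_numpy(), expected, atol=1e-9)


def test_zero_noise_extraction_reproduces_plan():
    """Raster-extracted band/elevation features equal the generator's plan."""
    cfg = exact_config()
    plan_table = generate_feature_table(cfg)
    from agbstack.synthetic import generate_plan

    plan = generate_plan(cfg)
    stack, footprints = generate_rasters(cfg, plan["agb_true"])
    grids = {name: stack[name].data for name in ["B4", "B8", "B11", "Elevation"]}
    table, report = extract_plot_features(grids, stack["B4"].transform, footprints)
    assert report["n_kept"] == cfg.n_plots
    for name in ["B4", "B8", "B11", "Elevation"]:
        if name == "B12":
            continue
        np.testing.assert_allclose(
            table[name].to_numpy(), plan_table.loc[table.index, name].to_numpy(), atol=1e-9
        )


def test_footprint_outside_extent_raises():
    cfg = exact_config(raster_shape=(12, 12))  # far too small for 12 plots
    with pytest.raises(GeometryError):
        generate_rasters(cfg, {f"P{i:04d}": 50.0 for i in range(cfg.n_plots)})
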