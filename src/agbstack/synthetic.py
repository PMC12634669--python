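"""Synthetic two-cycle inventories, plot footprints and raster stacks.

The generator emulates a national-inventory campaign over square 0.0667-ha
plots (25.82 m x 25.82 m) with a 5-cm DBH measurement threshold, a first
survey in 2017 and a revisit 4–6 years later, and co-registered 10-m raster
predictors. It is built so every downstream stage has known ground truth:

1. Per plot, predictor values ("the plan") are sampled first and the true
   plot AGB is *defined* as a configured linear signal of those predictors
   plus N(0, ``agb_noise_sd``) noise. Environment drives biomass, so an
   ordinary least-squares regression of plot AGB on the plan features
   recovers ``signal_coefficients`` (the noise is orthogonal to the
   features by construction).
2. A tree list (lognormal baseline DBH, species from a configurable pool)
   is scaled by a common power-law factor so its summed allometric biomass
   equals that plot's AGB exactly. A fraction of plots are regeneration
   "hotspots" carrying extra small stems, which makes the under-threshold
   share and its biomass increment vary realistically between plots.
3. Each (plot, species, DBH class) group receives one true annual DBH
   increment; growth is linear in time, so the back-casting stage can
   recover the truth. Mortality is off by default (``dropout_rate``).
4. Rasters paint each plot's plan values into its footprint (constant
   within the plot) over a spatially autocorrelated background, with the
   first signal feature solved per plot so the configured signal reproduces
   the supplied plot AGB up to ``agb_noise_sd``.

Fixing ``seed`` fixes every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .allometry import AGB_EXP, tree_agb
from .backcast import GrowthRateTable, classify_dbh
from .errors import ConfigurationError, GeometryError
from .inventory import PlotGeometry
from .rasters import (
    BAND_NAMES,
    BIOPHYSICAL_NAMES,
    RasterGrid,
    Transform,
    vegetation_indices,
)

#: sampling ranges of the plan features (uniform); reflectances sit in the
#: regime of closed-canopy vegetation
FEATURE_RANGES = {
    "B1": (0.010, 0.050), "B2": (0.020, 0.060), "B3": (0.030, 0.090),
    "B4": (0.020, 0.100), "B5": (0.050, 0.150), "B6": (0.100, 0.300),
    "B7": (0.150, 0.400), "B8": (0.150, 0.450), "B8A": (0.150, 0.450),
    "B9": (0.100, 0.350), "B11": (0.080, 0.280), "B12": (0.050, 0.420),
    "Cab": (20.0, 60.0), "CWC": (0.005, 0.060), "FAPAR": (0.30, 0.95),
    "Fcover": (0.20, 0.95), "LAI": (0.5, 6.0),
    "Elevation": (200.0, 1400.0), "Slope": (0.0, 40.0), "Aspect": (0.0, 360.0),
    "Curvature": (-2.0, 2.0), "Roughness": (0.0, 30.0), "TPI": (-5.0, 5.0),
    "TWI": (4.0, 12.0),
}

_DEFAULT_SPECIES = (
    ("Quercus", 0.5762),
    ("P.massoniana", 0.4476),
    ("Cunninghamia Lanceolata", 0.3098),
    ("Betula", 0.4848),
    ("Eucalyptus", 0.5820),
    ("Cryptomeria", 0.3493),
)

_DEFAULT_SIGNAL = {"B12": -300.0, "B8": 60.0, "B4": -200.0, "Elevation": 0.01}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark (defaults ARE the benchmark)."""

    n_plots: int = 600
    plot_side_m: float = 25.82
    species_pool: tuple = _DEFAULT_SPECIES
    trees_per_plot: tuple = (60, 140)
    #: (mu, sigma) of the baseline lognormal DBH before plot-level scaling
    dbh_lognormal_params: tuple = (2.35, 0.44)
    #: (mean, sd) of true annual increments, cm/yr, one draw per group
    group_increment_params: tuple = (0.30, 0.10)
    #: truncation bounds of sampled increments, cm/yr
    increment_bounds: tuple = (0.05, 0.80)
    dbh_noise_sd_cm: float = 1.0
    cycle1_year: int = 2017
    cycle2_years: tuple = (2021, 2022, 2023)
    #: share of plots carrying a dense cohort of extra small stems
    regen_hotspot_prob: float = 0.15
    #: mean of the exponential intensity of that extra cohort (stems/plot)
    regen_stems_mean: float = 180.0
    #: (mu, sigma) of the lognormal DBH of extra regeneration stems
    regen_dbh_lognormal: tuple = (math.log(4.4), 0.25)
    dropout_rate: float = 0.0
    raster_shape: tuple = (220, 220)
    pixel_size_m: float = 10.0
    origin_xy: tuple = (500000.0, 3300000.0)
    crs: str = "EPSG:32648"
    #: linear weights of plan features defining true plot AGB; the FIRST key
    #: is the feature solved per plot when painting rasters for a given AGB
    signal_coefficients: dict = field(default_factory=lambda: dict(_DEFAULT_SIGNAL))
    signal_intercept: float = 140.0
    #: residual noise between the feature signal and realised plot AGB, Mg/ha
    agb_noise_sd: float = 19.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 10:
            raise ConfigurationError("n_plots must be >= 10")
        if self.plot_side_m <= 0 or self.pixel_size_m <= 0:
            raise ConfigurationError("lengths must be positive")
        if self.dbh_noise_sd_cm < 0 or self.agb_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        lo, hi = self.trees_per_plot
        if not (0 < lo <= hi):
            raise ConfigurationError("trees_per_plot must be a positive range")
        if not all(t > self.cycle1_year for t in self.cycle2_years):
            raise ConfigurationError("revisit years must follow the first survey")
        if not self.signal_coefficients:
            raise ConfigurationError("signal_coefficients must not be empty")

    @property
    def plot_area_ha(self) -> float:
        return self.plot_side_m**2 / 10_000.0


@dataclass
class SyntheticDataset:
    """Everything one seeded draw of the generator knows."""

    plan: pd.DataFrame  # per-plot plan features + agb_signal + agb_true
    cycle1: pd.DataFrame
    cycle2: pd.DataFrame
    truth: GrowthRateTable
    truth_increments: pd.DataFrame  # (plot_id, species, dbh_class, increment, n)
    plot_truth: pd.DataFrame  # per-plot true incl/excl AGB and under-threshold share
    trees_truth: pd.DataFrame  # per-stem true d1/d2, increment and threshold status


def _streams(config: SyntheticConfig):
    root = np.random.SeedSequence(config.seed)
    plan_s, tree_s, bg_s, eps_s = root.spawn(4)
    return (
        np.random.default_rng(plan_s),
        np.random.default_rng(tree_s),
        np.random.default_rng(bg_s),
        np.random.default_rng(eps_s),
    )


def _plot_ids(n):
    return [f"P{i:04d}" for i in range(n)]


def generate_plan(config: SyntheticConfig) -> pd.DataFrame:
    """Per-plot plan features and the latent AGB signal (deterministic in seed)."""
    config.validate()
    rng, _, _, _ = _streams(config)
    ids = _plot_ids(config.n_plots)
    plan = pd.DataFrame(index=pd.Index(ids, name="plot_id"))
    for name, (lo, hi) in FEATURE_RANGES.items():
        plan[name] = rng.uniform(lo, hi, size=config.n_plots)
    signal = np.full(config.n_plots, config.signal_intercept)
    for feat, coef in config.signal_coefficients.items():
        if feat not in plan.columns:
            raise ConfigurationError(f"signal feature {feat!r} is not a plan feature")
        signal = signal + coef * plan[feat].to_numpy()
    plan["agb_signal"] = signal
    # noise drawn here so inventory and raster calls agree on the truth
    plan["agb_true"] = np.maximum(signal + rng.normal(0.0, config.agb_noise_sd, config.n_plots), 2.0)
    return plan


def _rho_lookup(config: SyntheticConfig):
    names = [s for s, _ in config.species_pool]
    rhos = np.array([r for _, r in config.species_pool])
    return names, rhos


def generate_inventory(config: SyntheticConfig):
    """Generate both survey cycles plus the true growth-rate table.

    Returns ``(cycle1, cycle2, truth)``; use :func:`generate_dataset` for the
    plan and per-plot truth as well.
    """
    return generate_dataset(config)[:3]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    config.validate()
    plan = generate_plan(config)
    _, rng, _, _ = _streams(config)
    names, rhos = _rho_lookup(config)
    mu0, sigma = config.dbh_lognormal_params
    inc_mean, inc_sd = config.group_increment_params
    area = config.plot_area_ha

    rows1, rows2, truth_rows, plot_rows, tree_rows = [], [], [], [], []
    for plot_id in plan.index:
        target = float(plan.loc[plot_id, "agb_true"])
        n_base = int(rng.integers(config.trees_per_plot[0], config.trees_per_plot[1] + 1))
        sp_idx = rng.integers(0, len(names), size=n_base)
        d1 = rng.lognormal(mu0, sigma, size=n_base)
        if rng.random() < config.regen_hotspot_prob:
            lam = rng.exponential(config.regen_stems_mean)
            m = int(rng.poisson(lam))
            if m > 0:
                d1 = np.concatenate([d1, rng.lognormal(*config.regen_dbh_lognormal, size=m)])
                sp_idx = np.concatenate([sp_idx, rng.integers(0, len(names), size=m)])
        rho = rhos[sp_idx]
        realised = float(np.sum(tree_agb(rho, d1))) / 1000.0 / area
        d1 = d1 * (target / realised) ** (1.0 / AGB_EXP)  # scale to hit target exactly

        cls = classify_dbh(d1)
        t2 = int(rng.choice(config.cycle2_years))
        dt = t2 - config.cycle1_year
        # one true increment per (species, class) group within the plot
        incs = np.empty(len(d1))
        group_keys = sorted({(names[s], c) for s, c in zip(sp_idx, cls)})
        group_inc = {}
        for sp, c in group_keys:
            inc = float(np.clip(rng.normal(inc_mean, inc_sd), *config.increment_bounds))
            group_inc[(sp, c)] = inc
        for i in range(len(d1)):
            incs[i] = group_inc[(names[sp_idx[i]], cls[i])]
        d2 = d1 + incs * dt

        alive = rng.random(len(d1)) >= config.dropout_rate
        noise1 = rng.normal(0.0, config.dbh_noise_sd_cm, len(d1)) if config.dbh_noise_sd_cm else np.zeros(len(d1))
        noise2 = rng.normal(0.0, config.dbh_noise_sd_cm, len(d1)) if config.dbh_noise_sd_cm else np.zeros(len(d1))

        under = d1 < 5.0
        for i in range(len(d1)):
            tree_id = f"T{i:04d}"
            sp = names[sp_idx[i]]
            tree_rows.append(
                (plot_id, tree_id, sp, d1[i], d2[i], incs[i], cls[i], bool(under[i]), bool(alive[i]))
            )
            if not under[i]:
                # measured at the threshold protocol: recorded DBH never < 5
                rows1.append((plot_id, tree_id, sp, max(5.0, d1[i] + noise1[i]), config.cycle1_year, "measured"))
                if alive[i]:
                    rows2.append((plot_id, tree_id, sp, max(0.1, d2[i] + noise2[i]), t2, "preserved"))
            elif alive[i] and d2[i] >= 5.0:
                rows2.append((plot_id, tree_id, sp, max(5.0, d2[i] + noise2[i]), t2, "entered"))

        for (sp, c), inc in sorted(group_inc.items()):
            n_grp = int(np.sum([(names[s] == sp) and (cc == c) for s, cc in zip(sp_idx, cls)]))
            truth_rows.append((plot_id, sp, c, inc, n_grp))

        excl_true = float(np.sum(tree_agb(rho[~under], d1[~under]))) / 1000.0 / area if (~under).any() else 0.0
        plot_rows.append(
            {
                "plot_id": plot_id,
                "agb_incl_true": target,
                "agb_excl_true": excl_true,
                "n_stems_true": int(len(d1)),
                "n_under_true": int(under.sum()),
                "under_share": float(under.mean()),
                "cycle2_year": t2,
            }
        )

    cols = ["plot_id", "tree_id", "species", "dbh_cm", "year", "measure_type"]
    cycle1 = pd.DataFrame(rows1, columns=cols)
    cycle2 = pd.DataFrame(rows2, columns=cols)
    truth_increments = pd.DataFrame(
        truth_rows, columns=["plot_id", "species", "dbh_class", "increment", "n_trees"]
    )
    truth = _truth_table(truth_increments)
    plot_truth = pd.DataFrame(plot_rows).set_index("plot_id")
    trees_truth = pd.DataFrame(
        tree_rows,
        columns=["plot_id", "tree_id", "species", "d1_true", "d2_true",
                 "increment", "dbh_class", "under_threshold", "alive"],
    )
    return SyntheticDataset(plan, cycle1, cycle2, truth, truth_increments, plot_truth, trees_truth)


def _truth_table(truth_increments: pd.DataFrame) -> GrowthRateTable:
    """Assemble the true increments into the fallback-table structure."""
    df = truth_increments.loc[truth_increments["n_trees"] > 0].copy()
    expanded = df.loc[df.index.repeat(df["n_trees"])]
    levels = []
    for keys in [("plot_id", "species", "dbh_class"), ("plot_id", "dbh_class"),
                 ("species", "dbh_class"), ("dbh_class",)]:
        grouped = expanded.groupby(list(keys), sort=True)["increment"].agg(["mean", "size"])
        levels.append(
            {
                (k if isinstance(k, tuple) else (k,)): (float(m), int(n))
                for k, (m, n) in grouped.iterrows()
            }
        )
    return GrowthRateTable(
        levels=levels,
        global_mean=float(expanded["increment"].mean()),
        global_n=int(len(expanded)),
    )


# ---------------------------------------------------------------------------
# footprints and rasters
# ---------------------------------------------------------------------------

def generate_footprints(config: SyntheticConfig) -> list[PlotGeometry]:
    """Non-overlapping square footprints laid out on a jittered grid."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    side = config.plot_side_m
    cell = side + 3.0 * config.pixel_size_m
    per_row = int(math.ceil(math.sqrt(config.n_plots)))
    x0, y0 = config.origin_xy
    extent_x = config.raster_shape[1] * config.pixel_size_m
    extent_y = config.raster_shape[0] * config.pixel_size_m
    if per_row * cell > min(extent_x, extent_y):
        raise GeometryError(
            f"{config.n_plots} plots need a {per_row * cell:.0f} m extent; raster covers "
            f"{extent_x:.0f} m x {extent_y:.0f} m"
        )
    out = []
    for k, plot_id in enumerate(_plot_ids(config.n_plots)):
        r, c = divmod(k, per_row)
        jx, jy = rng.uniform(0.0, cell - side, size=2)
        llx = x0 + c * cell + jx
        lly = y0 - (r + 1) * cell + jy
        out.append(
            PlotGeometry(
                plot_id=plot_id,
                footprint=Polygon(
                    [(llx, lly), (llx + side, lly), (llx + side, lly + side), (llx, lly + side)]
                ),
            )
        )
    return out


def _paint(grid, footprint, value, transform):
    gx0, gy0, gx1, gy1 = footprint.bounds
    r_hi, c_lo = transform.index_of(gx0, gy0)
    r_lo, c_hi = transform.index_of(gx1, gy1)
    r_range = np.arange(max(int(np.floor(r_lo)), 0), min(int(np.ceil(r_hi)) + 1, grid.shape[0]))
    c_range = np.arange(max(int(np.floor(c_lo)), 0), min(int(np.ceil(c_hi)) + 1, grid.shape[1]))
    if len(r_range) == 0 or len(c_range) == 0:
        return
    rr, cc = np.meshgrid(r_range, c_range, indexing="ij")
    px, py = transform.pixel_center(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(footprint, px, py)
    grid[rr.ravel()[inside], cc.ravel()[inside]] = value


def generate_rasters(config: SyntheticConfig, plot_agb) -> tuple[dict, list[PlotGeometry]]:
    """Raster stack (12 bands, 5 biophysical layers, DEM) plus footprints.

    ``plot_agb`` maps plot_id to the AGB (Mg/ha) the imagery should encode
    (a dict, Series, or DataFrame with an ``agb_incl`` column). Inside each
    footprint every layer is constant at the plot's plan value, except the
    first signal feature, which is solved so the configured linear signal
    equals that plot's AGB plus N(0, ``agb_noise_sd``) noise. Outside
    footprints, layers show a smoothed (spatially autocorrelated) background.
    """
    config.validate()
    if isinstance(plot_agb, pd.DataFrame):
        plot_agb = plot_agb["agb_incl"]
    plot_agb = dict(plot_agb)
    plan = generate_plan(config)
    _, _, bg_rng, eps_rng = _streams(config)
    footprints = generate_footprints(config)
    transform = Transform(
        x0=config.origin_xy[0], y0=config.origin_xy[1],
        dx=config.pixel_size_m, dy=config.pixel_size_m,
    )
    xmin, ymin, xmax, ymax = transform.bounds(config.raster_shape)
    for g in footprints:
        gx0, gy0, gx1, gy1 = g.footprint.bounds
        if gx0 < xmin or gy0 < ymin or gx1 > xmax or gy1 > ymax:
            raise GeometryError(f"footprint {g.plot_id} outside raster extent")

    signal_feats = list(config.signal_coefficients.keys())
    primary = signal_feats[0]
    c_primary = config.signal_coefficients[primary]
    eps = {
        pid: (eps_rng.normal(0.0, config.agb_noise_sd) if config.agb_noise_sd else 0.0)
        for pid in plan.index
    }
    solved = {}
    for pid in plan.index:
        if pid not in plot_agb:
            raise GeometryError(f"plot {pid} missing from plot_agb")
        rest = config.signal_intercept + sum(
            config.signal_coefficients[f] * plan.loc[pid, f] for f in signal_feats[1:]
        )
        solved[pid] = (float(plot_agb[pid]) + eps[pid] - rest) / c_primary

    def background(lo, hi):
        noise = bg_rng.normal(size=config.raster_shape)
        smooth = ndimage.gaussian_filter(noise, sigma=5.0)
        s = (smooth - smooth.min()) / max(smooth.max() - smooth.min(), 1e-12)
        return lo + s * (hi - lo)

    stack = {}
    for name in BAND_NAMES + BIOPHYSICAL_NAMES + ["Elevation"]:
        lo, hi = FEATURE_RANGES[name]
        grid = background(lo, hi)
        for g in footprints:
            value = solved[g.plot_id] if name == primary else float(plan.loc[g.plot_id, name])
            _paint(grid, g.footprint, value, transform)
        stack[name] = RasterGrid(data=grid, transform=transform, crs=config.crs)
    return stack, footprints


def generate_feature_table(config: SyntheticConfig, targets: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-plot table of all canonical features from the plan (tabular path).

    Band, biophysical and topographic columns come straight from the plan;
    vegetation indices are computed from the plan band values with the same
    formulas the raster path uses (bands are constant within a footprint, so
    the plot mean of an index equals the index of the plot band values).
    ``targets`` (a frame indexed by plot_id, e.g. the per-plot AGB table) is
    joined on when given.
    """
    plan = generate_plan(config)
    bands = {b: plan[b].to_numpy() for b in BAND_NAMES}
    table = plan.drop(columns=["agb_signal", "agb_true"]).copy()
    for name, values in vegetation_indices(bands).items():
        table[name] = values
    if targets is not None:
        table = table.join(targets, how="inner")
    return table
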