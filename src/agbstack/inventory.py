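"""Inventory, wood-density and plot-geometry I/O.

The canonical in-memory container for tree records is a :class:`pandas.DataFrame`
with the columns in :data:`INVENTORY_COLUMNS`:

``plot_id``       plot identifier (string)
``tree_id``       tree identifier, unique within a plot and stable across cycles
``species``       species code/name as it appears in the wood-density table
``dbh_cm``        diameter at breast height (1.3 m), cm, strictly positive
``year``          survey calendar year
``measure_type``  one of ``measured`` (first cycle), ``preserved`` (re-measured
                  in the second cycle), ``entered`` (crossed the 5-cm threshold
                  between cycles) or ``backcast`` (produced by the pipeline's
                  diameter back-casting stage — never read from disk by default)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .errors import DensityLookupError, FormatError

INVENTORY_COLUMNS = ["plot_id", "tree_id", "species", "dbh_cm", "year", "measure_type"]

#: measure types accepted when reading inventories from disk
DISK_MEASURE_TYPES = {"measured", "preserved", "entered"}

#: the full set, including the pipeline-internal back-cast category
MEASURE_TYPES = DISK_MEASURE_TYPES | {"backcast"}

#: nominal fixed-area plot footprint (square of 25.82 m x 25.82 m)
DEFAULT_PLOT_AREA_HA = 0.0667
DEFAULT_PLOT_SIDE_M = 25.82


# ---------------------------------------------------------------------------
# inventory tables
# ---------------------------------------------------------------------------

def read_inventory(path, expected_years, allow_backcast: bool = False):
    """Read and clean a tree-level inventory CSV.

    Rows with missing or non-positive DBH, an unknown ``measure_type``, or a
    ``year`` outside ``expected_years`` are dropped and counted; surviving rows
    are never mutated.

    Returns ``(records, report)`` where ``report`` maps drop reason to count.

    Raises
    ------
    FormatError
        If the file is empty or a required column is missing.
    """
    path = Path(path)
    try:
        # round_trip parsing keeps write->read lossless to the last ULP
        df = pd.read_csv(
            path,
            dtype={"plot_id": str, "tree_id": str, "species": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty inventory file: {path}") from None
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"inventory {path} missing required columns: {missing}")
    if len(df) == 0:
        raise FormatError(f"inventory {path} contains no rows")

    accepted = MEASURE_TYPES if allow_backcast else DISK_MEASURE_TYPES
    expected_years = set(int(y) for y in expected_years)

    report = {"missing_dbh": 0, "nonpositive_dbh": 0, "bad_measure_type": 0, "bad_year": 0}
    dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
    bad_missing = dbh.isna()
    bad_nonpos = ~bad_missing & (dbh <= 0)
    bad_type = ~df["measure_type"].isin(accepted)
    year = pd.to_numeric(df["year"], errors="coerce")
    bad_year = year.isna() | ~year.isin(expected_years)

    report["missing_dbh"] = int(bad_missing.sum())
    report["nonpositive_dbh"] = int(bad_nonpos.sum())
    report["bad_measure_type"] = int((bad_type & ~bad_missing & ~bad_nonpos).sum())
    report["bad_year"] = int(
        (bad_year & ~bad_type & ~bad_missing & ~bad_nonpos).sum()
    )

    keep = ~(bad_missing | bad_nonpos | bad_type | bad_year)
    out = df.loc[keep, INVENTORY_COLUMNS].copy()
    out["dbh_cm"] = dbh[keep]
    out["year"] = year[keep].astype(int)
    out = out.reset_index(drop=True)
    return out, report


def write_inventory(records: pd.DataFrame, path) -> None:
    """Write an inventory table to CSV (lossless round-trip with read)."""
    records.loc[:, INVENTORY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# wood density
# ---------------------------------------------------------------------------

def _normalize_species(name: str) -> str:
    return " ".join(str(name).split()).casefold()


_GROUP_DEFAULT_KEYS = {
    "pine": "Other pines",
    "hardwood": "Other hardwood broad-leaves",
    "softwood": "Other softwood broad-leaves",
}


@dataclass
class WoodDensityTable:
    """Species -> basic wood density rho (g·cm⁻³) with group fallbacks.

    Lookup is case-insensitive exact match on a whitespace-normalised code;
    unmatched species fall back to the group default ("Other pines",
    "Other hardwood broad-leaves" or "Other softwood broad-leaves").
    """

    rho: dict  # normalised species -> rho
    display: dict  # normalised species -> printed name
    group_of: dict  # normalised species -> group
    defaults: dict  # group -> rho
    fallback_log: list = field(default_factory=list)

    @classmethod
    def from_csv(cls, path=None, overrides: dict | None = None) -> "WoodDensityTable":
        """Load from CSV (``species,rho_g_cm3,group``); default: bundled table.

        ``overrides`` maps species name to a replacement rho, e.g. to correct
        a suspect printed value without editing the shipped table.
        """
        if path is None:
            with resources.files("agbstack.data").joinpath("wood_density.csv").open() as fh:
                df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
        for col in ("species", "rho_g_cm3"):
            if col not in df.columns:
                raise FormatError(f"wood-density table missing column {col!r}")
        rho, display, group_of = {}, {}, {}
        for _, row in df.iterrows():
            key = _normalize_species(row["species"])
            rho[key] = float(row["rho_g_cm3"])
            display[key] = str(row["species"])
            group_of[key] = str(row.get("group", "hardwood"))
        if overrides:
            for name, value in overrides.items():
                rho[_normalize_species(name)] = float(value)
        defaults = {}
        for group, species_key in _GROUP_DEFAULT_KEYS.items():
            key = _normalize_species(species_key)
            if key in rho:
                defaults[group] = rho[key]
        bad = [k for k, v in rho.items() if not v > 0]
        if bad:
            raise FormatError(f"non-positive wood density for: {bad}")
        return cls(rho=rho, display=display, group_of=group_of, defaults=defaults)

    def lookup(self, species: str, group: str | None = None) -> float:
        """Return rho for ``species``; exact match wins, else group fallback.

        ``group`` (``pine``/``hardwood``/``softwood``) selects the fallback
        used for unknown species; each applied fallback is logged on
        :attr:`fallback_log`.
        """
        if not str(species).strip():
            raise DensityLookupError("empty species name")
        key = _normalize_species(species)
        if key in self.rho:
            return self.rho[key]
        if group is not None and group in self.defaults:
            self.fallback_log.append((str(species), group))
            return self.defaults[group]
        raise DensityLookupError(
            f"no density for species {species!r} and no fallback group configured"
        )

    def attach(self, records: pd.DataFrame, default_group: str | None = "hardwood") -> pd.DataFrame:
        """Return a copy of ``records`` with a ``rho_g_cm3`` column."""
        out = records.copy()
        out["rho_g_cm3"] = [
            self.lookup(sp, group=default_group) for sp in out["species"]
        ]
        return out


# ---------------------------------------------------------------------------
# plot geometries
# ---------------------------------------------------------------------------

@dataclass
class PlotGeometry:
    """A square plot footprint in the raster CRS."""

    plot_id: str
    footprint: Polygon

    @property
    def area_ha(self) -> float:
        return self.footprint.area / 10_000.0

    def check_area(self, nominal_ha: float = DEFAULT_PLOT_AREA_HA, tol: float = 0.01) -> bool:
        return math.isclose(self.area_ha, nominal_ha, rel_tol=tol)


def write_footprints(footprints: list[PlotGeometry], path, crs: str = "EPSG:32648") -> None:
    """Write plot footprints as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": [
            {
                "type": "Feature",
                "properties": {"plot_id": g.plot_id, "area_ha": g.area_ha},
                "geometry": mapping(g.footprint),
            }
            for g in footprints
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_footprints(path) -> list[PlotGeometry]:
    """Read plot footprints from GeoJSON."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise FormatError(f"{path} is not a GeoJSON FeatureCollection")
    out = []
    for feat in fc["features"]:
        out.append(
            PlotGeometry(
                plot_id=str(feat["properties"]["plot_id"]),
                footprint=shape(feat["geometry"]),
            )
        )
    return out
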