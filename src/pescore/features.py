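"""Species x predictor feature extraction.

Turns rasters + range polygons + occurrence points into the modelling
table: per-species zonal summaries (min/max/mean/median of every stressor
layer over range cells and over occurrence cells), point-count predictors
(dams, power plants), range extent, occurrence counts, taxonomy, domain
indicators and habitat counts.

Cell-assignment conventions (used everywhere, stated once):

* a grid cell belongs to a species' range iff its rectangle intersects any
  native+extant seasonal polygon with positive area; seasonal polygons are
  unioned; if no cell qualifies, the cell containing the centroid of the
  largest polygon is used, so a range is never empty;
* an occurrence point maps to its half-open cell
  ``(floor((lon+180)/res), floor((90-lat)/res))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import GridSpec
from .layers import StressorLayer

logger = logging.getLogger(__name__)

ZONAL_STATS = ("min", "max", "mean", "median")
SUPPORTS = ("range", "occ")

TAXONOMY_COLUMNS = ("kingdom", "phylum", "class", "family")
DOMAIN_COLUMNS = ("domain_terrestrial", "domain_freshwater", "domain_marine")


@dataclass
class ZonalSummary:
    """min/max/mean/median of one layer over one cell set (NaN if undefined)."""

    layer_name: str
    over: str  # "range_cells" | "occurrence_cells"
    min: float
    max: float
    mean: float
    median: float


def rasterize_range(polygons, grid: GridSpec) -> np.ndarray:
    """Cells covered by the union of a species' native+extant seasonal polygons.

    Returns sorted flat cell indices.  A cell is included iff its rectangle
    has a positive-area intersection with any polygon; a range too small to
    cover any cell falls back to the cell containing the centroid of its
    largest polygon.
    """
    usable = [
        p for p in polygons if p.origin == "native" and p.presence == "extant"
    ]
    if not usable:
        raise ValueError("species has no native+extant range polygon")
    res = grid.resolution
    cells: set[int] = set()
    for rp in usable:
        geom = rp.geometry
        if geom.is_empty or geom.area <= 0:
            continue
        x0, y0, x1, y1 = geom.bounds
        c0 = max(int(np.floor((x0 - grid.lon_min) / res)), 0)
        c1 = min(int(np.floor((x1 - grid.lon_min) / res)), grid.n_cols - 1)
        r0 = max(int(np.floor((grid.lat_max - y1) / res)), 0)
        r1 = min(int(np.floor((grid.lat_max - y0) / res)), grid.n_rows - 1)
        cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        cc, rr = cc.ravel(), rr.ravel()
        bx0 = grid.lon_min + cc * res
        by1 = grid.lat_max - rr * res
        boxes = shapely.box(bx0, by1 - res, bx0 + res, by1)
        shapely.prepare(geom)
        hit = shapely.intersects(geom, boxes)
        if not np.any(hit):
            continue
        # positive-area overlap <=> interiors intersect <=> intersects but
        # not merely touching along the boundary
        touch = shapely.touches(geom, boxes[hit])
        keep = np.flatnonzero(hit)[~touch]
        cells.update((rr[keep] * grid.n_cols + cc[keep]).tolist())
    if not cells:
        largest = max(usable, key=lambda p: p.geometry.area)
        pt = largest.geometry.centroid
        cells = {grid.cell_of(pt.x, pt.y)}
    return np.array(sorted(cells), dtype=np.int64)


def occurrence_cells(points: np.ndarray, grid: GridSpec) -> tuple[int, np.ndarray]:
    """(n_points, sorted unique cell indices) for an occurrence point set."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return 0, np.array([], dtype=np.int64)
    cells = grid.cell_of(points[:, 0], points[:, 1])
    return len(points), np.unique(cells)


def zonal_stats(layer: StressorLayer, cells: np.ndarray, over: str = "range_cells") -> ZonalSummary:
    """min/max/mean/median of a layer over a non-empty cell set.

    Missing cell values are ignored; if every value is missing all four
    statistics are NaN.  The even-count median is the mean of the two middle
    values.
    """
    cells = np.asarray(cells, dtype=np.int64)
    if cells.size == 0:
        raise ValueError("zonal_stats requires a non-empty cell set")
    vals = layer.values.ravel()[cells]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return ZonalSummary(layer.name, over, np.nan, np.nan, np.nan, np.nan)
    return ZonalSummary(
        layer.name,
        over,
        float(vals.min()),
        float(vals.max()),
        float(vals.mean()),
        float(np.median(vals)),
    )


def count_points_in_range(point_layer: StressorLayer, cells: np.ndarray) -> int:
    """Total count of a count-like layer (dams, power plants) over range cells."""
    if point_layer.kind != "count-like":
        raise ValueError(f"layer {point_layer.name!r} is not count-like")
    vals = point_layer.values.ravel()[np.asarray(cells, dtype=np.int64)]
    vals = vals[np.isfinite(vals)]
    if np.any(vals < 0):
        raise ValueError("negative counts in count-like layer")
    return int(vals.sum())


def compute_range_cells(species, grid: GridSpec) -> dict[str, np.ndarray]:
    """Range cell sets for a list of SpeciesRecord (shared convention)."""
    return {rec.species_id: rasterize_range(rec.ranges, grid) for rec in species}


def assemble_feature_table(
    species,
    occurrences,
    layers: list[StressorLayer],
    grid: GridSpec,
    range_cells: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Build the species x predictor table.

    One row per species, sorted by species_id (so the result is invariant to
    input order).  Occurrence-derived columns are missing — not zero — when
    a species has no occurrence points; ``n_occurrence_points`` itself is 0.
    Count-like layers become point-count predictors; all other layers
    contribute 4 statistics x 2 supports zonal columns.
    """
    occ_by_id = {o.species_id: o for o in occurrences}
    unknown = set(occ_by_id) - {rec.species_id for rec in species}
    if unknown:
        raise ValueError(f"occurrence sets for unknown species: {sorted(unknown)[:5]}")
    if range_cells is None:
        range_cells = compute_range_cells(species, grid)
    value_layers = [l for l in layers if l.kind != "count-like"]
    count_layers = [l for l in layers if l.kind == "count-like"]

    rows = []
    for rec in sorted(species, key=lambda r: r.species_id):
        cells = range_cells[rec.species_id]
        row: dict[str, object] = {
            "species_id": rec.species_id,
            "kingdom": rec.kingdom,
            "phylum": rec.phylum,
            "class": rec.class_name,
            "family": rec.family,
            "category": rec.category,
            "outdated_assessment": rec.outdated_assessment,
            "domain_terrestrial": int("terrestrial" in rec.domains),
            "domain_freshwater": int("freshwater" in rec.domains),
            "domain_marine": int("marine" in rec.domains),
            "is_marine": rec.is_marine,
            "n_habitats": rec.habitat_counts[0],
            "n_sub_habitats": rec.habitat_counts[1],
            "n_major_habitats": rec.habitat_counts[2],
            "n_native_countries": rec.n_native_countries,
            "range_extent_cells": len(cells),
            "range_extent_km2": float(grid.cell_area_km2(cells).sum()),
        }
        occ = occ_by_id.get(rec.species_id)
        if occ is not None and len(occ.points):
            n_pts, ocells = occurrence_cells(occ.points, grid)
            row["n_occurrence_points"] = n_pts
            row["n_occurrence_cells"] = len(ocells)
        else:
            n_pts, ocells = 0, None
            row["n_occurrence_points"] = 0
            row["n_occurrence_cells"] = np.nan
        for layer in count_layers:
            row[f"n_{layer.name}_in_range"] = count_points_in_range(layer, cells)
        for layer in value_layers:
            zs = zonal_stats(layer, cells, "range_cells")
            for stat in ZONAL_STATS:
                row[f"{layer.name}_{stat}_range"] = getattr(zs, stat)
            if ocells is not None and len(ocells):
                zo = zonal_stats(layer, ocells, "occurrence_cells")
                for stat in ZONAL_STATS:
                    row[f"{layer.name}_{stat}_occ"] = getattr(zo, stat)
            else:
                for stat in ZONAL_STATS:
                    row[f"{layer.name}_{stat}_occ"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["species_id"].duplicated().any():
        raise ValueError("duplicated species_id in feature table")
    return table.set_index("species_id", drop=False)


def column_manifest(table: pd.DataFrame, layers: list[StressorLayer]) -> pd.DataFrame:
    """Sidecar manifest: (name, source_layer, statistic, support) per column."""
    layer_names = {l.name for l in layers}
    recs = []
    for col in table.columns:
        source, stat, support = "", "", ""
        parts = col.rsplit("_", 2)
        if len(parts) == 3 and parts[0] in layer_names and parts[1] in ZONAL_STATS:
            source, stat = parts[0], parts[1]
            support = "range_cells" if parts[2] == "range" else "occurrence_cells"
        elif col.startswith("n_") and col.endswith("_in_range"):
            source, stat, support = col[2:-9], "count", "range_cells"
        recs.append({"name": col, "source_layer": source, "statistic": stat, "support": support})
    return pd.DataFrame(recs)


class RandomValueImputer:
    """Hot-deck imputation: missing entries drawn from the column's observed
    values in the *training* rows, seeded.  Mirrors random-value NA
    imputation; observed entries are never touched.
    """

    def __init__(self, seed: int):
        self.seed = seed
        self.pools_: dict[str, np.ndarray] = {}
        self.dropped_: list[str] = []

    def fit(self, table: pd.DataFrame, fit_index=None) -> "RandomValueImputer":
        rows = table if fit_index is None else table.loc[fit_index]
        self.pools_.clear()
        self.dropped_ = []
        for col in table.columns:
            if not pd.api.types.is_numeric_dtype(table[col]) or pd.api.types.is_bool_dtype(table[col]):
                continue
            observed = rows[col].dropna().to_numpy()
            if observed.size == 0:
                self.dropped_.append(col)
                logger.warning("column %r has no observed training values; dropped", col)
            else:
                self.pools_[col] = observed
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.drop(columns=self.dropped_, errors="ignore").copy()
        # one independent substream per column: fill order never matters
        for i, col in enumerate(sorted(self.pools_)):
            if col not in out.columns:
                continue
            mask = out[col].isna()
            if mask.any():
                rng = np.random.default_rng(np.random.SeedSequence([self.seed, i]))
                out.loc[mask, col] = rng.choice(self.pools_[col], size=int(mask.sum()))
        return out


def impute_missing(table: pd.DataFrame, seed: int, fit_index=None) -> pd.DataFrame:
    """Impute missing numeric entries with seeded draws from observed values.

    Pools come from ``fit_index`` rows (default: all rows), so test / DD rows
    are filled from training-observed values only.
    """
    return RandomValueImputer(seed).fit(table, fit_index).transform(table)


class FeatureEncoder:
    """Deterministic numeric design matrix from the feature table.

    Taxonomy categoricals become one-hot blocks (category sets frozen at
    fit time; unseen levels encode to all-zeros), numeric columns pass
    through.  ``blocks`` maps encoded column -> source column, which is how
    one-hot blocks are grouped during feature selection.
    """

    _NON_FEATURE = ("species_id", "category", "outdated_assessment", "is_marine", "label")

    def __init__(self):
        self.categories_: dict[str, list[str]] = {}
        self.numeric_: list[str] = []
        self.columns_: list[str] = []
        self.blocks: dict[str, str] = {}

    def fit(self, table: pd.DataFrame) -> "FeatureEncoder":
        self.categories_.clear()
        self.blocks = {}
        cols = [c for c in table.columns if c not in self._NON_FEATURE]
        self.numeric_ = [c for c in cols if pd.api.types.is_numeric_dtype(table[c])]
        out_cols: list[str] = []
        for col in cols:
            if col in self.numeric_:
                out_cols.append(col)
                self.blocks[col] = col
            else:
                levels = sorted(table[col].astype(str).unique())
                self.categories_[col] = levels
                for lv in levels:
                    name = f"{col}={lv}"
                    out_cols.append(name)
                    self.blocks[name] = col
        self.columns_ = out_cols
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        data = {}
        for col in self.columns_:
            if "=" in col and col not in table.columns:
                src, lv = col.split("=", 1)
                data[col] = (table[src].astype(str) == lv).astype(float)
            else:
                data[col] = pd.to_numeric(table[col]).astype(float)
        return pd.DataFrame(data, index=table.index)
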