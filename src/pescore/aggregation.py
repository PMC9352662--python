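"""Spatial conservation-priority aggregation of PE scores.

Two per-cell summaries over the global grid:

* the fraction of data-deficient (DD) species present in a cell that are
  predicted threatened (conservation hotspot map for unassessed species);
* the percent change in mean PE score when DD species are pooled with
  data-sufficient (DS) species — where this is positive, ignoring DD
  species understates local conservation priority.

Presence means range-cell membership under the same rasterisation
convention used for feature extraction.  Cells with no relevant species
are masked (raster nodata), never zero.  DS species contribute their
model-predicted PE score to the mean-PE maps (switchable to a 0/1 encoding
of their Red List label via ``ds_scores``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec


@dataclass
class GridSummary:
    """Per-cell species counts, mean PE scores and the percent-change field."""

    grid: GridSpec
    n_ds: np.ndarray
    n_dd: np.ndarray
    mean_pe_ds: np.ma.MaskedArray
    mean_pe_all: np.ma.MaskedArray
    pct_change: np.ma.MaskedArray


def _accumulate(
    values: pd.Series, range_cells: dict[str, np.ndarray], grid: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(per-cell sum of values, per-cell species count) over flat cell arrays."""
    total = np.zeros(grid.n_cells)
    count = np.zeros(grid.n_cells)
    for sid, val in values.items():
        cells = range_cells[sid]
        total[cells] += val
        count[cells] += 1
    return total, count


def fraction_dd_threatened(
    predictions: pd.DataFrame,
    range_cells: dict[str, np.ndarray],
    grid: GridSpec,
) -> np.ma.MaskedArray:
    """Per-cell fraction of present DD species predicted threatened.

    ``predictions`` needs columns species_id and predicted_label and must
    cover exactly the DD species; cells where no DD species occurs are
    masked.
    """
    missing = set(predictions["species_id"]) - set(range_cells)
    if missing:
        raise ValueError(f"no range cells for predicted species: {sorted(missing)[:5]}")
    flags = pd.Series(
        (predictions["predicted_label"] == "threatened").astype(float).to_numpy(),
        index=predictions["species_id"],
    )
    hits, count = _accumulate(flags, range_cells, grid)
    with np.errstate(invalid="ignore"):
        frac = hits / count
    out = np.ma.MaskedArray(frac, mask=count == 0)
    return out.reshape(grid.shape)


def percent_change_map(
    predictions_ds: pd.Series,
    predictions_dd: pd.Series,
    range_cells: dict[str, np.ndarray],
    grid: GridSpec,
) -> GridSummary:
    """Percent change in per-cell mean PE score when DD species are included.

    ``predictions_ds`` / ``predictions_dd`` map species_id -> PE score.
    pct_change = 100 * (mean_all - mean_ds) / mean_ds, masked wherever no DS
    species is present (or the DS mean is zero).
    """
    sum_ds, n_ds = _accumulate(predictions_ds, range_cells, grid)
    sum_dd, n_dd = _accumulate(predictions_dd, range_cells, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ds = sum_ds / n_ds
        mean_all = (sum_ds + sum_dd) / (n_ds + n_dd)
        pct = 100.0 * (mean_all - mean_ds) / mean_ds
    mask_ds = n_ds == 0
    mask_all = (n_ds + n_dd) == 0
    shape = grid.shape
    return GridSummary(
        grid=grid,
        n_ds=n_ds.reshape(shape),
        n_dd=n_dd.reshape(shape),
        mean_pe_ds=np.ma.MaskedArray(mean_ds, mask=mask_ds).reshape(shape),
        mean_pe_all=np.ma.MaskedArray(mean_all, mask=mask_all).reshape(shape),
        pct_change=np.ma.MaskedArray(pct, mask=mask_ds | (mean_ds == 0)).reshape(shape),
    )


def per_class_summary(
    predictions_dd: pd.DataFrame,
    species_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per taxonomic class: DD counts, predicted-threatened fraction, and the
    combined threatened fraction before/after including DD species.

    "Before" is the fraction of DS species whose Red List category is
    threatened; "after" pools DS threatened status with DD predictions.
    Classes without DD species are omitted.
    """
    from .partition import binarize_category

    sp = species_table.set_index("species_id")
    dd = predictions_dd.set_index("species_id")
    dd_class = sp.loc[dd.index, "class"]
    ds = sp[sp["category"].map(binarize_category).isin(["threatened", "not_threatened"])]
    ds_threat = ds["category"].map(binarize_category) == "threatened"
    rows = []
    for cls, members in dd.groupby(dd_class.to_numpy()):
        n_dd = len(members)
        n_thr = int((members["predicted_label"] == "threatened").sum())
        ds_cls = ds[ds["class"] == cls]
        n_ds = len(ds_cls)
        n_ds_thr = int(ds_threat.loc[ds_cls.index].sum())
        rows.append(
            {
                "class": cls,
                "n_dd": n_dd,
                "n_dd_predicted_threatened": n_thr,
                "frac_dd_threatened": n_thr / n_dd,
                "n_ds": n_ds,
                "frac_threatened_ds_only": n_ds_thr / n_ds if n_ds else np.nan,
                "frac_threatened_with_dd": (n_ds_thr + n_thr) / (n_ds + n_dd),
            }
        )
    return pd.DataFrame(rows).sort_values("class").reset_index(drop=True)
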