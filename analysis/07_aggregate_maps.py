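"""Spatial conservation-priority aggregation: per-cell fraction of DD
species predicted threatened, and the percent change in mean PE score when
DD species are pooled with data-sufficient species."""

import numpy as np
import pandas as pd

from common import run_config
from pescore.geoio import read_geotiff
from pescore.pipeline import stage_aggregate

config = run_config()
stage_aggregate(config)
adir = config.out / "aggregation"
frac, _ = read_geotiff(adir / "fraction_dd_threatened.tif")
pct, _ = read_geotiff(adir / "pct_change.tif")
print(f"maps -> {adir} (GeoTIFF, masked cells = nodata)")
print(f"  cells with DD species: {np.isfinite(frac).sum()}; "
      f"mean fraction predicted threatened there: {np.nanmean(frac):.3f}")
print(f"  cells with a defined percent change: {np.isfinite(pct).sum()}; "
      f"median {np.nanmedian(pct):+.1f}%, "
      f">+10% in {np.mean(pct[np.isfinite(pct)] > 10) * 100:.0f}% of them")
summary = pd.read_csv(adir / "per_class_summary.csv")
print("per-class DD summary:")
print(summary.to_string(index=False))
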