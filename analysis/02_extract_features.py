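"""Extract the species x predictor table: zonal min/max/mean/median of every
stressor layer over range cells and occurrence cells, point-count
predictors (dams, power plants), range extent, occurrence counts, taxonomy,
domains and habitat counts."""

import pandas as pd

from common import run_config
from pescore.pipeline import stage_extract

config = run_config()
path = stage_extract(config)
table = pd.read_csv(path)
numeric = table.select_dtypes("number")
print(f"feature table: {table.shape[0]} species x {table.shape[1]} columns -> {path}")
print(f"  missing entries: {100 * numeric.isna().to_numpy().mean():.1f}% of numeric cells "
      "(species without occurrences, layer gaps)")
stats = ("_min_", "_max_", "_mean_", "_median_")
n_zonal = sum(any(s in c for s in stats) and c.endswith(("_range", "_occ")) for c in table.columns)
print(f"  zonal columns: {n_zonal}, column manifest: {config.out / 'column_manifest.csv'}")
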