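"""Reclassify categories to the binary label, apply the EX/EW and
outdated-assessment exclusions, hold DD species out, and split the rest
75/25 stratified on (family, marine-flag, label)."""

import pandas as pd

from common import run_config
from pescore.pipeline import stage_split

config = run_config()
path = stage_split(config)
split = pd.read_csv(path, keep_default_na=False)
counts = split.role.value_counts()
labelled = counts.get("train", 0) + counts.get("test", 0)
print(f"split -> {path}")
print(f"  roles: {counts.to_dict()}")
print(f"  train fraction of labelled species: {counts.get('train', 0) / labelled:.3f}")
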