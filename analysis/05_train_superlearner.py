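"""Train the stacked super-learner(s): 4 base learners with 10-fold CV and
in-fold minority oversampling, combined by a non-negative LASSO logistic
meta-model. Trains partition 1 (all species) and partition 2 (separate
marine / non-marine models), then writes PE scores for test + DD species."""

import json

import pandas as pd

from common import run_config
from pescore.pipeline import stage_train

config = run_config()
path = stage_train(config)
meta = json.load(open(config.out / "models" / "manifest.json"))
for tag, m in meta.items():
    coef = {k: round(v, 3) for k, v in m["meta_coefficients"].items()}
    print(f"model[{tag}]: n_train={m['n_train']}, features={m['n_confirmed_features']}, "
          f"meta coefficients {coef}, threshold {m['threshold']:.3f}")
preds = pd.read_csv(path)
print(f"predictions -> {path} ({len(preds)} rows, partitions: "
      f"{sorted(preds.partition_tag.unique())})")
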