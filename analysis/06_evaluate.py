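"""Evaluate on the set-aside test species: confusion-matrix metrics,
AUC / AUC_PR / Gini, and permutation variable importance (50 repetitions of
the AUC loss per permuted feature)."""

import json

import pandas as pd

from common import run_config
from pescore.pipeline import stage_evaluate

config = run_config()
path = stage_evaluate(config)
report = json.load(open(path))
if "selected_partition" in report:
    chosen = report.pop("selected_partition")["partition"]
    scheme = "all species together" if chosen == "all" else "separate marine / non-marine"
    print(f"partition selected by class-averaged AUC: {chosen} ({scheme})")
for tag, r in report.items():
    m = r["metrics"]
    shown = {k: round(m[k], 2) for k in
             ("accuracy", "specificity", "sensitivity", "npv", "ppv", "balanced_accuracy")
             if m.get(k) is not None}
    rank = {k: round(m[k], 2) for k in ("auc", "auc_pr", "gini") if m.get(k) is not None}
    print(f"[{tag}] confusion {r['confusion']}")
    print(f"   {shown}")
    print(f"   ranking: {rank}")
imp = pd.read_csv(config.out / "importance.csv")
print("top permutation importances (mean AUC loss):")
print(imp.head(5).to_string(index=False))
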