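"""Generate the synthetic world: grid, stressor layers, species, truth.

The world is the study's stand-in for the real inputs (range maps,
occurrence records, stressor rasters): 2000 species with log-uniform range
sizes, 3 causal + 20 noise stressor layers, and Red List categories drawn
from a known logistic threat model, with 20% of species relabelled Data
Deficient (biased toward small ranges).
"""

import json

from common import run_config
from pescore.pipeline import stage_simulate

config = run_config()
stage_simulate(config)
manifest = json.load(open(config.out / "world" / "manifest.json"))
print(f"world written to {config.out / 'world'}")
print(f"  species: {manifest['n_species']}, layers: {len(manifest['layer_names'])}, "
      f"range polygons: {manifest['n_range_features']}, "
      f"species with occurrences: {manifest['n_occurrence_sets']}")
print(f"  true model: intercept {manifest['config']['intercept']}, "
      f"coefficients {manifest['config']['coefficients']}")
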