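"""Shared plumbing for the numbered analysis scripts: one run directory,
one seed, configurable from the command line."""

from __future__ import annotations

import argparse
from pathlib import Path

from pescore.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run_config(argv=None, **defaults) -> RunConfig:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=defaults.get("seed", 1))
    parser.add_argument("--outdir", default=str(RESULTS / "run"))
    parser.add_argument("--n-species", type=int, default=defaults.get("n_species", 2000))
    args = parser.parse_args(argv)
    return RunConfig(seed=args.seed, outdir=args.outdir, n_species=args.n_species)
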