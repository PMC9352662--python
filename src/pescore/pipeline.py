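"""Staged, reproducible orchestration of the full analysis.

Stages (each reads the previous stage's artifacts from the run directory
and writes its own, plus a manifest with input hashes, seed and wall time):

    simulate -> extract -> split -> select -> train -> evaluate -> aggregate

A run is a pure function of (RunConfig, code version): rerunning with the
same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, evaluation, geoio
from .features import assemble_feature_table, column_manifest, compute_range_cells
from .partition import binarize_category, make_split_assignment
from .selection import boruta_select

from .study import default_feature_subset
from .world import generate_world, read_world, write_world

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "split", "select", "train", "evaluate", "aggregate")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is absent (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Declarative description of one full run."""

    seed: int = 0
    outdir: str = "runs/default"
    n_species: int = 2000
    n_causal: int = 3
    n_noise: int = 20
    dd_fraction: float = 0.20
    folds: int = 10
    boruta_runs: int = 50
    boruta_alpha: float = 0.01
    perm_reps: int = 50
    feature_set: str = "compact"  # compact | full
    partitions: str = "both"  # both | all
    min_subset_rows: int = 50

    def __post_init__(self):
        if self.n_species < 10:
            raise ConfigError("n_species must be >= 10")
        if not 0 <= self.dd_fraction < 1:
            raise ConfigError("dd_fraction must be in [0, 1)")
        if self.feature_set not in ("compact", "full"):
            raise ConfigError(f"unknown feature_set {self.feature_set!r}")
        if self.partitions not in ("both", "all"):
            raise ConfigError(f"unknown partitions {self.partitions!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed config {path}: {exc}") from exc
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, 1000 + idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _write_manifest(config: RunConfig, stage: str, inputs: list[Path], outputs: list[Path], t0: float) -> None:
    mdir = config.out / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    entry = {
        "stage": stage,
        "seed": config.seed,
        "stage_seed": config.stage_seed(stage),
        "wall_time_s": round(time.time() - t0, 3),
        "inputs": {str(p): _sha256(p) for p in inputs if p.is_file()},
        "outputs": {str(p): _sha256(p) for p in outputs if p.is_file()},
    }
    (mdir / f"{stage}.json").write_text(json.dumps(entry, indent=2, sort_keys=True))


def _csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


# --------------------------------------------------------------------------- stages


def stage_simulate(config: RunConfig) -> list[Path]:
    t0 = time.time()
    world = generate_world(
        config.stage_seed("simulate"),
        n_species=config.n_species,
        n_causal=config.n_causal,
        n_noise=config.n_noise,
        dd_fraction=config.dd_fraction,
    )
    world_dir = config.out / "world"
    world_dir.mkdir(parents=True, exist_ok=True)
    write_world(world, world_dir)
    config.to_yaml(config.out / "config.yaml")
    outputs = sorted(world_dir.rglob("*"))
    _write_manifest(config, "simulate", [], outputs + [config.out / "config.yaml"], t0)
    return outputs


def _load_world(config: RunConfig):
    _require(config.out / "world" / "manifest.json", "simulate")
    return read_world(config.out / "world")


def stage_extract(config: RunConfig) -> Path:
    t0 = time.time()
    world = _load_world(config)
    cells = compute_range_cells(world.species, world.grid)
    table = assemble_feature_table(world.species, world.occurrences, world.layers, world.grid, cells)
    out = _csv(table, config.out / "features.csv")
    man = _csv(column_manifest(table, world.layers), config.out / "column_manifest.csv")
    _write_manifest(config, "extract", [config.out / "world" / "manifest.json"], [out, man], t0)
    return out


def _load_features(config: RunConfig) -> pd.DataFrame:
    path = _require(config.out / "features.csv", "extract")
    table = pd.read_csv(path).set_index("species_id", drop=False)
    table["label"] = table["category"].map(binarize_category)
    return table


def stage_split(config: RunConfig) -> Path:
    t0 = time.time()
    table = _load_features(config)
    split = make_split_assignment(table, config.stage_seed("split"))
    out = _csv(split, config.out / "split.csv")
    _write_manifest(config, "split", [config.out / "features.csv"], [out], t0)
    return out


def _load_split(config: RunConfig) -> pd.DataFrame:
    return pd.read_csv(_require(config.out / "split.csv", "split"), keep_default_na=False)


def _candidate_columns(config: RunConfig, table: pd.DataFrame) -> list[str] | None:
    return default_feature_subset(table) if config.feature_set == "compact" else None


def stage_select(config: RunConfig) -> Path:
    """Feature selection for the all-species partition (recorded as CSV).

    Per-partition selection for the marine / non-marine models runs inside
    the train stage on each model's own training data.
    """
    t0 = time.time()
    table = _load_features(config)
    split = _load_split(config)
    from .features import FeatureEncoder, RandomValueImputer

    roles = split.set_index("species_id")["role"]
    train_ids = roles[roles == "train"].index
    seed = config.stage_seed("select")
    train = table.loc[train_ids]
    imputer = RandomValueImputer(seed).fit(table.drop(columns=["label"]), train_ids)
    encoder = FeatureEncoder().fit(imputer.transform(train))
    X = encoder.transform(imputer.transform(train))
    subset = _candidate_columns(config, table)
    if subset is not None:
        X = X[[c for c in encoder.columns_ if encoder.blocks[c] in set(subset)]]
    result = boruta_select(
        X, train["label"].to_numpy(), R=config.boruta_runs,
        alpha=config.boruta_alpha, seed=seed, blocks=encoder.blocks,
    )
    out = config.out / "selection_all.csv"
    result.to_csv(out)
    (config.out / "confirmed_all.json").write_text(json.dumps(result.confirmed))
    _write_manifest(
        config, "select",
        [config.out / "features.csv", config.out / "split.csv"],
        [out, config.out / "confirmed_all.json"], t0,
    )
    return out


def stage_train(config: RunConfig) -> Path:
    t0 = time.time()
    table = _load_features(config)
    split = _load_split(config)
    confirmed_path = _require(config.out / "confirmed_all.json", "select")
    confirmed_all = json.loads(confirmed_path.read_text())
    seed = config.stage_seed("train")
    kwargs = dict(
        folds=config.folds,
        boruta_runs=config.boruta_runs,
        boruta_alpha=config.boruta_alpha,
        feature_subset=_candidate_columns(config, table),
    )
    roles = split.set_index("species_id")["role"]
    train_ids = roles[roles == "train"].index
    from .stacking import train_model

    models = {
        "all": train_model(
            table, train_ids, seed, partition_tag="all", confirmed=confirmed_all,
            folds=config.folds,
        )
    }
    if config.partitions == "both":
        marine = table.loc[train_ids, "is_marine"].astype(bool)
        for tag, ids in (("marine", train_ids[marine]), ("non_marine", train_ids[~marine])):
            if len(ids) < config.min_subset_rows:
                logger.warning("%s subset too small (%d rows); skipped", tag, len(ids))
                continue
            models[tag] = train_model(table, ids, seed, partition_tag=tag, **kwargs)

    mdir = config.out / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    meta = {}
    for tag, model in models.items():
        with open(mdir / f"{tag}.pkl", "wb") as fh:
            pickle.dump(model, fh)
        outputs.append(mdir / f"{tag}.pkl")
        meta[tag] = {
            "roster": [s.name for s in model.roster],
            "meta_coefficients": {k: float(v) for k, v in model.meta_coef.items()},
            "intercept": model.intercept,
            "lambda": model.lambda_,
            "threshold": model.threshold,
            "n_confirmed_features": len(model.feature_columns),
            "feature_columns": model.feature_columns,
            "n_train": len(model.train_ids),
        }
    (mdir / "manifest.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    outputs.append(mdir / "manifest.json")

    # predictions for test + DD holdout species, per partition scheme
    test_ids = roles[roles == "test"].index
    dd_ids = roles[roles == "dd_holdout"].index
    score_ids = test_ids.append(dd_ids)
    frames = [models["all"].predict(table.loc[score_ids])]
    if "marine" in models or "non_marine" in models:
        marine_mask = table.loc[score_ids, "is_marine"].astype(bool)
        for tag, mask in (("marine", marine_mask), ("non_marine", ~marine_mask)):
            if tag in models and mask.any():
                frames.append(models[tag].predict(table.loc[score_ids[mask]]))
    preds = pd.concat(frames, ignore_index=True).sort_values(
        ["partition_tag", "species_id"]
    )
    outputs.append(_csv(preds, config.out / "predictions.csv"))
    _write_manifest(
        config, "train",
        [config.out / "features.csv", config.out / "split.csv", confirmed_path],
        outputs, t0,
    )
    return config.out / "predictions.csv"


def _load_models(config: RunConfig) -> dict:
    mdir = _require(config.out / "models", "train")
    models = {}
    for path in sorted(Path(mdir).glob("*.pkl")):
        with open(path, "rb") as fh:
            models[path.stem] = pickle.load(fh)
    if not models:
        raise MissingArtifactError("no trained models found; run the 'train' stage first")
    return models


def stage_evaluate(config: RunConfig) -> Path:
    t0 = time.time()
    table = _load_features(config)
    split = _load_split(config)
    models = _load_models(config)
    preds = pd.read_csv(_require(config.out / "predictions.csv", "train"))
    seed = config.stage_seed("evaluate")
    roles = split.set_index("species_id")["role"]
    test_ids = roles[roles == "test"].index

    report: dict[str, dict] = {}
    for tag in sorted(models):
        sub = preds[(preds.partition_tag == tag) & preds.species_id.isin(test_ids)]
        if sub.empty:
            continue
        y = table.loc[sub.species_id, "label"].to_numpy()
        cm = evaluation.confusion(sub.predicted_label.to_numpy(), y)
        metrics = evaluation.compute_metrics(cm)
        if len(set(y)) == 2:
            metrics.auc = evaluation.auc(sub.pe_score.to_numpy(), y)
            metrics.auc_pr = evaluation.auc_pr(sub.pe_score.to_numpy(), y)
            metrics.gini = 2 * metrics.auc - 1
        report[tag] = {
            "confusion": dataclasses.asdict(cm),
            "metrics": metrics.rounded(ndigits=6),
        }
    if len(models) > 1:
        from .stacking import partition_cv_scores, select_partition

        cv_scores = partition_cv_scores(models, table)
        report["selected_partition"] = {
            "partition": select_partition(cv_scores, table["label"], table["class"])
        }
    imp = evaluation.permutation_importance(
        models["all"], table.loc[test_ids], table.loc[test_ids, "label"].to_numpy(),
        reps=config.perm_reps, seed=seed,
    )
    out_metrics = config.out / "metrics.json"
    out_metrics.write_text(json.dumps(report, indent=2, sort_keys=True))
    out_imp = _csv(imp, config.out / "importance.csv")
    _write_manifest(
        config, "evaluate",
        [config.out / "features.csv", config.out / "split.csv", config.out / "predictions.csv"],
        [out_metrics, out_imp], t0,
    )
    return out_metrics


def stage_aggregate(config: RunConfig) -> list[Path]:
    t0 = time.time()
    world = _load_world(config)
    table = _load_features(config)
    split = _load_split(config)
    preds = pd.read_csv(_require(config.out / "predictions.csv", "train"))
    preds = preds[preds.partition_tag == "all"]
    roles = split.set_index("species_id")["role"]
    dd_ids = roles[roles == "dd_holdout"].index
    test_ids = roles[roles == "test"].index
    cells = compute_range_cells(world.species, world.grid)

    dd_preds = preds[preds.species_id.isin(dd_ids)]
    frac = aggregation.fraction_dd_threatened(dd_preds, cells, world.grid)
    ds_scores = preds[preds.species_id.isin(test_ids)].set_index("species_id")["pe_score"]
    dd_scores = dd_preds.set_index("species_id")["pe_score"]
    summary = aggregation.percent_change_map(ds_scores, dd_scores, cells, world.grid)

    adir = config.out / "aggregation"
    adir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for name, arr in (
        ("fraction_dd_threatened", frac),
        ("mean_pe_ds", summary.mean_pe_ds),
        ("mean_pe_all", summary.mean_pe_all),
        ("pct_change", summary.pct_change),
    ):
        path = adir / f"{name}.tif"
        geoio.write_geotiff(path, arr.filled(np.nan), world.grid)
        outputs.append(path)
    per_class = aggregation.per_class_summary(dd_preds, table.reset_index(drop=True))
    outputs.append(_csv(per_class, adir / "per_class_summary.csv"))
    _write_manifest(
        config, "aggregate",
        [config.out / "predictions.csv", config.out / "world" / "manifest.json"],
        outputs, t0,
    )
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "split": stage_split,
    "select": stage_select,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "aggregate": stage_aggregate,
}


def run_stage(stage: str, config: RunConfig):
    """Run one named stage; raises MissingArtifactError if upstreams are absent."""
    if stage not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {stage!r}; stages are {', '.join(STAGES)}")
    logger.info("stage %s -> %s", stage, config.outdir)
    return _STAGE_FUNCS[stage](config)


def run_all(config: RunConfig) -> None:
    """Run every stage in order in one process."""
    for stage in STAGES:
        t0 = time.time()
        run_stage(stage, config)
        logger.info("stage %-9s done in %.1fs", stage, time.time() - t0)
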