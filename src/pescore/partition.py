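"""Binary reclassification, exclusion rules, stratified split, oversampling.

Red List categories collapse to a binary response: threatened (VU, EN, CR)
versus not threatened (LC, LR/LC, LR/CD, NT).  DD species are set aside as
the prediction target, EX/EW are excluded.  Outdated assessments are
removed unless a taxonomic class would drop below five records.  Labelled
species are split 75/25 into train/test, stratified on
(family, marine-flag, label) so the threat balance is maintained within
taxonomic families and environmental domains.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

THREATENED = frozenset({"VU", "EN", "CR"})
NOT_THREATENED = frozenset({"LC", "LR/LC", "LR/CD", "NT"})
EXCLUDED = frozenset({"EX", "EW"})

TRAIN_FRACTION = 0.75
MIN_CLASS_RECORDS = 5


def binarize_category(category: str) -> str:
    """Map a Red List category to {threatened, not_threatened, dd, excluded}."""
    if category in THREATENED:
        return "threatened"
    if category in NOT_THREATENED:
        return "not_threatened"
    if category == "DD":
        return "dd"
    if category in EXCLUDED:
        return "excluded"
    raise ValueError(f"unknown Red List category {category!r}")


def apply_outdated_rule(species: pd.DataFrame) -> pd.DataFrame:
    """Drop outdated assessments, keeping enough to leave >=5 records per class.

    Within each taxonomic class, non-outdated records are always kept; if
    fewer than five remain, outdated records are added back in lexicographic
    species_id order until the class reaches five (or none are left).
    """
    keep: list[pd.Index] = []
    for _, group in species.groupby("class", sort=True):
        fresh = group[~group["outdated_assessment"].astype(bool)]
        kept = fresh.index
        if len(fresh) < MIN_CLASS_RECORDS:
            stale = group[group["outdated_assessment"].astype(bool)]
            order = stale["species_id"].sort_values().index
            kept = kept.append(order[: MIN_CLASS_RECORDS - len(fresh)])
        keep.append(kept)
    index = keep[0].append(keep[1:]) if len(keep) > 1 else keep[0]
    return species.loc[species.index.intersection(index, sort=False)]


def stratified_split(labelled: pd.DataFrame, seed: int) -> pd.DataFrame:
    """75/25 train/test assignment of labelled species.

    Stratified on (family, marine-flag, label); train counts per stratum by
    largest-remainder rounding against the global 75% target, ties broken by
    stratum id; a seeded shuffle within each stratum decides who goes where.
    Returns a DataFrame (species_id, role, stratum_id).
    """
    if len(labelled) < 2:
        raise ValueError("need at least two labelled species to split")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    strata: list[tuple[str, list[str]]] = []
    for (family, marine, label), group in labelled.groupby(
        ["family", "is_marine", "label"], sort=True
    ):
        stratum_id = f"{family}|{'marine' if marine else 'non_marine'}|{label}"
        ids = sorted(group["species_id"])
        order = rng.permutation(len(ids))
        strata.append((stratum_id, [ids[k] for k in order]))

    n_total = len(labelled)
    target_train = int(round(TRAIN_FRACTION * n_total))
    quotas = [TRAIN_FRACTION * len(ids) for _, ids in strata]
    base = [int(np.floor(q)) for q in quotas]
    # singletons always train (logged); they get a forced base of 1
    for k, (sid, ids) in enumerate(strata):
        if len(ids) == 1 and base[k] == 0:
            base[k] = 1
            logger.info("singleton stratum %s assigned to train", sid)
    leftover = target_train - sum(base)
    remainders = sorted(
        range(len(strata)),
        key=lambda k: (-(quotas[k] - np.floor(quotas[k])), strata[k][0]),
    )
    extra = set()
    for k in remainders:
        if leftover <= 0:
            break
        if base[k] < len(strata[k][1]):
            extra.add(k)
            leftover -= 1

    rows = []
    for k, (stratum_id, ids) in enumerate(strata):
        n_train = min(base[k] + (1 if k in extra else 0), len(ids))
        for j, sid in enumerate(ids):
            rows.append(
                {
                    "species_id": sid,
                    "role": "train" if j < n_train else "test",
                    "stratum_id": stratum_id,
                }
            )
    return pd.DataFrame(rows).sort_values("species_id").reset_index(drop=True)


def make_split_assignment(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Full role assignment for a feature table: train/test/dd_holdout/excluded.

    Applies the binary reclassification, removes EX/EW, applies the
    outdated-assessment rule (removed labelled species are marked excluded),
    holds DD out, and splits the remaining labelled species 75/25.
    """
    table = table.copy()
    table["label"] = table["category"].map(binarize_category)
    roles = pd.Series("excluded", index=table.index, name="role")
    roles[table["label"] == "dd"] = "dd_holdout"
    labelled = table[table["label"].isin(["threatened", "not_threatened"])]
    retained = apply_outdated_rule(labelled)
    split = stratified_split(retained, seed).set_index("species_id")
    roles.loc[split.index] = split["role"]
    strata = pd.Series("", index=table.index)
    strata.loc[split.index] = split["stratum_id"]
    return pd.DataFrame(
        {
            "species_id": table["species_id"].to_numpy(),
            "role": roles.to_numpy(),
            "stratum_id": strata.to_numpy(),
        }
    )


def oversample_minority(rows: pd.DataFrame, seed: int, label_col: str = "label") -> pd.DataFrame:
    """Duplicate seeded draws of the minority class until classes balance.

    Every added row is an exact copy of an original minority row.  Applied
    only inside CV training folds (and the final training refit), never to
    validation folds or test data.
    """
    counts = rows[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError("oversampling needs both classes present")
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return rows
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    pool = rows[rows[label_col] == minority]
    picks = rng.integers(0, len(pool), deficit)
    return pd.concat([rows, pool.iloc[picks]], axis=0)


def oversample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index-array form of minority oversampling for (X, y) matrices."""
    y = np.asarray(y)
    values, counts = np.unique(y, return_counts=True)
    if len(values) < 2:
        raise ValueError("oversampling needs both classes present")
    minority = values[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    idx = np.arange(len(y))
    if deficit == 0:
        return idx
    pool = idx[y == minority]
    return np.concatenate([idx, rng.choice(pool, size=deficit, replace=True)])
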