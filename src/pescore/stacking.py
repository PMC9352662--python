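"""Stacked super-learner: base learners + non-negative L1 logistic meta-model.

Protocol: base learners are trained with stratified 10-fold cross
validation (the smaller class oversampled inside each fold's training part
only), producing an out-of-fold probability matrix.  A non-negative
L1-regularised logistic regression — the super-learner's meta-model — is
fitted on that matrix; its penalty is chosen by internal cross validation
with the 1-SE rule, so weak base learners get exactly zero weight.  Base
models are then refit on the full (oversampled) training set and combined
with the meta-coefficients for prediction.  The decision threshold for the
binary label is the out-of-fold max-F1 cut.

On the non-negative orthant the L1 penalty is linear, so the penalised
logistic loss is smooth there and bound-constrained L-BFGS solves it
exactly, including coefficients parked at the zero bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .evaluation import auc
from .features import FeatureEncoder, RandomValueImputer
from .partition import oversample_indices
from .selection import SelectionResult, boruta_select

logger = logging.getLogger(__name__)

POSITIVE = "threatened"


@dataclass
class BaseLearnerSpec:
    """One base learner: a named sklearn estimator factory with a small grid."""

    name: str
    kind: str  # regularized-GLM | random-forest | gradient-boosted-trees | extremely-randomized-trees
    params: dict = field(default_factory=dict)

    def build(self, seed: int):
        p = dict(self.params)
        if self.kind == "regularized-GLM":
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(max_iter=2000, **p),
            )
        if self.kind == "random-forest":
            return RandomForestClassifier(n_jobs=1, random_state=seed, **p)
        if self.kind == "gradient-boosted-trees":
            return HistGradientBoostingClassifier(random_state=seed, **p)
        if self.kind == "extremely-randomized-trees":
            return ExtraTreesClassifier(n_jobs=1, random_state=seed, **p)
        raise ValueError(f"unknown base learner kind {self.kind!r}")


def default_roster() -> list[BaseLearnerSpec]:
    """The fixed 4-family roster (GLM, RF, GBT, extra-trees)."""
    return [
        BaseLearnerSpec("glm", "regularized-GLM", {"C": 1.0}),
        BaseLearnerSpec("rf", "random-forest", {"n_estimators": 120, "min_samples_leaf": 2}),
        BaseLearnerSpec(
            "gbt",
            "gradient-boosted-trees",
            {"max_iter": 120, "learning_rate": 0.1, "early_stopping": False},
        ),
        BaseLearnerSpec("xrt", "extremely-randomized-trees", {"n_estimators": 120, "min_samples_leaf": 2}),
    ]


def _proba(model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def cv_oof(
    X: pd.DataFrame,
    y: np.ndarray,
    roster: list[BaseLearnerSpec],
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Out-of-fold probability matrix (rows x base learners) + fold assignment.

    Stratified folds; the minority class is oversampled within each fold's
    training part before fitting, never in the validation part.  Every OOF
    entry comes from a model that never saw that row.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y_bin = np.asarray(y) == POSITIVE if np.asarray(y).dtype.kind in "OUS" else np.asarray(y)
    y_bin = y_bin.astype(int)
    if len(np.unique(y_bin)) < 2:
        raise ValueError("cv_oof needs both classes present")
    ss = np.random.SeedSequence([seed, 31])
    fold_seed, os_seed, fit_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    Xv = X.to_numpy(dtype=float)
    fold_assignment = pd.Series(-1, index=X.index, dtype=int)
    oof = pd.DataFrame(np.nan, index=X.index, columns=[s.name for s in roster])
    for attempt, skf_seed in enumerate((fold_seed, fold_seed + 1)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=skf_seed)
        splits = list(skf.split(Xv, y_bin))
        ok = all(len(np.unique(y_bin[tr])) == 2 for tr, _ in splits)
        if ok:
            break
        if attempt == 1:
            raise ValueError("a fold ended up single-class even after reshuffling")
        logger.warning("single-class fold; reshuffling once with derived seed")

    os_rng = np.random.default_rng(os_seed)
    for k, (tr, va) in enumerate(splits):
        fold_assignment.iloc[va] = k + 1
        res = oversample_indices(y_bin[tr], os_rng)
        Xtr, ytr = Xv[tr][res], y_bin[tr][res]
        for spec in roster:
            model = spec.build(fit_seed).fit(Xtr, ytr)
            oof.iloc[va, oof.columns.get_loc(spec.name)] = _proba(model, Xv[va])
    return oof, fold_assignment


# ---------------------------------------------------------------------------
# non-negative L1-regularised logistic meta-learner


def _nnlasso_logistic(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Minimise mean log-loss + lam * sum(beta) s.t. beta >= 0 (free intercept)."""
    n, p = Z.shape

    def objective(w):
        b0, b = w[0], w[1:]
        eta = b0 + Z @ b
        # stable log(1+exp(-s*eta)) with s = +-1
        s = 2 * y - 1
        loss = np.mean(np.logaddexp(0.0, -s * eta))
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = (mu - y) / n
        grad = np.concatenate([[r.sum()], Z.T @ r + lam])
        return loss + lam * b.sum(), grad

    w0 = np.zeros(p + 1)
    bounds = [(None, None)] + [(0.0, None)] * p
    res = minimize(objective, w0, jac=True, method="L-BFGS-B", bounds=bounds)
    return res.x[1:], float(res.x[0])


def fit_meta(
    oof: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_lambda: int = 25,
    cv: int = 5,
) -> tuple[pd.Series, float, float]:
    """Fit the non-negative LASSO meta-model on the OOF matrix.

    Returns (coefficients >= 0 per base learner, intercept, lambda).  The
    penalty path runs from the smallest lambda that zeroes every
    coefficient down three decades; lambda is chosen by ``cv``-fold CV
    log-loss with the 1-SE rule (most-regularised model within one standard
    error of the best), which is what produces sparse ensembles.
    """
    if oof.isna().any().any():
        raise ValueError("OOF matrix must be complete")
    Z = oof.to_numpy(dtype=float)
    y_bin = (np.asarray(y) == POSITIVE).astype(int) if np.asarray(y).dtype.kind in "OUS" else np.asarray(y).astype(int)
    if Z.std(axis=0).max() == 0:
        logger.warning("all OOF columns constant; the lambda path is degenerate")
    # lambda_max: KKT bound at beta=0 (intercept at base rate); with the
    # non-negativity constraint only descent directions (negative gradients)
    # can activate a coefficient, so the bound is max_j of -grad_j
    ybar = y_bin.mean()
    grad0 = Z.T @ (ybar - y_bin) / len(y_bin)
    lam_max = max(float(np.max(-grad0)), 1e-6)
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)

    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=int(np.random.SeedSequence([seed, 41]).generate_state(1)[0] % (2**31)))
    losses = np.zeros((cv, n_lambda))
    for k, (tr, va) in enumerate(skf.split(Z, y_bin)):
        for i, lam in enumerate(lambdas):
            b, b0 = _nnlasso_logistic(Z[tr], y_bin[tr], lam)
            eta = b0 + Z[va] @ b
            s = 2 * y_bin[va] - 1
            losses[k, i] = np.mean(np.logaddexp(0.0, -s * eta))
    mean_loss = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(cv)
    best = int(np.argmin(mean_loss))
    # 1-SE rule: lambdas are descending, so the smallest index within one SE
    # of the optimum is the most regularised admissible choice
    one_se = int(np.flatnonzero(mean_loss <= mean_loss[best] + se[best])[0])
    lam = float(lambdas[one_se])
    beta, intercept = _nnlasso_logistic(Z, y_bin, lam)
    return pd.Series(beta, index=oof.columns, name="meta_coef"), intercept, lam


def superlearner_score(oof_or_proba: pd.DataFrame, coef: pd.Series, intercept: float) -> np.ndarray:
    eta = intercept + oof_or_proba[coef.index].to_numpy(dtype=float) @ coef.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max-F1 threshold on out-of-fold super-learner scores (ties: smallest).

    Candidates are the observed score values; predicted threatened iff
    score >= threshold.  Always returns a value in the open interval (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == POSITIVE).astype(int) if np.asarray(labels).dtype.kind in "OUS" else np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    # at threshold t = s[k] (unique values), positives = all rows with score >= t
    tp = np.cumsum(yy)
    pred_pos = np.arange(1, len(s) + 1)
    total_pos = yy.sum()
    f1 = 2 * tp / (pred_pos + total_pos)
    # evaluate at the last row of each tied score block
    last_of_block = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    cand_f1 = f1[last_of_block]
    cand_t = s[last_of_block]
    best_f1 = cand_f1.max()
    # ties -> smallest threshold
    threshold = float(cand_t[np.flatnonzero(np.isclose(cand_f1, best_f1))[-1]])
    eps = 1e-9
    return float(np.clip(threshold, eps, 1 - eps))


@dataclass
class StackedModel:
    """A trained super-learner for one data partition."""

    partition_tag: str  # all | marine | non_marine
    roster: list[BaseLearnerSpec]
    imputer: RandomValueImputer
    encoder: FeatureEncoder
    selection: SelectionResult
    feature_columns: list[str]
    fold_assignment: pd.Series
    oof: pd.DataFrame
    meta_coef: pd.Series
    intercept: float
    lambda_: float
    threshold: float
    base_models: dict = field(default_factory=dict)
    train_ids: list[str] = field(default_factory=list)
    train_labels: pd.Series | None = None

    @property
    def oof_super_scores(self) -> np.ndarray:
        return superlearner_score(self.oof, self.meta_coef, self.intercept)

    def encode(self, table: pd.DataFrame) -> pd.DataFrame:
        """Impute (training-fitted pools) and encode rows to the model's design."""
        imputed = self.imputer.transform(table)
        X = self.encoder.transform(imputed)
        missing = [c for c in self.feature_columns if c not in X.columns]
        if missing:
            raise ValueError(f"missing confirmed feature column(s): {missing}")
        return X[self.feature_columns]

    def score_encoded(self, X: pd.DataFrame) -> np.ndarray:
        proba = pd.DataFrame(
            {name: _proba(m, X.to_numpy(dtype=float)) for name, m in self.base_models.items()},
            index=X.index,
        )
        return superlearner_score(proba, self.meta_coef, self.intercept)

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """PE scores and binary labels for feature-table rows."""
        X = self.encode(table)
        pe = self.score_encoded(X)
        return pd.DataFrame(
            {
                "species_id": table["species_id"].to_numpy(),
                "pe_score": pe,
                "predicted_label": np.where(pe >= self.threshold, "threatened", "not_threatened"),
                "partition_tag": self.partition_tag,
            }
        )


def train_model(
    table: pd.DataFrame,
    train_ids,
    seed: int,
    roster: list[BaseLearnerSpec] | None = None,
    folds: int = 10,
    boruta_runs: int = 50,
    boruta_alpha: float = 0.01,
    partition_tag: str = "all",
    feature_subset: list[str] | None = None,
    confirmed: list[str] | None = None,
) -> StackedModel:
    """Train one stacked super-learner on the given training species.

    Imputation pools, the one-hot encoder, feature selection and all model
    fits use training rows only.  ``feature_subset`` optionally restricts
    the candidate predictor columns before selection; ``confirmed`` skips
    Boruta and uses a precomputed confirmed list.
    """
    roster = roster or default_roster()
    ss = np.random.SeedSequence([seed, 57])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    train = table.loc[train_ids]
    y = train["label"].to_numpy()

    imputer = RandomValueImputer(seeds[0]).fit(table[sorted(set(table.columns) - {"label"})], train_ids)
    train_imp = imputer.transform(train)
    encoder = FeatureEncoder().fit(train_imp)
    X_train = encoder.transform(train_imp)
    if feature_subset is not None:
        cols = [c for c in encoder.columns_ if encoder.blocks[c] in set(feature_subset)]
        X_train = X_train[cols]
    if confirmed is None:
        selection = boruta_select(
            X_train, y, R=boruta_runs, alpha=boruta_alpha, seed=seeds[1], blocks=encoder.blocks
        )
        confirmed_cols = selection.confirmed
    else:
        selection = SelectionResult(
            table=pd.DataFrame({"feature": confirmed, "hits": -1, "decision": "confirmed"}),
            R=0, alpha=boruta_alpha, blocks=encoder.blocks, confirmed=list(confirmed),
        )
        confirmed_cols = list(confirmed)
    if not confirmed_cols:
        logger.warning("no features confirmed; falling back to all candidates")
        confirmed_cols = list(X_train.columns)
    Xc = X_train[confirmed_cols]

    oof, fold_assignment = cv_oof(Xc, y, roster, folds=folds, seed=seeds[2])
    meta_coef, intercept, lam = fit_meta(oof, y, seed=seeds[3])
    threshold = choose_threshold(superlearner_score(oof, meta_coef, intercept), y)

    # final base models: refit on the full oversampled training set
    refit_rng = np.random.default_rng(seeds[4])
    y_bin = (y == POSITIVE).astype(int)
    res = oversample_indices(y_bin, refit_rng)
    base_models = {
        spec.name: spec.build(seeds[4]).fit(Xc.to_numpy(dtype=float)[res], y_bin[res])
        for spec in roster
    }
    return StackedModel(
        partition_tag=partition_tag,
        roster=roster,
        imputer=imputer,
        encoder=encoder,
        selection=selection,
        feature_columns=confirmed_cols,
        fold_assignment=fold_assignment,
        oof=oof,
        meta_coef=meta_coef,
        intercept=intercept,
        lambda_=lam,
        threshold=threshold,
        base_models=base_models,
        train_ids=list(train_ids),
        train_labels=pd.Series(y, index=train.index),
    )


def train_partitions(
    table: pd.DataFrame,
    split: pd.DataFrame,
    seed: int,
    roster: list[BaseLearnerSpec] | None = None,
    min_subset_rows: int = 50,
    **kwargs,
) -> dict[str, StackedModel]:
    """Train partition 1 (all species) and partition 2 (marine / non-marine).

    Feature selection runs independently on each trained model's own
    training data.  A marine or non-marine training subset smaller than
    ``min_subset_rows`` is skipped with a warning (partition 2 then
    degenerates to the remaining model).
    """
    roles = split.set_index("species_id")["role"]
    train_ids = roles[roles == "train"].index
    models = {"all": train_model(table, train_ids, seed, roster, partition_tag="all", **kwargs)}
    marine = table.loc[train_ids, "is_marine"].astype(bool)
    for tag, ids in (("marine", train_ids[marine]), ("non_marine", train_ids[~marine])):
        if len(ids) < min_subset_rows:
            logger.warning("%s training subset has %d rows (< %d); skipped", tag, len(ids), min_subset_rows)
            continue
        models[tag] = train_model(table, ids, seed, roster, partition_tag=tag, **kwargs)
    return models


def partition_cv_scores(models: dict[str, StackedModel], table: pd.DataFrame) -> dict[str, pd.Series]:
    """Cross-validated super-learner scores per partition, keyed by species."""
    out: dict[str, pd.Series] = {}
    if "all" in models:
        m = models["all"]
        out["all"] = pd.Series(m.oof_super_scores, index=m.oof.index)
    parts = [models[t] for t in ("marine", "non_marine") if t in models]
    if parts:
        out["marine_split"] = pd.concat(
            [pd.Series(m.oof_super_scores, index=m.oof.index) for m in parts]
        )
    return out


def select_partition(
    cv_scores: dict[str, pd.Series],
    labels: pd.Series,
    classes: pd.Series,
    min_class_members: int = 5,
) -> str:
    """Pick the partition with the highest mean AUC across taxonomic classes.

    The mean is unweighted over classes with at least ``min_class_members``
    labelled species scored by every partition; ties (and the no-eligible-
    class fallback, which uses pooled AUC) go to partition "all".
    """
    if len(cv_scores) < 2:
        raise ValueError("need at least two partitions to select between")
    common = None
    for s in cv_scores.values():
        common = s.index if common is None else common.intersection(s.index)
    y = labels.loc[common]
    cls = classes.loc[common]
    means: dict[str, float] = {}
    for tag, s in cv_scores.items():
        aucs = []
        for c, members in cls.groupby(cls).groups.items():
            yc = y.loc[members]
            if len(members) >= min_class_members and yc.nunique() == 2:
                aucs.append(auc(s.loc[members].to_numpy(), (yc == POSITIVE).to_numpy()))
        means[tag] = float(np.mean(aucs)) if aucs else auc(
            s.loc[common].to_numpy(), (y == POSITIVE).to_numpy()
        )
    best = max(means.values())
    if np.isclose(means.get("all", -np.inf), best):
        return "all"
    return max(means, key=means.get)
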