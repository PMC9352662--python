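"""Shadow-feature (Boruta-style) relevance filtering.

Each run duplicates every feature as an independently permuted "shadow",
fits a seeded random forest on originals + shadows, and scores a hit for
every original feature whose out-of-bag permutation importance strictly
exceeds the best shadow's.  After R runs (default 50), a two-sided exact
binomial test of the hit count against Binomial(R, 1/2) at alpha = 0.01
declares each feature confirmed, rejected, or tentative; only confirmed
features continue downstream.

The variant here is one-shot (all features stay in every run) and uses
out-of-bag permutation importance rather than impurity importance, which is
biased toward high-cardinality features and would distort the shadow
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

DEFAULT_RUNS = 50
DEFAULT_ALPHA = 0.01
_FOREST_SIZE = 60


def _bootstrap_oob_masks(estimator: RandomForestClassifier, n: int) -> list[np.ndarray]:
    """Per-tree out-of-bag boolean masks, replaying sklearn's bootstrap draw."""
    masks = []
    for tree in estimator.estimators_:
        sampled = np.random.RandomState(tree.random_state).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def oob_permutation_importance(
    estimator: RandomForestClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean over trees of the OOB accuracy drop when one column is permuted.

    Features a tree never splits on contribute zero for that tree, so the
    per-tree work scales with the features actually used.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    n, p = X.shape
    importances = np.zeros(p)
    masks = _bootstrap_oob_masks(estimator, n)
    for tree, oob in zip(estimator.estimators_, masks):
        if not oob.any():
            continue
        Xo = X[oob].copy()
        yo = y[oob]
        t = tree.tree_
        base = float(np.mean(t.predict(Xo).reshape(len(Xo), -1).argmax(axis=1) == yo))
        used = np.unique(t.feature[t.feature >= 0])
        for j in used:
            saved = Xo[:, j].copy()
            Xo[:, j] = saved[rng.permutation(len(saved))]
            acc = float(np.mean(t.predict(Xo).reshape(len(Xo), -1).argmax(axis=1) == yo))
            Xo[:, j] = saved
            importances[j] += base - acc
    return importances / len(estimator.estimators_)


def shadow_run(
    X: pd.DataFrame, y: np.ndarray, seed: int, n_estimators: int = _FOREST_SIZE
) -> pd.Series:
    """One Boruta run: hit indicator per feature.

    A feature hits iff its OOB permutation importance strictly exceeds the
    maximum importance among all shadow (permuted-copy) features.
    """
    if X.shape[1] < 2:
        raise ValueError("shadow_run needs at least two features")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("shadow_run needs both classes present")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    shadows = Xv[rng.permuted(np.tile(np.arange(n), (p, 1)).T, axis=0), np.arange(p)]
    Xfull = np.hstack([Xv, shadows])
    y_enc = np.asarray(pd.factorize(np.asarray(y), sort=True)[0])
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        bootstrap=True,
        n_jobs=1,
        random_state=int(rng.integers(2**31)),
    ).fit(Xfull, y_enc)
    imp = oob_permutation_importance(forest, Xfull, y_enc, rng)
    threshold = imp[p:].max()
    return pd.Series(imp[:p] > threshold, index=X.columns, name="hit")


@dataclass
class SelectionResult:
    """Per-feature hit counts and binomial decisions over R shadow runs."""

    table: pd.DataFrame  # columns: feature, hits, decision
    R: int
    alpha: float
    blocks: dict[str, str] | None = None
    confirmed: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    R: int = DEFAULT_RUNS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    blocks: dict[str, str] | None = None,
    n_estimators: int = _FOREST_SIZE,
) -> SelectionResult:
    """Aggregate R shadow runs into confirmed / rejected / tentative decisions.

    ``blocks`` maps encoded columns to source columns (one-hot blocks); a
    block counts as confirmed when any of its member columns is confirmed,
    and then the whole block is kept.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    ss = np.random.SeedSequence([seed, 23])
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(R)]
    hits = pd.Series(0, index=X.columns, dtype=int)
    for rs in run_seeds:
        hits += shadow_run(X, y, rs, n_estimators=n_estimators).astype(int)

    def decide(h: int) -> str:
        p = stats.binomtest(h, R, 0.5).pvalue
        if p < alpha:
            return "confirmed" if h > R / 2 else "rejected"
        return "tentative"

    decisions = hits.map(decide)
    confirmed_cols = set(decisions[decisions == "confirmed"].index)
    if blocks:
        confirmed_blocks = {blocks[c] for c in confirmed_cols}
        confirmed_cols = {c for c in X.columns if blocks.get(c, c) in confirmed_blocks}
    table = pd.DataFrame(
        {"feature": X.columns, "hits": hits.values, "decision": decisions.values}
    )
    return SelectionResult(
        table=table,
        R=R,
        alpha=alpha,
        blocks=blocks,
        confirmed=sorted(confirmed_cols, key=list(X.columns).index),
    )
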