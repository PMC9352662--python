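"""Classifier evaluation: confusion-matrix metrics, AUC, AUC_PR, Gini,
permutation variable importance, and validation on re-assessed species.

The threshold-dependent metrics are the standard confusion-matrix ratios
(accuracy, specificity, sensitivity/recall, false positive rate, negative
and positive predictive value) plus balanced accuracy, the mean of
specificity and sensitivity.  Metrics with a zero denominator are reported
as undefined (None), never coerced to 0.  AUC uses the rank-statistic
formulation (ties count one half); AUC_PR is average precision with
step-wise interpolation; Gini = 2*AUC - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

POSITIVE = "threatened"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class MetricsReport:
    """Confusion-based metrics; None marks an undefined (0/0) entry."""

    accuracy: float | None = None
    specificity: float | None = None
    sensitivity: float | None = None
    false_positive_rate: float | None = None
    npv: float | None = None
    ppv: float | None = None
    balanced_accuracy: float | None = None
    auc: float | None = None
    auc_pr: float | None = None
    gini: float | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        """Display rounding, half-up (matching printed tables)."""
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                out[f.name] = None
            else:
                shift = 10**ndigits
                out[f.name] = float(np.floor(v * shift + 0.5) / shift)
        return out


def confusion(predicted, reference) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with 'threatened' as the positive class."""
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference label lists differ in length")
    pred_pos = predicted == POSITIVE
    ref_pos = reference == POSITIVE
    return ConfusionMatrix(
        tp=int(np.sum(pred_pos & ref_pos)),
        tn=int(np.sum(~pred_pos & ~ref_pos)),
        fp=int(np.sum(pred_pos & ~ref_pos)),
        fn=int(np.sum(~pred_pos & ref_pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Exact confusion-matrix arithmetic; full precision, round only for display."""
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        specificity=spec,
        sensitivity=sens,
        false_positive_rate=_ratio(cm.fp, cm.fp + cm.tn),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        balanced_accuracy=(spec + sens) / 2 if spec is not None and sens is not None else None,
    )


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == POSITIVE).astype(int)
    return labels.astype(int)


def auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties: 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Average precision: sum over descending-score cuts of dR * precision.

    Step-wise (no linear interpolation between PR points); tied scores are
    processed as one block.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUC_PR undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    tp = np.cumsum(yy)
    pred = np.arange(1, len(s) + 1)
    block_end = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    precision = tp[block_end] / pred[block_end]
    recall = tp[block_end] / n_pos
    d_recall = np.diff(recall, prepend=0.0)
    return float(np.sum(d_recall * precision))


def gini(scores, labels) -> float:
    """Degree of class separation: 2*AUC - 1."""
    return 2.0 * auc(scores, labels) - 1.0


def ranking_metrics(scores, labels) -> MetricsReport:
    """AUC, AUC_PR and Gini in one report (threshold-independent part)."""
    a = auc(scores, labels)
    return MetricsReport(auc=a, auc_pr=auc_pr(scores, labels), gini=2 * a - 1)


def permutation_importance(
    model,
    test_table: pd.DataFrame,
    test_labels,
    reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean AUC loss on the test data when one feature is permuted.

    For each confirmed feature column: baseline test AUC (computed once)
    minus the AUC after permuting that column, averaged over ``reps``
    seeded permutations.  Returns a table sorted by descending importance.
    """
    y = _as_binary(test_labels)
    X = model.encode(test_table)
    baseline = auc(model.score_encoded(X), y)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    n = len(X)
    rows = []
    for col in model.feature_columns:
        # one stacked prediction call for all repetitions of this feature
        stacked = pd.concat([X] * reps, ignore_index=True)
        colv = X[col].to_numpy()
        permuted = np.concatenate([colv[rng.permutation(n)] for _ in range(reps)])
        stacked[col] = permuted
        scores = model.score_encoded(stacked)
        drops = [baseline - auc(scores[r * n : (r + 1) * n], y) for r in range(reps)]
        rows.append({"feature": col, "importance": float(np.mean(drops))})
    out = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    return out.reset_index(drop=True)


def validate_on_reassessed(
    model,
    reassessed_table: pd.DataFrame,
    revealed_labels: pd.Series,
) -> tuple[ConfusionMatrix, MetricsReport, int]:
    """Score formerly data-deficient species against newly revealed labels.

    The rows must have been held out of training (checked against the
    model's training ids); returns the confusion matrix, the metrics report
    (including ranking metrics when both classes occur), and the number of
    correctly classified species.
    """
    if len(reassessed_table) == 0:
        raise ValueError("empty re-assessed slice")
    overlap = set(reassessed_table["species_id"]) & set(model.train_ids)
    if overlap:
        raise ValueError(f"re-assessed species overlap training data: {sorted(overlap)[:5]}")
    preds = model.predict(reassessed_table)
    ref = revealed_labels.loc[preds["species_id"]].to_numpy()
    cm = confusion(preds["predicted_label"].to_numpy(), ref)
    report = compute_metrics(cm)
    y = _as_binary(ref)
    if 0 < y.sum() < len(y):
        report.auc = auc(preds["pe_score"].to_numpy(), y)
        report.auc_pr = auc_pr(preds["pe_score"].to_numpy(), y)
        report.gini = 2 * report.auc - 1
    return cm, report, cm.tp + cm.tn
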