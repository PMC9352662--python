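import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import planted_table
from pescore.evaluation import auc
from pescore.partition import make_split_assignment
from pescore.stacking import (
    BaseLearnerSpec,
    StackedModel,
    choose_threshold,
    cv_oof,
    default_roster,
    fit_meta,
    partition_cv_scores,
    select_partition,
    superlearner_score,
    train_model,
    train_partitions,
    _nnlasso_logistic,
)

FAST_ROSTER = [
    BaseLearnerSpec("glm", "regularized-GLM", {"C": 1.0}),
    BaseLearnerSpec("rf", "random-forest", {"n_estimators": 40}),
]


class TestCvOof:
    def setup_method(self):
        self.X, self.y = planted_table(200, 2, 3, seed=1, betas=(1.5, -1.2))

    def test_oof_auc_above_chance_with_signal(self):
        oof, _ = cv_oof(self.X, self.y, FAST_ROSTER, folds=5, seed=2)
        for col in oof.columns:
            assert auc(oof[col].to_numpy(), self.y) > 0.5

    def test_fold_sizes_differ_by_at_most_one(self):
        _, folds = cv_oof(self.X, self.y, FAST_ROSTER, folds=10, seed=3)
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == len(self.y)

    def test_same_seed_identical_assignment_and_scores(self):
        oof_a, fold_a = cv_oof(self.X, self.y, FAST_ROSTER, folds=5, seed=4)
        oof_b, fold_b = cv_oof(self.X, self.y, FAST_ROSTER, folds=5, seed=4)
        pd.testing.assert_series_equal(fold_a, fold_b)
        pd.testing.assert_frame_equal(oof_a, oof_b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cv_oof(self.X, np.zeros(len(self.X), dtype=int), FAST_ROSTER, folds=5, seed=1)


class TestNonNegativeLasso:
    def prox_grad_oracle(self, Z, y, lam, iters=120000, lr=0.1):
        """Independent solver: projected proximal gradient descent."""
        n, p = Z.shape
        b0, b = 0.0, np.zeros(p)
        for _ in range(iters):
            eta = b0 + Z @ b
            mu = 1 / (1 + np.exp(-eta))
            g = Z.T @ (mu - y) / n
            b0 -= lr * np.mean(mu - y)
            b = np.maximum(b - lr * (g + lam), 0.0)  # prox of lam*sum(b) on b>=0
        return b, b0

    def test_matches_proximal_gradient_oracle(self):
        rng = np.random.default_rng(5)
        Z = rng.random((300, 4))
        y = (rng.random(300) < Z[:, 0]).astype(int)
        for lam in (0.001, 0.02, 0.2):
            b, b0 = _nnlasso_logistic(Z, y, lam)
            ob, ob0 = self.prox_grad_oracle(Z, y, lam)
            np.testing.assert_allclose(b, ob, atol=2e-3)
            assert b0 == pytest.approx(ob0, abs=2e-3)

    def test_noise_learners_zeroed(self):
        """An OOF column equal to the Bayes probabilities should carry the
        ensemble; pure-noise columns should get exactly zero weight in at
        least 9 of 10 replicates."""
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            p_true = rng.beta(2, 2, 500)
            y = (rng.random(500) < p_true).astype(int)
            oof = pd.DataFrame(
                {
                    "good": p_true,
                    "noise1": rng.random(500),
                    "noise2": rng.random(500),
                }
            )
            coef, _, _ = fit_meta(oof, y, seed=rep)
            wins += (coef["good"] > 0) and (coef[["noise1", "noise2"]] == 0).all()
        assert wins >= 9

    def test_coefficients_nonnegative_and_single_learner_monotone(self):
        rng = np.random.default_rng(7)
        scores = rng.random(300)
        y = (rng.random(300) < scores).astype(int)
        oof = pd.DataFrame({"only": scores})
        coef, intercept, _ = fit_meta(oof, y, seed=1)
        assert (coef >= 0).all()
        combined = superlearner_score(oof, coef, intercept)
        rho = spearmanr(combined, scores).statistic
        assert rho == pytest.approx(1.0)

    def test_incomplete_oof_rejected(self):
        oof = pd.DataFrame({"a": [0.5, np.nan]})
        with pytest.raises(ValueError):
            fit_meta(oof, np.array([0, 1]), seed=1)


class TestThreshold:
    def brute_force(self, scores, y):
        best = (-1.0, None)
        for t in np.unique(scores):
            pred = scores >= t
            tp = np.sum(pred & (y == 1))
            f1 = 2 * tp / (pred.sum() + y.sum()) if (pred.sum() + y.sum()) else 0.0
            if f1 > best[0] + 1e-12 or (abs(f1 - best[0]) <= 1e-12 and t < best[1]):
                best = (f1, t)
        return best[1]

    def test_matches_exhaustive_cutpoint_search(self, rng):
        for _ in range(25):
            scores = rng.choice(np.round(rng.random(12), 2), size=40)
            y = (rng.random(40) < scores).astype(int)
            if y.sum() in (0, len(y)):
                continue
            assert choose_threshold(scores, y) == pytest.approx(
                np.clip(self.brute_force(scores, y), 1e-9, 1 - 1e-9)
            )

    def test_perfectly_separated_returns_gap_edge(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert choose_threshold(scores, y) == pytest.approx(0.8)

    def test_threshold_in_open_unit_interval(self, rng):
        scores = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0, 1, 0, 1])
        assert 0 < choose_threshold(scores, y) < 1


@pytest.fixture(scope="module")
def trained(small_table):
    split = make_split_assignment(small_table, seed=13)
    roles = split.set_index("species_id")["role"]
    model = train_model(
        small_table,
        roles[roles == "train"].index,
        seed=13,
        roster=FAST_ROSTER,
        folds=5,
        boruta_runs=8,
    )
    return model, small_table, roles


class TestTrainedModel:
    def test_scores_in_unit_interval_and_labels_match_threshold(self, trained):
        model, table, roles = trained
        preds = model.predict(table.loc[roles[roles == "test"].index])
        assert preds.pe_score.between(0, 1).all()
        expected = np.where(preds.pe_score >= model.threshold, "threatened", "not_threatened")
        assert (preds.predicted_label == expected).all()

    def test_dd_rows_never_in_training(self, trained):
        model, table, roles = trained
        dd_ids = set(roles[roles == "dd_holdout"].index)
        assert not dd_ids & set(model.train_ids)
        preds = model.predict(table.loc[sorted(dd_ids)])
        assert len(preds) == len(dd_ids)

    def test_missing_confirmed_column_named(self, trained):
        model, table, roles = trained
        broken = table.drop(columns=[model.selection.blocks[model.feature_columns[0]]])
        with pytest.raises((ValueError, KeyError)):
            model.predict(broken.loc[roles[roles == "test"].index])

    def test_oof_rows_align_with_training_ids(self, trained):
        model, _, _ = trained
        assert sorted(model.oof.index) == sorted(model.train_ids)
        assert model.oof.notna().all().all()
        assert (model.meta_coef >= 0).all()

    def test_no_information_leak_from_test_rows(self, small_table):
        """Deleting the test/DD rows before training must not change the
        trained model (hash comparison of its learned parameters)."""
        split = make_split_assignment(small_table, seed=14)
        roles = split.set_index("species_id")["role"]
        train_ids = roles[roles == "train"].index

        def fingerprint(table):
            model = train_model(table, train_ids, seed=14, roster=FAST_ROSTER,
                                folds=5, boruta_runs=5)
            blob = (
                model.meta_coef.to_json()
                + f"{model.intercept:.12f}{model.threshold:.12f}"
                + model.oof.round(12).to_json()
                + ",".join(model.feature_columns)
            )
            return hashlib.sha256(blob.encode()).hexdigest()

        full = fingerprint(small_table)
        train_only = fingerprint(small_table.loc[train_ids])
        assert full == train_only


class TestPartitions:
    def _table(self, seed, n=400, opposite=False):
        rng = np.random.default_rng(seed)
        X, _ = planted_table(n, 1, 3, seed=seed, betas=(0.0,))
        marine = rng.random(n) < 0.5
        slope = np.where(marine, 2.0, -2.0) if opposite else np.full(n, 2.0)
        eta = slope * X["f00"].to_numpy()
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        table = X.copy()
        table["species_id"] = [f"sp{i:04d}" for i in range(n)]
        table["family"] = np.where(rng.random(n) < 0.5, "A", "B")
        table["class"] = np.where(rng.random(n) < 0.5, "C1", "C2")
        table["is_marine"] = marine
        table["label"] = np.where(y, "threatened", "not_threatened")
        table["category"] = np.where(y, "VU", "LC")
        table["outdated_assessment"] = False
        return table.set_index("species_id", drop=False)

    def _split(self, table, seed):
        return make_split_assignment(table, seed)

    def test_marine_model_never_sees_non_marine_rows(self):
        table = self._table(1)
        split = self._split(table, 1)
        models = train_partitions(table, split, seed=1, roster=FAST_ROSTER,
                                  folds=4, confirmed=["f00", "g00"])
        marine_ids = set(table[table.is_marine].species_id)
        assert set(models["marine"].train_ids) <= marine_ids
        assert not set(models["non_marine"].train_ids) & marine_ids

    def test_both_partitions_score_same_test_ids(self):
        table = self._table(2)
        split = self._split(table, 2)
        models = train_partitions(table, split, seed=2, roster=FAST_ROSTER,
                                  folds=4, confirmed=["f00", "g00"])
        roles = split.set_index("species_id")["role"]
        test = table.loc[roles[roles == "test"].index]
        p1 = models["all"].predict(test)
        marine = test[test.is_marine]
        non_marine = test[~test.is_marine]
        p2_ids = set(models["marine"].predict(marine).species_id) | set(
            models["non_marine"].predict(non_marine).species_id
        )
        assert set(p1.species_id) == p2_ids

    def test_tiny_subset_skipped_with_degenerate_partition(self):
        table = self._table(3, n=150)
        table["is_marine"] = False
        table.loc[table.index[:5], "is_marine"] = True
        split = self._split(table, 3)
        models = train_partitions(table, split, seed=3, roster=FAST_ROSTER,
                                  folds=3, confirmed=["f00"])
        assert "marine" not in models and "non_marine" in models

    def test_identical_scores_tie_goes_to_all(self):
        scores = pd.Series([0.9, 0.2, 0.8, 0.1], index=list("abcd"))
        labels = pd.Series(["threatened", "not_threatened"] * 2, index=list("abcd"))
        classes = pd.Series(["C"] * 4, index=list("abcd"))
        chosen = select_partition(
            {"all": scores, "marine_split": scores.copy()}, labels, classes, min_class_members=2
        )
        assert chosen == "all"

    def test_small_class_excluded_from_average(self):
        # class D (4 members) carries opposite ranking; it must be ignored
        idx = [f"i{k}" for k in range(14)]
        labels = pd.Series(["threatened"] * 7 + ["not_threatened"] * 7, index=idx)
        classes = pd.Series(["C"] * 5 + ["D"] * 2 + ["C"] * 5 + ["D"] * 2, index=idx)
        good = pd.Series(np.r_[np.ones(5), np.zeros(2), np.zeros(5), np.ones(2)], index=idx)
        bad = 1 - good
        chosen = select_partition({"all": bad, "marine_split": good}, labels, classes)
        assert chosen == "marine_split"

    def test_opposite_domain_effects_prefer_split_partition(self):
        """When marine and non-marine species respond oppositely to the same
        stressor, the split partition should win the class-averaged AUC in
        at least 8 of 10 replicates."""
        wins = 0
        glm_only = [BaseLearnerSpec("glm", "regularized-GLM", {"C": 1.0})]
        for rep in range(10):
            table = self._table(50 + rep, n=400, opposite=True)
            split = self._split(table, rep)
            models = train_partitions(table, split, seed=rep, roster=glm_only,
                                      folds=4, confirmed=["f00"])
            scores = partition_cv_scores(models, table)
            labels = table["label"]
            classes = table["class"]
            chosen = select_partition(scores, labels, classes)
            wins += chosen == "marine_split"
        assert wins >= 8
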