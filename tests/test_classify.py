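"""SMOTE balancing, metric definitions, and the CV engine."""

import numpy as np
import pandas as pd
import pytest

from copreserve import CvConfig, SelectionConfig, compute_metrics, run_cv, smote_balance

FAST_CV = CvConfig(
    classifiers=("LR", "KNN"),
    grids={"LR": [{"C": 1.0}], "KNN": [{"n_neighbors": 3}]},
    repeat_seeds=(0,),
)


class TestSmote:
    def test_balanced_input_is_a_noop(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.repeat([0, 1], 5)
        Xb, yb = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_two_minority_points_interpolate_on_the_segment(self, rng):
        X = np.vstack([rng.normal(10, 0.1, size=(8, 2)), [[0.0, 0.0], [1.0, 1.0]]])
        y = np.array([0] * 8 + [1] * 2)
        Xb, yb = smote_balance(X, y, seed=3)
        synthetic = Xb[10:]
        assert len(synthetic) == 6
        for p in synthetic:
            assert p[0] == pytest.approx(p[1])  # on the segment (0,0)-(1,1)
            assert 0.0 <= p[0] <= 1.0

    def test_counting_30_52(self, rng):
        X = rng.normal(size=(82, 4))
        y = np.array([1] * 30 + [0] * 52)
        Xb, yb = smote_balance(X, y, seed=1)
        assert len(Xb) == 104
        assert (yb == 1).sum() == (yb == 0).sum() == 52
        np.testing.assert_array_equal(Xb[:82], X)  # originals untouched

    def test_synthetic_points_use_at_most_k_nearest_neighbours(self, rng):
        """Each synthetic row lies on a segment between a minority point and
        one of its k=3 nearest minority neighbours."""
        from sklearn.neighbors import NearestNeighbors

        X_min = rng.normal(size=(10, 2))
        X = np.vstack([rng.normal(5, 1, size=(20, 2)), X_min])
        y = np.array([0] * 20 + [1] * 10)
        Xb, _ = smote_balance(X, y, seed=7, k_cap=3)
        synthetic = Xb[30:]
        nbr = NearestNeighbors(n_neighbors=4).fit(X_min)
        _, nn = nbr.kneighbors(X_min)
        ok = []
        for p in synthetic:
            found = False
            for i in range(10):
                for j in nn[i, 1:]:
                    a, b = X_min[i], X_min[j]
                    denom = b - a
                    with np.errstate(divide="ignore", invalid="ignore"):
                        lam = np.where(denom != 0, (p - a) / denom, np.nan)
                    lam = lam[np.isfinite(lam)]
                    if len(lam) and np.allclose(lam, lam[0], atol=1e-8) and -1e-9 <= lam[0] <= 1 + 1e-9:
                        found = True
            ok.append(found)
        assert all(ok)

    def test_single_minority_point_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="minority"):
            smote_balance(X, y, seed=0)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 8 + [1] * 4)
        a, _ = smote_balance(X, y, seed=5)
        b, _ = smote_balance(X, y, seed=5)
        np.testing.assert_array_equal(a, b)


class TestComputeMetrics:
    def test_confusion_matrix_hand_example(self):
        m = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(1.0)
        assert m["recall"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(2.0 / 3.0)

    def test_perfect_probabilities(self):
        m = compute_metrics([0, 0, 1, 1], [0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m["roc_auc"] == 1.0
        assert m["aupr"] == 1.0

    def test_constant_probabilities_give_chance_auc(self):
        m = compute_metrics([0, 1, 0, 1], [0, 0, 0, 0], [0.5, 0.5, 0.5, 0.5])
        assert m["roc_auc"] == pytest.approx(0.5)

    def test_single_class_auc_reported_missing(self):
        m = compute_metrics([1, 1, 1], [1, 1, 0], [0.9, 0.8, 0.4])
        assert m["roc_auc"] is None
        assert m["aupr"] is None

    def test_no_positive_predictions_zero_precision(self):
        m = compute_metrics([1, 0], [0, 0], [0.4, 0.3])
        assert m["precision"] == 0.0


def _separable_frame(rng, n_per_class=15, p=4):
    y = np.repeat([0, 1], n_per_class)
    X = rng.normal(size=(2 * n_per_class, p)) * 0.05
    X[:, 0] += y * 10.0  # massive separation on one axis
    idx = [f"S{i:02d}" for i in range(2 * n_per_class)]
    return pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(p)]), y


class TestRunCv:
    def test_separable_features_reach_ceiling(self, rng):
        X, y = _separable_frame(rng)
        report = run_cv(X, y, FAST_CV)
        for clf in FAST_CV.classifiers:
            assert report.per_classifier[clf]["roc_auc"][0] == pytest.approx(1.0)
            assert report.per_classifier[clf]["accuracy"][0] == pytest.approx(1.0)

    def test_every_subject_scored_once_per_classifier_per_repeat(self, rng):
        X, y = _separable_frame(rng)
        cfg = CvConfig(classifiers=("LR",), grids={"LR": [{"C": 1.0}]}, repeat_seeds=(0, 1))
        report = run_cv(X, y, cfg)
        for rep in (0, 1):
            assert sorted(report.oof_probabilities["LR"][rep]) == sorted(X.index)

    def test_permuted_labels_are_at_chance(self, rng):
        """Label-permutation null: mean out-of-fold ROC-AUC near 0.5."""
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(40, 5)), index=[f"S{i}" for i in range(40)])
            X.columns = [f"f{j}" for j in range(5)]
            y = r.permutation(np.repeat([0, 1], 20))
            cfg = CvConfig(classifiers=("LR",), grids={"LR": [{"C": 1.0}]}, repeat_seeds=(seed,))
            report = run_cv(X, y, cfg)
            aucs.append(report.pooled["roc_auc"][0])
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_deterministic_given_seeds(self, rng):
        X, y = _separable_frame(rng)
        a = run_cv(X, y, FAST_CV, selection=SelectionConfig(rf_trees=50, rf_seed=0))
        b = run_cv(X, y, FAST_CV, selection=SelectionConfig(rf_trees=50, rf_seed=0))
        assert a.per_classifier == b.per_classifier
        assert a.oof_probabilities == b.oof_probabilities

    def test_per_fold_selection_differs_from_global_bookkeeping(self, rng):
        X, y = _separable_frame(rng, n_per_class=20, p=6)
        sel = SelectionConfig(rf_trees=50, rf_seed=0)
        rep = run_cv(X, y, FAST_CV, selection=sel, selection_scope="per_fold")
        assert all(1 <= len(v) <= 7 for v in rep.selected_per_fold.values())
        rep_g = run_cv(X, y, FAST_CV, selection=sel, selection_scope="global")
        assert len({tuple(v) for v in rep_g.selected_per_fold.values()}) == 1

    def test_too_few_subjects_per_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdef"))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="per class"):
            run_cv(X, y, FAST_CV)

    def test_paper_mode_runs_and_reports(self, rng):
        X, y = _separable_frame(rng)
        cfg = CvConfig(classifiers=("LR",), grids={"LR": [{"C": 0.1}, {"C": 1.0}]},
                       repeat_seeds=(0,), mode="paper")
        report = run_cv(X, y, cfg)
        assert report.per_classifier["LR"]["f1"][0] == pytest.approx(1.0)
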