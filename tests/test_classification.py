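"""Rule-based annotation, cubic-SVM training, CV and metric arithmetic."""

import numpy as np
import pandas as pd
import pytest

import crystalscreen as cs
from crystalscreen.classification import (
    AnnotationConflictError,
    StratificationError,
    _content_order,
    make_svm,
)
from sklearn.model_selection import StratifiedKFold


def _feature_frame(values: dict) -> pd.DataFrame:
    """A full-width feature table with given columns, rest zero."""
    n = len(next(iter(values.values())))
    df = pd.DataFrame({name: np.zeros(n) for name in cs.FEATURE_NAMES})
    for name, vals in values.items():
        df[name] = vals
    df.insert(0, "segment_id", np.arange(1, n + 1))
    return df


def _gaussian_clusters(n_per_class=50, n_classes=4, separation=15.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cls in range(n_classes):
        center = np.zeros(len(cs.FEATURE_NAMES))
        center[cls % len(cs.FEATURE_NAMES)] = separation
        rows.append(rng.normal(center, 1.0, size=(n_per_class, len(center))))
    X = np.vstack(rows)
    df = pd.DataFrame(X, columns=cs.FEATURE_NAMES)
    df["label"] = np.repeat(np.arange(n_classes), n_per_class)
    return df


class TestAnnotate:
    def test_single_rule_labels_only_matches(self):
        table = _feature_frame({"area": [100.0, 200.0]})
        rules = [cs.AnnotationRule("area", ">", 150.0, assigned_class=1)]
        labeled = cs.annotate(table, rules)
        assert labeled["label"].tolist() == [1]
        assert labeled["segment_id"].tolist() == [2]

    def test_empty_rule_list_gives_empty_table(self):
        table = _feature_frame({"area": [1.0, 2.0]})
        assert len(cs.annotate(table, [])) == 0

    def test_later_rule_overrides_earlier(self):
        table = _feature_frame({"area": [100.0]})
        rules = [
            cs.AnnotationRule("area", ">", 50.0, assigned_class=0),
            cs.AnnotationRule("area", ">", 90.0, assigned_class=1),
        ]
        assert cs.annotate(table, rules)["label"].tolist() == [1]

    def test_equal_precedence_conflict_raises_with_ids(self):
        table = _feature_frame({"area": [100.0, 10.0]})
        rules = [
            cs.AnnotationRule("area", ">", 50.0, assigned_class=0, precedence=5),
            cs.AnnotationRule("area", ">", 90.0, assigned_class=1, precedence=5),
        ]
        with pytest.raises(AnnotationConflictError, match=r"\[1\]"):
            cs.annotate(table, rules)

    def test_image_scoped_rules_respect_scope(self):
        table = _feature_frame({"area": [100.0, 100.0]})
        table["image_id"] = ["img-a", "img-b"]
        rules = [cs.AnnotationRule("area", ">", 50.0, assigned_class=2, scope="img-a")]
        labeled = cs.annotate(table, rules)
        assert labeled["image_id"].tolist() == ["img-a"]

    def test_rules_recover_generator_ground_truth(self):
        """Single-feature per-image thresholds agree with >= 95% of truth."""
        spec = cs.SceneSpec(n_com=40, n_cod=15, n_nd=0, n_noise=10, seed=5)
        image, truth = cs.render_scene(spec)
        label_map, segments = cs.segment_crystals(image)
        table = cs.extract_all(image, label_map, segments)
        matched = cs.match_segments(label_map, truth)
        truth_labels = np.array([matched[s.segment_id][0] for s in segments])
        rules = [
            cs.AnnotationRule("major_axis", "between", 5.5, threshold_hi=11.0,
                              assigned_class=0),
            cs.AnnotationRule("major_axis", ">", 11.0, assigned_class=1),
            cs.AnnotationRule("major_axis", "<", 5.5, assigned_class=3),
            # spurious fragments are tiny whatever their elongation;
            # the later rule overrides the size-based polymorph calls
            cs.AnnotationRule("area", "<", 16.0, assigned_class=3),
        ]
        labeled = cs.annotate(table, rules)
        agreement = (labeled["label"].to_numpy()
                     == truth_labels[labeled.index.to_numpy()]).mean()
        assert agreement >= 0.95


class TestTrain:
    def test_separable_clusters_reach_perfect_cv_accuracy(self):
        model, report = cs.train(_gaussian_clusters(), seed=0)
        assert report.overall_accuracy == 1.0
        assert report.n_folds == 5

    def test_confusion_matrix_marginals_match_class_counts(self):
        table = _gaussian_clusters(n_per_class=30, separation=2.0, seed=1)
        _, report = cs.train(table, seed=0)
        np.testing.assert_array_equal(report.confusion_matrix.sum(axis=1),
                                      [30, 30, 30, 30])

    def test_cv_accuracy_invariant_to_row_order(self):
        table = _gaussian_clusters(n_per_class=25, separation=3.0, seed=2)
        _, r1 = cs.train(table, seed=3)
        _, r2 = cs.train(table.sample(frac=1, random_state=9), seed=3)
        assert r1.overall_accuracy == r2.overall_accuracy
        np.testing.assert_array_equal(r1.confusion_matrix, r2.confusion_matrix)

    def test_small_class_raises_stratification_error(self):
        table = _gaussian_clusters(n_per_class=20, n_classes=2)
        table = pd.concat([table, table.iloc[-1:].assign(label=2)], ignore_index=True)
        with pytest.raises(StratificationError, match="class 2"):
            cs.train(table, seed=0)

    def test_single_class_rejected(self):
        table = _gaussian_clusters(n_per_class=20, n_classes=1)
        with pytest.raises(ValueError, match="2 classes"):
            cs.train(table, seed=0)

    def test_permuted_labels_give_chance_accuracy(self):
        """The permutation null: accuracy within the 99% band around 1/4."""
        table = _gaussian_clusters(n_per_class=100, separation=15.0, seed=4)
        rng = np.random.default_rng(0)
        table["label"] = rng.permutation(table["label"].to_numpy())
        _, report = cs.train(table, seed=0)
        n = len(table)
        half_width = 2.576 * np.sqrt(0.25 * 0.75 / n)
        assert abs(report.overall_accuracy - 0.25) <= half_width

    def test_per_fold_scaling_matches_manual_leak_free_cv(self):
        """Fold scalers are fit on training folds only (no leakage)."""
        table = _gaussian_clusters(n_per_class=25, separation=3.0, seed=5)
        # pathological scale shift on one feature
        table.iloc[: len(table) // 2, table.columns.get_loc("area")] *= 1e6
        _, report = cs.train(table, seed=1)
        X = table[cs.FEATURE_NAMES].to_numpy(float)
        y = table["label"].to_numpy(int)
        order = _content_order(X, y)
        Xo, yo = X[order], y[order]
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        y_pred = np.empty_like(yo)
        for tr, te in cv.split(Xo, yo):
            pipe = make_svm()
            pipe.fit(Xo[tr], yo[tr])  # scaler sees the training fold only
            y_pred[te] = pipe.predict(Xo[te])
        assert (y_pred == yo).mean() == report.overall_accuracy


class TestClassifyAndPersistence:
    def test_training_set_is_reproduced_on_separable_data(self):
        table = _gaussian_clusters()
        model, _ = cs.train(table, seed=0)
        labels = cs.classify(model, table)
        np.testing.assert_array_equal(labels, table["label"].to_numpy())

    def test_empty_input_gives_empty_output(self, small_model):
        empty = pd.DataFrame(columns=cs.FEATURE_NAMES)
        assert len(cs.classify(small_model, empty)) == 0

    def test_schema_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError, match="missing"):
            cs.classify(small_model, pd.DataFrame({"area": [1.0]}))

    def test_reloaded_model_predicts_identically(self, tmp_path, small_model):
        table = _gaussian_clusters(n_per_class=10, seed=7)
        path = tmp_path / "model.bin"
        small_model.save(path)
        reloaded = cs.ClassifierModel.load(path)
        np.testing.assert_array_equal(cs.classify(small_model, table),
                                      cs.classify(reloaded, table))


class TestEvaluate:
    def test_perfect_predictions(self):
        r = cs.evaluate([0, 1, 2, 3] * 5, [0, 1, 2, 3] * 5)
        assert r.overall_accuracy == 1.0
        assert all(v == 1.0 for v in r.f1.values())

    def test_two_class_hand_arithmetic(self):
        """TP=8 FP=2 FN=1 TN=9 for class 1."""
        y_true = [1] * 9 + [0] * 11
        y_pred = [1] * 8 + [0] + [1] * 2 + [0] * 9
        r = cs.evaluate(y_true, y_pred)
        p, rec = 0.8, 8 / 9
        assert r.precision[1] == pytest.approx(p)
        assert r.recall[1] == pytest.approx(rec)
        assert r.f1[1] == pytest.approx(2 * p * rec / (p + rec))

    def test_all_one_class_prediction(self):
        y_true = [0, 0, 1, 2, 3]
        r = cs.evaluate(y_true, [0] * 5)
        assert r.recall[0] == 1.0
        assert r.recall[1] == r.recall[2] == r.recall[3] == 0.0
        assert r.f1[1] == 0.0

    def test_out_of_vocabulary_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            cs.evaluate([0, 5], [0, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cs.evaluate([0], [0, 1])
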