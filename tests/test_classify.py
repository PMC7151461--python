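import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voitex import (
    class_weights,
    cross_validate,
    default_model_specs,
    hypothesis_check,
    prediction_confidence,
    train_classifier,
)
from voitex.classify import ModelSpec
from voitex.errors import SplitError, TrainingError


def _blob_table(
    seed: int,
    n_per_class=(20, 10, 30),
    separation: float = 10.0,
    n_features: int = 2,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    centers = {"control": 0.0, "prodromal": separation, "pd": 2 * separation}
    idx = 0
    for cls, n in zip(("control", "prodromal", "pd"), n_per_class):
        for _ in range(n):
            feats = centers[cls] + rng.normal(0, 0.3, size=n_features)
            rows.append({"scan_id": f"s{idx}", "class": cls, **{
                f"f{i}": feats[i] for i in range(n_features)
            }})
            idx += 1
    return pd.DataFrame(rows)


class TestClassWeights:
    def test_paper_cohort_truncated_weights(self):
        wset = class_weights({"control": 203, "prodromal": 66, "pd": 637}, tau=0.5)
        t4 = wset.truncated(4)
        assert t4["control"] == 0.3486
        assert t4["prodromal"] == 0.8365
        assert wset.truncated(2)["pd"] == 0.14

    def test_majority_class_full_precision(self):
        wset = class_weights({"control": 203, "prodromal": 66, "pd": 637}, tau=0.5)
        assert wset.weights["pd"] == pytest.approx(abs(math.log10(0.5 * 906 / 637)))

    def test_weight_zero_when_count_hits_tau_n(self):
        wset = class_weights({"a": 50, "b": 50}, tau=0.5)
        assert wset.weights["a"] == 0.0

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights({"a": 0, "b": 5})

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            class_weights({"a": 5, "b": 5}, tau=0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 40), st.integers(2, 50))
    def test_minority_weighted_more_property(self, n_small, gap):
        # for counts below tau*N the weight strictly decreases with count
        n_big = n_small + gap
        counts = {"small": n_small, "big": n_big, "rest": 200}
        wset = class_weights(counts, tau=0.5)
        total = sum(counts.values())
        if n_big < 0.5 * total:
            assert wset.weights["small"] > wset.weights["big"]


class TestHypothesisCheck:
    def test_diagonal_all_true(self):
        cm = np.diag([10, 5, 20])
        assert hypothesis_check(cm) == (True, True, True)

    def test_pd_mispredicted_fails_flag1(self):
        cm = np.array([[10, 0, 0], [0, 5, 0], [1, 0, 19]])
        flags = hypothesis_check(cm)
        assert flags[0] is False and flags[1] is True and flags[2] is True

    def test_prodromal_to_control_fails_flag2(self):
        cm = np.array([[10, 0, 0], [1, 4, 0], [0, 0, 20]])
        assert hypothesis_check(cm)[1] is False

    def test_control_recall_strict_boundary(self):
        # recall exactly 0.85 must fail the strict "more than 85%" rule
        cm = np.array([[17, 2, 1], [0, 5, 0], [0, 0, 20]])
        assert cm[0, 0] / cm[0].sum() == 0.85
        assert hypothesis_check(cm)[2] is False
        cm[0] = [18, 1, 1]
        assert hypothesis_check(cm)[2] is True

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            hypothesis_check(np.eye(2))


class TestTrainClassifier:
    # Table-8-style SVM (gamma 1e-4) and RF (leaf >= 10) underfit toy blobs
    # by design, so the separability check supplies fitting-capable params.
    _SEPARABLE_SPECS = {
        "mlp": ModelSpec("mlp", params={"epochs": 200}, seed=0),
        "gradient_boosted_trees": ModelSpec(
            "gradient_boosted_trees", params={"n_estimators": 60, "max_depth": 3}, seed=0
        ),
        "random_forest": ModelSpec(
            "random_forest", params={"n_estimators": 100, "min_samples_leaf": 1}, seed=0
        ),
        "svm": ModelSpec("svm", params={"gamma": "scale", "C": 10.0}, seed=0),
    }

    @pytest.mark.parametrize(
        "family", ["mlp", "gradient_boosted_trees", "random_forest", "svm"]
    )
    def test_separable_training_accuracy(self, family):
        table = _blob_table(0, n_per_class=(20, 12, 28))
        counts = table["class"].value_counts().to_dict()
        wset = class_weights(counts, tau=0.5)
        model = train_classifier(
            table, ["f0", "f1"], self._SEPARABLE_SPECS[family], wset
        )
        x = table[["f0", "f1"]].to_numpy(float)
        acc = float(np.mean(model.predict(x) == table["class"]))
        assert acc == 1.0, family

    def test_single_class_rejected(self):
        table = _blob_table(0)
        table["class"] = "pd"
        wset = class_weights({"pd": len(table)}, tau=0.5)
        with pytest.raises(TrainingError):
            train_classifier(table, ["f0"], default_model_specs()["mlp"], wset)

    def test_no_signal_collapses_to_weighted_class(self):
        # identical features: predictions go to the weight-favored class
        table = _blob_table(1, n_per_class=(20, 6, 40))
        for col in ("f0", "f1"):
            table[col] = 1.0
        counts = table["class"].value_counts().to_dict()
        wset = class_weights(counts, tau=0.5)
        favored = max(wset.weights, key=wset.weights.get)
        assert favored == "prodromal"
        for family in ("mlp", "random_forest"):
            spec = default_model_specs(seed=0)[family]
            model = train_classifier(table, ["f0", "f1"], spec, wset)
            preds = model.predict(table[["f0", "f1"]].to_numpy(float))
            assert set(preds) == {favored}, family

    def test_missing_feature_rejected(self):
        table = _blob_table(0)
        wset = class_weights(table["class"].value_counts().to_dict())
        with pytest.raises(ValueError, match="absent"):
            train_classifier(table, ["nope"], default_model_specs()["svm"], wset)


class TestPredictionConfidence:
    class _FixedModel:
        classes_ = np.array(["control", "prodromal", "pd"])

        def __init__(self, probs):
            self._probs = np.asarray(probs)

        def predict_proba(self, x):
            return np.tile(self._probs, (len(x), 1))

    def test_perfectly_confident(self):
        y = np.array(["control", "control", "pd"])
        model = self._FixedModel([1.0, 0.0, 0.0])
        out = prediction_confidence(model, np.zeros((3, 2)), y)
        assert out["control"]["confidence"] == 1.0
        assert out["pd"]["confidence"] == 0.0
        assert out["prodromal"]["confidence"] is None  # class absent

    def test_uniform_probabilities(self):
        y = np.array(["control", "prodromal", "pd"])
        model = self._FixedModel([1 / 3, 1 / 3, 1 / 3])
        out = prediction_confidence(model, np.zeros((3, 2)), y)
        for cls in ("control", "prodromal", "pd"):
            assert out[cls]["confidence"] == pytest.approx(1 / 3)
            assert out[cls]["qq_probabilities"] == [pytest.approx(1 / 3)]


class TestCrossValidate:
    def test_separable_cohort_perfect_splits(self):
        table = _blob_table(2, n_per_class=(10, 6, 14))
        specs = {"mlp": default_model_specs(0)["mlp"]}
        reports = cross_validate(table, ["f0", "f1"], specs=specs, n_splits=5, seed=0)
        rep = reports["mlp"]
        assert len(rep.splits) == 5
        for split in rep.splits:
            assert split["accuracy"] == 1.0
            assert split["hypothesis_flags"] == [True, True, True]

    def test_report_structure_all_families(self):
        table = _blob_table(3, n_per_class=(10, 6, 14))
        small_specs = {
            "mlp": ModelSpec("mlp", params={"epochs": 60}, seed=0),
            "gradient_boosted_trees": ModelSpec(
                "gradient_boosted_trees", params={"n_estimators": 30}, seed=0
            ),
            "random_forest": ModelSpec("random_forest", params={"n_estimators": 30}, seed=0),
            "svm": ModelSpec("svm", params={"gamma": "scale"}, seed=0),
        }
        reports = cross_validate(table, ["f0", "f1"], specs=small_specs, n_splits=5)
        assert set(reports) == set(small_specs)
        for rep in reports.values():
            assert len(rep.splits) == 5
            for split in rep.splits:
                cm = np.array(split["confusion_matrix"])
                assert cm.sum() == 6  # 30 samples / 5 splits
                assert 0.0 <= split["accuracy"] <= 1.0
                assert set(split["confidences"]) == {"control", "prodromal", "pd"}
            doc = rep.to_dict()
            assert set(doc["summary"]) == {
                "accuracy",
                "precision_macro",
                "precision_weighted",
                "recall_macro",
                "recall_weighted",
                "f1_macro",
                "f1_weighted",
            }

    def test_confusion_row_sums_match_class_counts(self):
        table = _blob_table(4, n_per_class=(10, 5, 15), separation=0.1)
        specs = {"svm": ModelSpec("svm", params={"gamma": "scale"}, seed=0)}
        reports = cross_validate(table, ["f0", "f1"], specs=specs, n_splits=5, seed=1)
        totals = np.zeros(3, dtype=int)
        for split in reports["svm"].splits:
            cm = np.array(split["confusion_matrix"])
            totals += cm.sum(axis=1)
        assert totals.tolist() == [10, 5, 15]

    def test_small_class_split_error(self):
        table = _blob_table(5, n_per_class=(10, 3, 10))
        with pytest.raises(SplitError, match="prodromal"):
            cross_validate(table, ["f0", "f1"], n_splits=5)

    def test_permuted_labels_near_majority_rate(self):
        # permutation null (uniform weights): accuracy ~ majority proportion
        base = _blob_table(6, n_per_class=(12, 6, 22), separation=5.0)
        specs = {"mlp": ModelSpec("mlp", params={"epochs": 100}, seed=0)}
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table = base.copy()
            table["class"] = rng.permutation(table["class"].to_numpy())
            rep = cross_validate(
                table, ["f0", "f1"], specs=specs, n_splits=5, seed=seed, tau=None
            )
            accs.append(rep["mlp"].mean_accuracy)
        majority = 22 / 40
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - majority) < 3 * se + 0.05
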