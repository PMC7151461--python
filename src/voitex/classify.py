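"""Class-weighted multiclass classification with 5-split cross-validation.

Implements the class-weight rule w_c = |log10(tau * N / n_c)|, trains the
four comparison model families (MLP, gradient-boosted trees, random
forest, RBF-SVM) with per-class loss weights, reports per-split metrics,
confusion matrices, per-class prediction confidence, and the three-part
hypothesis flags:

1. recall of the PD class equals 100%;
2. no prodromal sample is predicted as control;
3. recall of the control class exceeds 85% (strict).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import SplitError, TrainingError
from .mlp import MLPClassifier
from .phantom import CLASSES

__all__ = [
    "ClassWeightSet",
    "ModelSpec",
    "CVReport",
    "class_weights",
    "default_model_specs",
    "train_classifier",
    "cross_validate",
    "hypothesis_check",
    "prediction_confidence",
]

MODEL_FAMILIES = ("mlp", "gradient_boosted_trees", "random_forest", "svm")


@dataclass(frozen=True)
class ClassWeightSet:
    """Per-class training weights derived from sample counts."""

    counts: dict[str, int]
    tau: float
    weights: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def truncated(self, decimals: int) -> dict[str, float]:
        """Weights truncated (not rounded) to a fixed decimal count."""
        f = 10**decimals
        return {c: math.floor(w * f) / f for c, w in self.weights.items()}


def class_weights(counts: dict[str, int], tau: float = 0.5) -> ClassWeightSet:
    """w_c = |log10(tau * N / n_c)| for each class.

    Minority classes get larger weights (for n_c < tau*N the weight
    decreases strictly as n_c grows).
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if any(n < 1 for n in counts.values()):
        raise ValueError(f"all class counts must be >= 1, got {counts}")
    total = sum(counts.values())
    weights = {c: abs(math.log10(tau * total / n)) for c, n in counts.items()}
    return ClassWeightSet(counts=dict(counts), tau=tau, weights=weights)


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameters and seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


def default_model_specs(seed: int = 0) -> dict[str, ModelSpec]:
    """The four comparison configurations."""
    return {
        "mlp": ModelSpec(
            "mlp",
            params={
                "hidden_layers": (10, 128, 256, 64, 16),
                "learning_rate": 1.0,
                "plateau_factor": 0.8,
                "plateau_patience": 2,
                "epochs": 400,
            },
            seed=seed,
        ),
        "gradient_boosted_trees": ModelSpec(
            "gradient_boosted_trees",
            params={"n_estimators": 600, "max_depth": 9},
            seed=seed,
        ),
        "random_forest": ModelSpec(
            "random_forest",
            params={
                "n_estimators": 1000,
                "criterion": "gini",
                "max_depth": 7,
                "min_samples_split": 20,
                "min_samples_leaf": 10,
            },
            seed=seed,
        ),
        "svm": ModelSpec(
            "svm",
            params={
                "kernel": "rbf",
                "degree": 3,
                "gamma": 0.0001,
                "C": 1.0,
                "tol": 0.001,
                "cache_size": 200,
            },
            seed=seed,
        ),
    }


class _CalibratedSVC:
    """RBF-SVM with per-class sigmoid (Platt-style) score calibration.

    The SVC itself does not emit probabilities; a one-vs-rest logistic
    map is fitted on the training-fold decision scores, then the per-class
    sigmoids are normalized to a probability vector. Hard predictions
    come straight from the SVC decision rule.
    """

    def __init__(self, svc: SVC) -> None:
        self._pipe = Pipeline([("scale", StandardScaler()), ("svc", svc)])
        self._calibrators: list[LogisticRegression] = []
        self.classes_: np.ndarray | None = None

    def _scores(self, x: np.ndarray) -> np.ndarray:
        s = self._pipe.decision_function(x)
        if s.ndim == 1:  # binary: one margin column per class
            s = np.column_stack([-s, s])
        return s

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_CalibratedSVC":
        self._pipe.fit(x, y)
        self.classes_ = self._pipe.named_steps["svc"].classes_
        scores = self._scores(x)
        self._calibrators = []
        for j, cls in enumerate(self.classes_):
            lr = LogisticRegression(max_iter=1000)
            lr.fit(scores[:, [j]], (y == cls).astype(int))
            self._calibrators.append(lr)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        scores = self._scores(x)
        cols = []
        for j, lr in enumerate(self._calibrators):
            pos = list(lr.classes_).index(1) if 1 in lr.classes_ else None
            if pos is None:  # class never positive in training: probability 0
                cols.append(np.zeros(len(scores)))
            else:
                cols.append(lr.predict_proba(scores[:, [j]])[:, pos])
        p = np.column_stack(cols)
        total = p.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return p / total

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._pipe.predict(x)


def _fit_family(spec: ModelSpec, x: np.ndarray, y: np.ndarray, wset: ClassWeightSet):
    # the weight formula hits exactly 0 when n_c == tau*N, which would
    # remove a class from the loss entirely; floor the applied weights
    w = {c: max(v, 1e-3) for c, v in wset.weights.items()}
    if spec.family == "mlp":
        model = MLPClassifier(seed=spec.seed, **spec.params)
        return model.fit(x, y, class_weight=w)
    if spec.family == "gradient_boosted_trees":
        model = GradientBoostingClassifier(random_state=spec.seed, **spec.params)
        sample_weight = np.array([w[c] for c in y])
        return model.fit(x, y, sample_weight=sample_weight)
    if spec.family == "random_forest":
        model = RandomForestClassifier(
            random_state=spec.seed, class_weight=w, **spec.params
        )
        return model.fit(x, y)
    # svm: probabilities via sigmoid score calibration on the training fold
    model = _CalibratedSVC(
        SVC(class_weight=w, random_state=spec.seed, **spec.params)
    )
    return model.fit(x, y)


def train_classifier(
    table: pd.DataFrame,
    kept: list[str],
    spec: ModelSpec,
    weights: ClassWeightSet,
):
    """Train one family on the kept feature columns with class weights."""
    missing = [c for c in kept if c not in table.columns]
    if missing:
        raise ValueError(f"kept features absent from table: {missing[:5]}")
    y = table["class"].to_numpy()
    if len(np.unique(y)) < 2:
        raise TrainingError("training requires at least 2 classes")
    x = table[kept].to_numpy(dtype=float)
    return _fit_family(spec, x, y, weights)


def hypothesis_check(
    confusion: np.ndarray, class_order: tuple[str, ...] = CLASSES
) -> tuple[bool, bool, bool]:
    """Evaluate the three-part hypothesis on a 3x3 confusion matrix.

    Rows are true classes, columns predictions, both in ``class_order``.
    A class with no test samples passes its flag vacuously.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (3, 3):
        raise ValueError(f"expected a 3x3 confusion matrix, got {confusion.shape}")
    ctrl, prod, pd_ = (class_order.index(c) for c in ("control", "prodromal", "pd"))

    pd_total = confusion[pd_].sum()
    flag1 = bool(pd_total == 0 or confusion[pd_, pd_] == pd_total)
    flag2 = bool(confusion[prod, ctrl] == 0)
    ctrl_total = confusion[ctrl].sum()
    flag3 = bool(ctrl_total == 0 or confusion[ctrl, ctrl] / ctrl_total > 0.85)
    return flag1, flag2, flag3


def prediction_confidence(
    model, x_test: np.ndarray, y_test: np.ndarray
) -> dict[str, dict]:
    """Per-class mean predicted probability of the true class, plus the
    sorted per-sample probabilities for QQ plotting against the constant
    1.0 reference."""
    probs = model.predict_proba(x_test)
    model_classes = list(model.classes_)
    out: dict[str, dict] = {}
    for c in CLASSES:
        mask = y_test == c
        if not mask.any():
            out[c] = {"confidence": None, "qq_probabilities": []}
            continue
        if c not in model_classes:
            out[c] = {"confidence": 0.0, "qq_probabilities": []}
            continue
        p_true = probs[mask, model_classes.index(c)]
        out[c] = {
            "confidence": float(p_true.mean()),
            "qq_probabilities": sorted(float(v) for v in p_true),
        }
    return out


@dataclass
class CVReport:
    """Per-split metrics and summaries for one model family."""

    family: str
    n_splits: int
    splits: list[dict] = field(default_factory=list)

    def mean_metric(self, name: str) -> float:
        return float(np.mean([s[name] for s in self.splits]))

    @property
    def mean_accuracy(self) -> float:
        return self.mean_metric("accuracy")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_splits": self.n_splits,
            "splits": self.splits,
            "summary": {
                name: self.mean_metric(name)
                for name in (
                    "accuracy",
                    "precision_macro",
                    "precision_weighted",
                    "recall_macro",
                    "recall_weighted",
                    "f1_macro",
                    "f1_weighted",
                )
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _split_metrics(y_true, y_pred, confidences) -> dict:
    cm = confusion_matrix(y_true, y_pred, labels=list(CLASSES))
    flags = hypothesis_check(cm)
    kw = {"labels": list(CLASSES), "zero_division": 0}
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision_macro": float(precision_score(y_true, y_pred, average="macro", **kw)),
        "precision_weighted": float(
            precision_score(y_true, y_pred, average="weighted", **kw)
        ),
        "recall_macro": float(recall_score(y_true, y_pred, average="macro", **kw)),
        "recall_weighted": float(recall_score(y_true, y_pred, average="weighted", **kw)),
        "f1_macro": float(f1_score(y_true, y_pred, average="macro", **kw)),
        "f1_weighted": float(f1_score(y_true, y_pred, average="weighted", **kw)),
        "confusion_matrix": cm.tolist(),
        "hypothesis_flags": list(flags),
        "confidences": confidences,
    }


def cross_validate(
    table: pd.DataFrame,
    kept: list[str],
    specs: dict[str, ModelSpec] | None = None,
    n_splits: int = 5,
    seed: int = 0,
    tau: float | None = 0.5,
) -> dict[str, CVReport]:
    """Stratified shuffled k-fold CV for each model family.

    Class weights are recomputed from each training fold's counts (never
    from the full table) to avoid test-fold leakage. ``tau=None`` trains
    with uniform class weights; permutation-null controls use this so the
    no-signal predictor defaults to the majority class instead of the
    weight-favored minority.
    """
    specs = specs or default_model_specs(seed)
    y = table["class"].to_numpy()
    present, counts = np.unique(y, return_counts=True)
    for cls, n in zip(present, counts):
        if n < n_splits:
            raise SplitError(
                f"class {cls!r} has only {n} samples; needs >= {n_splits} "
                f"for {n_splits}-split stratified CV"
            )
    x = table[kept].to_numpy(dtype=float)

    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    reports = {name: CVReport(family=name, n_splits=n_splits) for name in specs}
    for split_idx, (tr, te) in enumerate(cv.split(x, y), start=1):
        fold_counts = {c: int(n) for c, n in zip(*np.unique(y[tr], return_counts=True))}
        if tau is None:
            wset = ClassWeightSet(
                counts=fold_counts, tau=1.0, weights={c: 1.0 for c in fold_counts}
            )
        else:
            wset = class_weights(fold_counts, tau=tau)
        for name, spec in specs.items():
            model = _fit_family(spec, x[tr], y[tr], wset)
            y_pred = model.predict(x[te])
            confidences = prediction_confidence(model, x[te], y[te])
            metrics = _split_metrics(y[te], y_pred, confidences)
            metrics["split"] = split_idx
            reports[name].splits.append(metrics)
    return reports
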