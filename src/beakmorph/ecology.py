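"""Trophic-niche classification: weights, splits, MC-CV tuning, evaluation.

Niche classes are heavily imbalanced (hundreds of invertivores versus a
dozen scavengers), so every specimen in class j receives case weight
``w_i = 1 / n_j`` — each class contributes equal total weight to model
fitting.  Model selection uses Monte-Carlo cross-validation: repeated
random stratified validation splits of the training data, scoring each
hyperparameter point by mean validation balanced accuracy, then refitting
the winner on all training rows.  Solvers (random forest, elastic-net
multinomial regression) are delegated to scikit-learn; this module owns
the protocol.

Balanced accuracy follows the average-of-sensitivity-and-specificity
definition, macro-averaged one-vs-rest over classes — robust to imbalance
where plain accuracy is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .core import InvalidParameterError

MODEL_FAMILIES = ("random_forest", "multinomial_elasticnet")


@dataclass
class WeightedLabels:
    """Labels with inverse-class-size case weights (each class sums to 1)."""

    labels: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.weights):
            raise InvalidParameterError("labels and weights must align")


def assign_case_weights(labels) -> WeightedLabels:
    """w_i = 1 / n_j for every member of class j."""
    labels = np.asarray([str(l) for l in np.asarray(labels, dtype=object)])
    if len(labels) == 0:
        raise InvalidParameterError("empty label vector")
    counts = pd.Series(labels).value_counts()
    weights = np.array([1.0 / counts[l] for l in labels])
    return WeightedLabels(labels=labels, weights=weights)


def stratified_split(
    labels, test_prop: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, test) index arrays, stratified by class.

    Each class contributes round(n_j * test_prop) members to the test set
    (at least 1, at most n_j - 1 so that both sides see every class).
    """
    if not 0.0 < test_prop < 1.0:
        raise InvalidParameterError("test_prop must lie in (0, 1)")
    labels = np.asarray([str(l) for l in np.asarray(labels, dtype=object)])
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        rng.shuffle(idx)
        n_test = int(np.floor(len(idx) * test_prop + 0.5))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


@dataclass
class EvalReport:
    """Accuracy, balanced accuracy and the full confusion matrix."""

    accuracy: float
    balanced_accuracy: float
    confusion: pd.DataFrame  # rows = truth, columns = prediction
    per_class_sensitivity: pd.Series = field(default=None)
    per_class_specificity: pd.Series = field(default=None)


def confusion_metrics(confusion: pd.DataFrame) -> EvalReport:
    """Metrics from a truth-by-prediction count matrix.

    Balanced accuracy is the macro average over classes of
    (sensitivity_j + specificity_j) / 2 in one-vs-rest form.  Classes
    absent from both truth and prediction are excluded with a warning.
    """
    cm = confusion.to_numpy(dtype=float)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    sens, spec, kept = {}, {}, []
    for j, cls in enumerate(confusion.index):
        tp = cm[j, j]
        pos = cm[j, :].sum()
        pred_pos = cm[:, j].sum()
        if pos == 0 and pred_pos == 0:
            warnings.warn(
                f"class {cls!r} absent from truth and predictions; excluded"
            )
            continue
        tn = total - pos - pred_pos + tp
        neg = total - pos
        sens[cls] = tp / pos if pos > 0 else np.nan
        spec[cls] = tn / neg if neg > 0 else np.nan
        kept.append(cls)
    per_class = np.array(
        [0.5 * (sens[c] + spec[c]) for c in kept if np.isfinite(sens[c])]
    )
    return EvalReport(
        accuracy=accuracy,
        balanced_accuracy=float(per_class.mean()),
        confusion=confusion,
        per_class_sensitivity=pd.Series(sens),
        per_class_specificity=pd.Series(spec),
    )


def evaluate(model, features_test: np.ndarray, labels_test) -> EvalReport:
    """Score a fitted classifier on held-out rows."""
    labels_test = np.asarray([str(l) for l in np.asarray(labels_test, dtype=object)])
    if len(labels_test) == 0:
        raise InvalidParameterError("empty test set")
    pred = np.asarray([str(p) for p in model.predict(features_test)])
    classes = sorted(set(labels_test) | set(pred))
    cm = pd.crosstab(
        pd.Categorical(labels_test, categories=classes),
        pd.Categorical(pred, categories=classes),
        dropna=False,
    )
    cm.index = classes
    cm.columns = classes
    return confusion_metrics(cm)


def _make_model(model: str, point: dict, seed: int):
    if model == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(point.get("trees", 200)),
            max_features=point.get("mtry", "sqrt"),
            min_samples_leaf=int(point.get("min_n", 1)),
            random_state=seed,
            n_jobs=1,
        )
    if model == "multinomial_elasticnet":
        lam = float(point.get("lambda", 1e-3))
        return LogisticRegression(
            solver="saga",
            l1_ratio=float(point.get("alpha", 0.5)),
            C=1.0 / max(lam, 1e-12),
            max_iter=int(point.get("max_iter", 2000)),
            random_state=seed,
        )
    raise InvalidParameterError(
        f"unknown model family {model!r}; choose from {MODEL_FAMILIES}"
    )


@dataclass
class TunedModel:
    model: object
    family: str
    chosen: dict
    cv_results: pd.DataFrame


def tune_and_fit(
    features: np.ndarray,
    weighted_labels: WeightedLabels,
    model: str = "random_forest",
    grid: list[dict] | None = None,
    n_mc_splits: int = 20,
    val_prop: float = 0.2,
    seed: int = 0,
) -> TunedModel:
    """Monte-Carlo CV hyperparameter search, then refit on all rows.

    Each of ``n_mc_splits`` random stratified splits holds out
    ``val_prop`` of the rows for validation; the grid point with the best
    mean validation balanced accuracy wins (ties to the earlier point).
    The final model is refit on every row with the case weights.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = weighted_labels.labels
    weights = weighted_labels.weights
    if len(X) != len(labels):
        raise InvalidParameterError("features row count must match labels")
    if not grid:
        raise InvalidParameterError("hyperparameter grid must be non-empty")

    scores = np.zeros((len(grid), n_mc_splits))
    for s in range(n_mc_splits):
        tr, va = stratified_split(labels, test_prop=val_prop, seed=seed + 1000 + s)
        for g, point in enumerate(grid):
            clf = _make_model(model, point, seed)
            clf.fit(X[tr], labels[tr], sample_weight=weights[tr])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = evaluate(clf, X[va], labels[va])
            scores[g, s] = rep.balanced_accuracy
    mean_scores = scores.mean(axis=1)
    best = int(np.argmax(mean_scores))
    final = _make_model(model, grid[best], seed)
    final.fit(X, labels, sample_weight=weights)
    cv = pd.DataFrame(
        {"point": [str(p) for p in grid], "mean_balanced_accuracy": mean_scores}
    )
    return TunedModel(model=final, family=model, chosen=grid[best], cv_results=cv)


def classification_experiment(
    features: np.ndarray,
    labels,
    model: str = "random_forest",
    grid: list[dict] | None = None,
    test_prop: float = 0.2,
    n_mc_splits: int = 20,
    seed: int = 0,
    qc_keep: np.ndarray | None = None,
) -> EvalReport:
    """The full protocol: QC filter, stratified holdout, weights, tune, score.

    ``qc_keep`` is an optional boolean mask dropping specimens whose
    meshes failed manual quality control.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray([str(l) for l in np.asarray(labels, dtype=object)])
    if qc_keep is not None:
        X = X[np.asarray(qc_keep, bool)]
        labels = labels[np.asarray(qc_keep, bool)]
    tr, te = stratified_split(labels, test_prop=test_prop, seed=seed)
    wl = assign_case_weights(labels[tr])
    grid = grid or [{"trees": 200, "mtry": "sqrt", "min_n": 1}]
    tuned = tune_and_fit(
        X[tr], wl, model=model, grid=grid, n_mc_splits=n_mc_splits, seed=seed
    )
    return evaluate(tuned.model, X[te], labels[te])
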