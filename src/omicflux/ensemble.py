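"""Per-omic-layer classifiers, uniform-weight soft voting, and SHAP ranking.

Each omic layer gets its own random-forest classifier (grid-searched with
stratified CV on 80% of the samples); class probabilities are pooled across
layers by weighted averaging with uniform weights by default.  Global
feature importance is the mean absolute SHAP attribution, with markers
selected above a fixed threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expression import ExpressionMatrix
from .treeshap import forest_shap_values

__all__ = [
    "LayerModel",
    "EnsembleModel",
    "EvalReport",
    "ShapRanking",
    "split_train_test",
    "fit_layer",
    "vote",
    "evaluate",
    "shap_rank",
    "svm_baseline",
    "DEFAULT_RF_GRID",
    "DEFAULT_SHAP_THRESHOLD",
    "DEFAULT_TRAIN_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_TRAIN_FRACTION = 0.8
DEFAULT_CV_FOLDS = 5
DEFAULT_SHAP_THRESHOLD = 1e-4

#: Conventional coverage of the named forest hyperparameter dimensions.
DEFAULT_RF_GRID: dict[str, list] = {
    "clf__n_estimators": [100, 300, 500],
    "clf__max_depth": [None, 10, 30],
    "clf__max_features": ["sqrt", "log2"],
    "clf__min_samples_leaf": [1, 3],
    "clf__min_samples_split": [2, 5],
}

#: Compact grid for quick runs and tests.
SMALL_RF_GRID: dict[str, list] = {
    "clf__n_estimators": [100],
    "clf__max_depth": [None, 10],
}

DEFAULT_SVM_GRID: dict[str, list] = {
    "clf__C": [0.1, 1.0, 10.0],
    "clf__kernel": ["rbf", "linear"],
}


def split_train_test(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified, seeded train/test split of sample ids."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    labels = list(labels)
    counts = pd.Series(labels).value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        raise ValueError(
            f"classes with fewer than 2 samples cannot be split: {singletons}"
        )
    train, test = train_test_split(
        list(sample_ids),
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return list(train), list(test)


@dataclass
class LayerModel:
    """A fitted per-layer classifier with its provenance."""

    layer: str
    estimator: Pipeline
    hyperparameters: dict
    classes: list[str]
    feature_ids: list[str]
    cv_score: float = float("nan")

    def _design(self, X: ExpressionMatrix, samples: Sequence[str]) -> np.ndarray:
        missing = set(self.feature_ids) - set(X.gene_ids)
        if missing:
            raise ValueError(
                f"layer {self.layer}: matrix lacks fitted features "
                f"{sorted(missing)[:5]}"
            )
        return X.values.loc[self.feature_ids, list(samples)].to_numpy(dtype=float).T

    def predict_proba(
        self, X: ExpressionMatrix, samples: Sequence[str]
    ) -> pd.DataFrame:
        proba = self.estimator.predict_proba(self._design(X, samples))
        return pd.DataFrame(proba, index=list(samples), columns=self.classes)


def _grid_fit(
    pipeline: Pipeline,
    grid: Mapping[str, list],
    X: np.ndarray,
    y: Sequence[str],
    cv_folds: int,
    seed: int,
) -> GridSearchCV:
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be nonempty")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        pipeline, dict(grid), scoring="accuracy", cv=cv, n_jobs=1, refit=True
    )
    search.fit(X, list(y))
    return search


def fit_layer(
    X: ExpressionMatrix,
    y: Mapping[str, str],
    train_samples: Sequence[str],
    grid: Optional[Mapping[str, list]] = None,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    class_weight: Optional[str] = None,
) -> LayerModel:
    """Grid-searched random forest for one omic layer.

    Features are standardized inside the CV pipeline; the best grid point by
    mean stratified-CV accuracy (first-listed wins ties) is refit on all the
    training samples.
    """
    if grid is None:
        grid = DEFAULT_RF_GRID
    labels = [y[s] for s in train_samples]
    design = X.values[list(train_samples)].to_numpy(dtype=float).T
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                RandomForestClassifier(random_state=seed, class_weight=class_weight),
            ),
        ]
    )
    search = _grid_fit(pipeline, grid, design, labels, cv_folds, seed)
    logger.info(
        "layer %s: best grid point %s (CV accuracy %.3f)",
        X.layer,
        search.best_params_,
        search.best_score_,
    )
    return LayerModel(
        layer=X.layer,
        estimator=search.best_estimator_,
        hyperparameters=dict(search.best_params_),
        classes=[str(c) for c in search.best_estimator_.classes_],
        feature_ids=X.gene_ids,
        cv_score=float(search.best_score_),
    )


def svm_baseline(
    X: ExpressionMatrix,
    y: Mapping[str, str],
    train_samples: Sequence[str],
    grid: Optional[Mapping[str, list]] = None,
    cv_folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
) -> LayerModel:
    """Margin-based comparison classifier with calibrated probabilities."""
    if grid is None:
        grid = DEFAULT_SVM_GRID
    labels = [y[s] for s in train_samples]
    design = X.values[list(train_samples)].to_numpy(dtype=float).T
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", SVC(probability=True, random_state=seed)),
        ]
    )
    search = _grid_fit(pipeline, grid, design, labels, cv_folds, seed)
    return LayerModel(
        layer=X.layer,
        estimator=search.best_estimator_,
        hyperparameters=dict(search.best_params_),
        classes=[str(c) for c in search.best_estimator_.classes_],
        feature_ids=X.gene_ids,
        cv_score=float(search.best_score_),
    )


@dataclass
class EnsembleModel:
    """Per-layer models pooled by weighted soft voting."""

    layer_models: list[LayerModel]
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.layer_models:
            raise ValueError("ensemble requires at least one layer model")
        if self.weights is None:
            self.weights = np.full(
                len(self.layer_models), 1.0 / len(self.layer_models)
            )
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.layer_models):
            raise ValueError("one weight per layer model required")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        classes = self.layer_models[0].classes
        for lm in self.layer_models[1:]:
            if lm.classes != classes:
                raise ValueError(
                    f"layer {lm.layer}: class list {lm.classes} differs "
                    f"from {classes}"
                )

    @property
    def classes(self) -> list[str]:
        return self.layer_models[0].classes

    def predict_proba(
        self, layers: Mapping[str, ExpressionMatrix], samples: Sequence[str]
    ) -> pd.DataFrame:
        missing = [lm.layer for lm in self.layer_models if lm.layer not in layers]
        if missing:
            raise ValueError(f"no data supplied for layer(s): {missing}")
        per_layer = [
            lm.predict_proba(layers[lm.layer], samples) for lm in self.layer_models
        ]
        return vote(self, per_layer)


def vote(
    ensemble: EnsembleModel, per_layer_probs: Sequence[pd.DataFrame]
) -> pd.DataFrame:
    """Weighted average of per-layer class probabilities.

    With uniform weights this is the plain arithmetic mean.  The predicted
    label is the argmax, ties broken by class order.
    """
    if len(per_layer_probs) != len(ensemble.layer_models):
        raise ValueError(
            f"expected probabilities for {len(ensemble.layer_models)} layers, "
            f"got {len(per_layer_probs)}"
        )
    classes = ensemble.classes
    pooled = None
    for w, probs in zip(ensemble.weights, per_layer_probs):
        aligned = probs[classes]
        pooled = w * aligned if pooled is None else pooled + w * aligned
    return pooled


def predict_labels(probs: pd.DataFrame) -> pd.Series:
    """Argmax class per row; ties resolve to the earlier column."""
    return probs.idxmax(axis=1)


@dataclass
class EvalReport:
    accuracy: float
    per_class: pd.DataFrame  # precision, recall, f1, support (+ zero flags)
    confusion: pd.DataFrame
    roc: dict[str, pd.DataFrame]
    auc: dict[str, float]
    classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
            "auc": self.auc,
        }


def evaluate(
    probs: pd.DataFrame, y_true: Mapping[str, str]
) -> EvalReport:
    """Metric suite from class probabilities on a held-out test set.

    Per-class precision/recall/F1 (zero-division reported as 0 and
    flagged), accuracy, confusion matrix, and one-vs-rest ROC curves with
    AUC per class.
    """
    classes = list(probs.columns)
    truth = pd.Series({s: y_true[s] for s in probs.index})
    unseen = set(truth) - set(classes)
    if unseen:
        raise ValueError(f"test set contains unseen class(es): {sorted(unseen)}")
    predicted = predict_labels(probs)
    cm = confusion_matrix(truth, predicted, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    rows = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec_zero = (tp + fp) == 0
        rec_zero = (tp + fn) == 0
        precision = 0.0 if prec_zero else tp / (tp + fp)
        recall = 0.0 if rec_zero else tp / (tp + fn)
        f1_zero = (precision + recall) == 0
        f1 = 0.0 if f1_zero else 2 * precision * recall / (precision + recall)
        rows[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": int(cm[i, :].sum()),
            "zero_division": bool(prec_zero or rec_zero or f1_zero),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    accuracy = float((predicted == truth).mean())
    roc: dict[str, pd.DataFrame] = {}
    aucs: dict[str, float] = {}
    for cls in classes:
        binary = (truth == cls).astype(int).to_numpy()
        scores = probs[cls].to_numpy()
        if binary.min() == binary.max():
            roc[cls] = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
            aucs[cls] = float("nan")
            continue
        fpr, tpr, thr = roc_curve(binary, scores)
        roc[cls] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
        aucs[cls] = float(auc(fpr, tpr))
    return EvalReport(
        accuracy=accuracy,
        per_class=per_class,
        confusion=confusion,
        roc=roc,
        auc=aucs,
        classes=classes,
    )


@dataclass
class ShapRanking:
    """Features ordered by global mean absolute attribution."""

    table: pd.DataFrame  # feature_id, mean_abs_shap, selected (desc order)
    threshold: float
    base_value: np.ndarray

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "feature_id"].tolist()

    def to_tsv(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False, lineterminator="\n")


def shap_rank(
    model: LayerModel,
    X: ExpressionMatrix,
    samples: Sequence[str],
    threshold: float = DEFAULT_SHAP_THRESHOLD,
) -> ShapRanking:
    """Mean |SHAP| per feature over evaluation rows (and classes).

    Attribution runs on the forest behind the scaling step, with the scaler
    applied to the evaluation rows first.  Only tree ensembles support the
    exact path-dependent attribution; the SVM baseline does not.
    """
    if not list(samples):
        raise ValueError("shap_rank requires a nonempty evaluation set")
    clf = model.estimator.named_steps["clf"]
    if not isinstance(clf, RandomForestClassifier):
        raise TypeError(
            f"shap_rank supports tree ensembles, got {type(clf).__name__}"
        )
    design = model._design(X, samples)
    scaled = model.estimator.named_steps["scale"].transform(design)
    phi, base = forest_shap_values(clf, scaled)
    mean_abs = np.abs(phi).mean(axis=(0, 2))
    table = pd.DataFrame(
        {
            "feature_id": model.feature_ids,
            "mean_abs_shap": mean_abs,
        }
    )
    table["selected"] = table["mean_abs_shap"] > threshold
    table = table.sort_values(
        ["mean_abs_shap", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return ShapRanking(table=table, threshold=threshold, base_value=base)
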