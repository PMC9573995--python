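"""Classifier backends and the four-classifier hierarchy.

The hierarchy predicts the relationship degree first (unrelated / 1st / 2nd /
3rd; one classifier over all pairs) and then the relationship type within the
predicted degree (one classifier per degree, trained only on pairs of that
degree).  Pairs predicted unrelated receive type "unrelated" without invoking
a type model.

Two backends are supported: a random forest consuming raw features, and an
RBF-kernel SVM whose features are z-scored inside the fold pipeline so the
scaling statistics never leak from validation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .simulate import TYPES_BY_DEGREE

TASKS = ("degree", "deg1", "deg2", "deg3")


def task_xy(table: pd.DataFrame, task: str) -> tuple[pd.DataFrame, np.ndarray]:
    """(X, y) for one classification task from an extracted feature table.

    ``degree`` uses all pairs with the degree as label; ``deg1``/``deg2``/
    ``deg3`` restrict to pairs of that true degree with the type as label.
    """
    if task == "degree":
        return table[list(FEATURE_NAMES)], table["degree"].to_numpy()
    if task in ("deg1", "deg2", "deg3"):
        d = int(task[-1])
        sub = table[table["degree"] == d]
        return sub[list(FEATURE_NAMES)], sub["type"].to_numpy()
    raise ValueError(f"unknown task {task!r}")


@dataclass(frozen=True)
class RandomForestBackend:
    """Random forest; consumes raw (unscaled) features."""

    n_estimators: int = 300
    max_features: str | float = "sqrt"
    seed: int = 0

    id = "rf"

    def make(self):
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )

    def with_seed(self, seed: int) -> "RandomForestBackend":
        return RandomForestBackend(self.n_estimators, self.max_features, seed)


@dataclass(frozen=True)
class SVMBackend:
    """RBF-kernel SVM with per-fit feature standardization in a pipeline."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    seed: int = 0

    id = "svm"

    def make(self):
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(C=self.C, kernel=self.kernel, gamma=self.gamma, random_state=self.seed)),
            ]
        )

    def with_seed(self, seed: int) -> "SVMBackend":
        return SVMBackend(self.C, self.kernel, self.gamma, seed)


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------


class TrainingError(ValueError):
    """Training data do not cover the required classes."""


@dataclass
class TrainedHierarchy:
    """One degree classifier plus three within-degree type classifiers."""

    degree_model: object
    degree_features: list[str]
    type_models: dict[int, tuple[object, list[str]]]
    ger_train: float = 0.0


def train_hierarchy(
    table: pd.DataFrame,
    feature_sets: dict[str, list[str]],
    backend,
    seed: int = 0,
) -> TrainedHierarchy:
    """Fit the four classifiers on an extracted feature table.

    ``feature_sets`` maps task names ("degree", "deg1", "deg2", "deg3") to
    the feature subsets each classifier uses.
    """
    for task in TASKS:
        if not feature_sets.get(task):
            raise TrainingError(f"empty feature set for task {task!r}")
    X, y = task_xy(table, "degree")
    if set(y) != {0, 1, 2, 3}:
        raise TrainingError("training data must contain all four degree classes")
    degree_model = backend.with_seed(seed).make()
    degree_model.fit(X[feature_sets["degree"]].to_numpy(), y)
    type_models: dict[int, tuple[object, list[str]]] = {}
    for d in (1, 2, 3):
        Xd, yd = task_xy(table, f"deg{d}")
        if set(yd) != set(TYPES_BY_DEGREE[d]):
            raise TrainingError(f"degree-{d} training data missing a relationship type")
        feats = feature_sets[f"deg{d}"]
        model = backend.with_seed(seed + d).make()
        model.fit(Xd[feats].to_numpy(), yd)
        type_models[d] = (model, list(feats))
    return TrainedHierarchy(
        degree_model=degree_model,
        degree_features=list(feature_sets["degree"]),
        type_models=type_models,
        ger_train=float(table["ger"].iloc[0]) if len(table) else 0.0,
    )


def predict_hierarchy(model: TrainedHierarchy, table: pd.DataFrame) -> pd.DataFrame:
    """Predict (degree, type) for every row of a feature table.

    The degree is predicted first; pairs predicted unrelated are typed
    "unrelated" directly, all others are routed to the matching type model.
    """
    degree = model.degree_model.predict(table[model.degree_features].to_numpy())
    pred_type = np.full(len(table), "unrelated", dtype=object)
    for d, (type_model, feats) in model.type_models.items():
        sel = degree == d
        if np.any(sel):
            pred_type[sel] = type_model.predict(table.loc[sel, feats].to_numpy())
    out = pd.DataFrame(
        {"pred_degree": degree.astype(int), "pred_type": pred_type}, index=table.index
    )
    if "pair_id" in table:
        out.insert(0, "pair_id", table["pair_id"])
    return out


@dataclass
class ConfusionResult:
    accuracy: float
    table: pd.DataFrame  # rows = truth, columns = prediction
    per_class_accuracy: pd.Series = field(default=None)  # type: ignore[assignment]


def evaluate_confusion(predictions, truth) -> ConfusionResult:
    """Overall accuracy, confusion matrix and per-class accuracy.

    Rows of the confusion table sum to the true class counts.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    labels = sorted(set(truth) | set(predictions), key=str)
    table = pd.crosstab(
        pd.Categorical(truth, categories=labels),
        pd.Categorical(predictions, categories=labels),
        dropna=False,
    )
    table.index.name = "truth"
    table.columns.name = "predicted"
    accuracy = float(np.mean(predictions == truth))
    diag = pd.Series(np.diag(table.to_numpy()), index=table.index, dtype=float)
    with np.errstate(invalid="ignore"):
        per_class = diag / table.sum(axis=1).replace(0, np.nan)
    return ConfusionResult(accuracy=accuracy, table=table, per_class_accuracy=per_class)


def compare_backends(
    tables_by_ger: dict[float, pd.DataFrame],
    tasks=TASKS,
    backends=None,
    k_folds: int = 10,
    max_steps: int = 17,
    seed: int = 0,
) -> dict[tuple[str, str, float], "SelectionTrace"]:  # noqa: F821
    """Forward-selection accuracy curves for each backend, task and GER.

    Reproduces the backend-comparison design: every (backend, task, GER)
    combination gets a full greedy forward-selection trace whose accuracy
    curve can be compared across backends.
    """
    from .selection import forward_select  # local import to avoid a cycle

    if backends is None:
        backends = (RandomForestBackend(), SVMBackend())
    traces = {}
    for backend in backends:
        for task in tasks:
            for ger, table in tables_by_ger.items():
                X, y = task_xy(table, task)
                trace = forward_select(
                    X, y, backend, k_folds=k_folds, max_steps=max_steps, seed=seed
                )
                trace.ger = ger
                traces[(backend.id, task, ger)] = trace
    return traces
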