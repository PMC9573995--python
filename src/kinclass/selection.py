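"""Greedy forward feature selection with cross-validation and consensus.

Per genotyping-error rate (GER), a greedy wrapper adds at every step the
feature whose addition maximizes stratified k-fold cross-validated accuracy;
the same folds are reused for every candidate within a run so comparisons are
paired.  The per-GER selected sets (each GER's accuracy-maximizing prefix)
are then counted across GERs, features are ranked by how many GER-specific
sets contain them, and the final feature set is the count-ordered prefix that
maximizes mean accuracy across all GERs — a single set that trades a little
per-GER accuracy for robustness when the true error rate is unknown.

Ties are always broken toward the canonical feature order (the fixed
17-feature order), making every stage deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X), columns=[f"f{i}" for i in range(np.asarray(X).shape[1])])


def _make_folds(y: np.ndarray, k_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} samples; "
            f"stratified {k_folds}-fold CV needs at least {k_folds} per class"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _cv_accuracy_folds(X: np.ndarray, y: np.ndarray, folds, backend, seed: int) -> float:
    accs = []
    for train, test in folds:
        model = backend.with_seed(seed).make()
        model.fit(X[train], y[train])
        accs.append(accuracy_score(y[test], model.predict(X[test])))
    return float(np.mean(accs))


def cv_accuracy(
    X,
    y,
    feature_subset: list[str],
    backend,
    k_folds: int = 10,
    seed: int = 0,
) -> float:
    """Stratified k-fold mean accuracy of ``backend`` on a feature subset.

    Folds are fixed by ``seed`` and the classifier is retrained per fold.
    """
    if not feature_subset:
        raise ValueError("feature subset must be nonempty")
    X = _as_frame(X)
    y = np.asarray(y)
    folds = _make_folds(y, k_folds, seed)
    return _cv_accuracy_folds(X[list(feature_subset)].to_numpy(), y, folds, backend, seed)


@dataclass
class SelectionTrace:
    """One greedy forward-selection run: order of addition and CV accuracies."""

    features: list[str]
    accuracies: list[float]
    backend_id: str
    ger: float | None = None

    def best_prefix(self, cap: int | None = None) -> list[str]:
        """The accuracy-maximizing prefix (earliest on ties), optionally capped."""
        acc = self.accuracies if cap is None else self.accuracies[:cap]
        best = int(np.argmax(acc))  # argmax takes the first maximum
        return self.features[: best + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "cv_accuracy": self.accuracies,
            }
        )


def forward_select(
    X,
    y,
    backend,
    k_folds: int = 10,
    max_steps: int = 17,
    seed: int = 0,
) -> SelectionTrace:
    """Greedy forward selection driven by cross-validated accuracy.

    At each step every unselected feature is evaluated appended to the current
    set and the argmax is kept (ties to the lower canonical column index).
    Runs to ``max_steps`` so the full rising/plateau/falling accuracy curve is
    recorded even past the peak.
    """
    X = _as_frame(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("forward selection needs at least two classes")
    folds = _make_folds(y, k_folds, seed)
    columns = list(X.columns)
    Xv = X.to_numpy()
    selected_idx: list[int] = []
    accuracies: list[float] = []
    remaining = list(range(len(columns)))
    for _ in range(min(max_steps, len(columns))):
        best_acc, best_j = -np.inf, None
        for j in remaining:  # canonical order; strict > keeps the first tie
            acc = _cv_accuracy_folds(Xv[:, selected_idx + [j]], y, folds, backend, seed)
            if acc > best_acc:
                best_acc, best_j = acc, j
        selected_idx.append(best_j)
        remaining.remove(best_j)
        accuracies.append(best_acc)
    return SelectionTrace(
        features=[columns[j] for j in selected_idx],
        accuracies=accuracies,
        backend_id=backend.id,
    )


@dataclass
class ConsensusRanking:
    """Cross-GER feature counts and the count-ordered ranking."""

    counts: dict[str, int]
    ranking: list[str] = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.ranking,
                "count": [self.counts.get(f, 0) for f in self.ranking],
                "rank": np.arange(1, len(self.ranking) + 1),
            }
        )


def consensus_rank(
    traces: list[SelectionTrace],
    set_sizes: list[int] | None = None,
    all_features: list[str] | None = None,
) -> ConsensusRanking:
    """Count how many per-GER selected sets contain each feature and rank.

    Each trace contributes its accuracy-maximizing prefix unless explicit
    ``set_sizes`` are given.  Ranking is by descending count, then mean
    position within the traces that selected the feature, then canonical
    feature order.
    """
    if not traces:
        raise ValueError("at least one selection trace required")
    if set_sizes is None:
        sets = [t.best_prefix() for t in traces]
    else:
        if len(set_sizes) != len(traces):
            raise ValueError("set_sizes must match the number of traces")
        sets = [t.features[:s] for t, s in zip(traces, set_sizes)]
    if all_features is None:
        seen = {f for t in traces for f in t.features}
        all_features = [f for f in FEATURE_NAMES if f in seen] or sorted(seen)
        for t in traces:  # preserve any non-canonical feature names
            for f in t.features:
                if f not in all_features:
                    all_features.append(f)
    counts = {f: sum(f in s for s in sets) for f in all_features}
    mean_pos = {}
    for f in all_features:
        pos = [s.index(f) for s in sets if f in s]
        mean_pos[f] = float(np.mean(pos)) if pos else np.inf
    canonical = {f: i for i, f in enumerate(all_features)}
    ranking = sorted(all_features, key=lambda f: (-counts[f], mean_pos[f], canonical[f]))
    return ConsensusRanking(counts=counts, ranking=ranking)


def choose_final_set(
    ranking: ConsensusRanking,
    X_by_ger: dict[float, pd.DataFrame],
    y_by_ger: dict[float, np.ndarray],
    backend,
    k_folds: int = 10,
    seed: int = 0,
    max_k: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Pick the count-ordered prefix maximizing mean CV accuracy across GERs.

    Returns the chosen feature list and the accuracy-by-k curve per GER
    (long-format DataFrame with columns ger, k, cv_accuracy).  Ties go to the
    smaller prefix.
    """
    if not ranking.ranking:
        raise ValueError("empty consensus ranking")
    ks = range(1, (max_k or len(ranking.ranking)) + 1)
    rows = []
    means = []
    for k in ks:
        subset = ranking.ranking[:k]
        accs = {}
        for ger, X in X_by_ger.items():
            accs[ger] = cv_accuracy(X, y_by_ger[ger], subset, backend, k_folds, seed)
            rows.append({"ger": ger, "k": k, "cv_accuracy": accs[ger]})
        means.append(float(np.mean(list(accs.values()))))
    best_k = int(np.argmax(means)) + 1  # first maximum -> smallest k on ties
    return ranking.ranking[:best_k], pd.DataFrame(rows)
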