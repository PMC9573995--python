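"""Forward selection, cross-validation and consensus ranking tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedKFold

import kinclass as kc
from kinclass import selection as sel
from kinclass.hierarchy import RandomForestBackend


class ConstantBackend:
    """Always predicts the most frequent training class."""

    id = "const"

    def make(self):
        return DummyClassifier(strategy="most_frequent")

    def with_seed(self, seed):
        return self


def toy_table(rng, n=120, informative=True):
    y = np.repeat([0, 1, 2, 3], n // 4)
    X = pd.DataFrame(
        {
            "signal": y + (0.05 * rng.normal(size=n) if informative else rng.normal(size=n)),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "noise3": rng.normal(size=n),
            "noise4": rng.normal(size=n),
        }
    )
    return X, y


class TestCvAccuracy:
    def test_constant_predictor_on_balanced_classes(self, rng):
        X, y = toy_table(rng)
        # 3 folds of 40 keep every fold exactly balanced (10 per class)
        acc = kc.cv_accuracy(X, y, ["noise1"], ConstantBackend(), k_folds=3, seed=0)
        assert acc == pytest.approx(0.25)

    def test_label_derived_feature_is_perfect(self, rng):
        X, y = toy_table(rng)
        backend = RandomForestBackend(n_estimators=20)
        assert kc.cv_accuracy(X, y, ["signal"], backend, k_folds=4, seed=0) == 1.0

    def test_matches_manual_fold_computation(self, rng):
        """Two-fold accuracy equals an independent per-fold recomputation."""
        X, y = toy_table(rng, n=40)
        backend = RandomForestBackend(n_estimators=15)
        got = kc.cv_accuracy(X, y, ["signal", "noise1"], backend, k_folds=2, seed=7)
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=7)
        Xv = X[["signal", "noise1"]].to_numpy()
        accs = []
        for train, test in skf.split(Xv, y):
            model = backend.with_seed(7).make().fit(Xv[train], y[train])
            accs.append(accuracy_score(y[test], model.predict(Xv[test])))
        assert got == pytest.approx(np.mean(accs))

    def test_small_class_raises(self, rng):
        X, y = toy_table(rng, n=12)
        with pytest.raises(ValueError, match="stratified"):
            kc.cv_accuracy(X, y, ["signal"], ConstantBackend(), k_folds=10, seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            kc.cv_accuracy(X, y, [], ConstantBackend(), k_folds=2, seed=0)


class TestForwardSelect:
    def test_label_feature_selected_first(self, rng):
        X, y = toy_table(rng)
        backend = RandomForestBackend(n_estimators=20)
        trace = kc.forward_select(X, y, backend, k_folds=4, max_steps=3, seed=0)
        assert trace.features[0] == "signal"
        assert trace.accuracies[0] == 1.0

    def test_greedy_matches_exhaustive_search(self, rng):
        """Step 1 and step 2 equal exhaustive subset search at sizes 1 and 2."""
        n = 160
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {
                "a": y * 0.8 + rng.normal(size=n),
                "b": y * 0.5 + rng.normal(size=n),
                "c": rng.normal(size=n),
                "d": y * 0.3 + rng.normal(size=n),
            }
        )
        backend = RandomForestBackend(n_estimators=30)
        trace = kc.forward_select(X, y, backend, k_folds=4, max_steps=2, seed=3)
        singles = {
            f: kc.cv_accuracy(X, y, [f], backend, k_folds=4, seed=3) for f in X.columns
        }
        best_single = max(singles, key=lambda f: (singles[f], -list(X.columns).index(f)))
        assert trace.features[0] == best_single
        assert trace.accuracies[0] == pytest.approx(singles[best_single])
        pairs = {
            f: kc.cv_accuracy(X, y, [best_single, f], backend, k_folds=4, seed=3)
            for f in X.columns
            if f != best_single
        }
        best_pair = max(pairs, key=lambda f: (pairs[f], -list(X.columns).index(f)))
        assert trace.features[1] == best_pair

    def test_tie_broken_to_lower_canonical_index(self, rng):
        X, y = toy_table(rng)
        X = X[["noise1", "signal"]].copy()
        X["dup"] = X["signal"]
        backend = RandomForestBackend(n_estimators=15)
        trace = kc.forward_select(X, y, backend, k_folds=4, max_steps=1, seed=0)
        assert trace.features[0] == "signal"  # column before its duplicate

    def test_greedy_optimality_reevaluation(self, rng):
        """Each selected feature attains the max paired-fold accuracy."""
        X, y = toy_table(rng)
        backend = RandomForestBackend(n_estimators=15)
        trace = kc.forward_select(X, y, backend, k_folds=4, max_steps=2, seed=5)
        chosen = trace.features[0]
        for f in X.columns:
            acc = kc.cv_accuracy(X, y, [f], backend, k_folds=4, seed=5)
            assert acc <= trace.accuracies[0] + 1e-12
            if f == chosen:
                assert acc == pytest.approx(trace.accuracies[0])

    def test_identical_seed_identical_trace(self, rng):
        X, y = toy_table(rng)
        backend = RandomForestBackend(n_estimators=15)
        a = kc.forward_select(X, y, backend, k_folds=4, max_steps=3, seed=1)
        b = kc.forward_select(X, y, backend, k_folds=4, max_steps=3, seed=1)
        assert a.features == b.features and a.accuracies == b.accuracies


def _trace(features, accuracies, ger=0.0):
    return sel.SelectionTrace(
        features=list(features), accuracies=list(accuracies), backend_id="rf", ger=ger
    )


class TestConsensus:
    def test_unanimous_sets_counted_six_times(self):
        feats = ["K1", "j4", "j7", "K0", "IBS0", "j6", "j8"]
        accs = [0.9, 0.95, 0.99, 1.0, 1.0, 1.0, 1.0]
        traces = [_trace(feats + ["j2"], accs + [0.9], ger=g) for g in kc.GER_GRID]
        ranking = kc.consensus_rank(traces, set_sizes=[7] * 6)
        assert all(ranking.counts[f] == 6 for f in feats)
        assert ranking.counts["j2"] == 0
        assert sum(ranking.counts.values()) == 42

    def test_single_trace_ranking_is_selection_order(self):
        t = _trace(["K1", "IBS0", "j4"], [0.8, 0.9, 0.85])
        ranking = kc.consensus_rank([t])  # best prefix = first two
        assert ranking.ranking[:2] == ["K1", "IBS0"]
        assert ranking.counts == {"K1": 1, "IBS0": 1, "j4": 0}

    def test_rank_by_count_then_mean_position(self):
        traces = [
            _trace(["a", "b", "c"], [0.5, 0.9, 0.8]),
            _trace(["b", "c", "a"], [0.5, 0.9, 0.8]),
        ]
        ranking = kc.consensus_rank(traces)  # prefixes: [a,b], [b,c]
        assert ranking.counts == {"a": 1, "b": 2, "c": 1}
        assert ranking.ranking[0] == "b"
        # a mean pos 0 beats c mean pos 1
        assert ranking.ranking[1:] == ["a", "c"]

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            kc.consensus_rank([])


class TestChooseFinalSet:
    def _run(self, monkeypatch, curve):
        ranking = sel.ConsensusRanking(
            counts={f: 1 for f in "abcde"}, ranking=list("abcde")
        )
        calls = {}

        def fake_cv(X, y, subset, backend, k_folds=10, seed=0):
            calls[len(subset)] = True
            return curve[len(subset) - 1]

        monkeypatch.setattr(sel, "cv_accuracy", fake_cv)
        X = pd.DataFrame(np.zeros((4, 5)), columns=list("abcde"))
        y = np.array([0, 0, 1, 1])
        final, curves = kc.choose_final_set(
            ranking, {0.0: X, 0.1: X}, {0.0: y, 0.1: y}, ConstantBackend()
        )
        return final, curves

    def test_flat_curve_returns_smallest_prefix(self, monkeypatch):
        final, _ = self._run(monkeypatch, [0.7] * 5)
        assert final == ["a"]

    def test_interior_maximum_returned(self, monkeypatch):
        final, curves = self._run(monkeypatch, [0.6, 0.8, 0.9, 0.85, 0.7])
        assert final == ["a", "b", "c"]
        assert set(curves["k"]) == set(range(1, 6))
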