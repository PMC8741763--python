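import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

import ctag
from ctag.io import ValidationError
from ctag.training import (
    GridPoint,
    HyperParamGrid,
    _select_from_trace,
    inner_grid_search,
    rank_features,
    select_stable_hyperparameters,
    train_ensemble,
    unconstrained_baseline,
)


@pytest.fixture(scope="module")
def separable_xy():
    rng = np.random.default_rng(0)
    n = 60
    X = rng.normal(size=(2 * n, 37))
    X[:n, 0] += 2.5  # one strongly informative feature
    y = np.array(["TSG"] * n + ["OG"] * n)
    return X, y


def point(n=5, mf="sqrt", d=2, c="gini"):
    return GridPoint(n, mf, d, c)


class TestHyperParamGrid:
    def test_default_ranges(self):
        g = HyperParamGrid()
        assert g.n_estimators == (5, 10, 15, 20, 25, 30, 35, 40)
        assert set(g.max_features) == {"sqrt", "log2"}
        assert g.max_depth == (2, 3, 4)
        assert set(g.criterion) == {"gini", "entropy"}
        assert len(list(g.points())) == 96

    def test_empty_axis_rejected(self):
        with pytest.raises(ValidationError):
            HyperParamGrid(n_estimators=())


class TestInnerGridSearch:
    def test_singleton_grid_returns_that_point(self, separable_xy):
        X, y = separable_xy
        g = HyperParamGrid((10,), ("sqrt",), (3,), ("gini",))
        p, acc = inner_grid_search(X, y, g, seed=4)
        assert p == GridPoint(10, "sqrt", 3, "gini")
        assert 0.0 <= acc <= 1.0

    def test_deterministic_given_seed(self, separable_xy):
        X, y = separable_xy
        g = HyperParamGrid((5, 10), ("sqrt",), (2, 3), ("gini",))
        assert inner_grid_search(X, y, g, seed=7) == inner_grid_search(X, y, g, seed=7)

    def test_matches_naive_per_point_forest_fits(self, separable_xy):
        """The incremental evaluation must agree exactly with fitting a fresh
        RandomForestClassifier per grid point under the same CV split."""
        X, y = separable_xy
        g = HyperParamGrid((5, 10, 20), ("sqrt", "log2"), (2, 3), ("gini",))
        seed = 11
        best, best_acc = inner_grid_search(X, y, g, seed=seed)
        skf = StratifiedKFold(5, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        ref_best, ref_acc = None, -1.0
        for n, mf, d, c in g.points():
            accs = []
            for tr, te in splits:
                clf = RandomForestClassifier(
                    n_estimators=n, max_features=mf, max_depth=d, criterion=c,
                    random_state=seed,
                ).fit(X[tr], y[tr])
                accs.append((clf.predict(X[te]) == y[te]).mean())
            acc = float(np.mean(accs))
            if acc > ref_acc:
                ref_best, ref_acc = (n, mf, d, c), acc
        assert (best.n_estimators, best.max_features, best.max_depth,
                best.criterion) == ref_best
        assert best_acc == pytest.approx(ref_acc, abs=1e-12)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValidationError):
            inner_grid_search(X, np.array(["TSG"] * 10))


class TestSelectFromTrace:
    def test_modal_tree_count_wins(self):
        trace = (
            [(point(n=10), 0.7)] * 6 + [(point(n=20), 0.9)] * 3 + [(point(n=40), 0.95)]
        )
        assert _select_from_trace(trace).n_estimators == 10

    def test_count_tie_broken_by_accuracy(self):
        trace = [(point(n=10), 0.80)] * 5 + [(point(n=20), 0.83)] * 5
        assert _select_from_trace(trace).n_estimators == 20

    def test_accuracy_tie_broken_by_smaller_tree_count(self):
        trace = [(point(n=20), 0.8)] * 5 + [(point(n=10), 0.8)] * 5
        assert _select_from_trace(trace).n_estimators == 10

    def test_best_point_among_modal_runs(self):
        trace = [
            (point(n=10, d=2), 0.70),
            (point(n=10, d=4), 0.90),
            (point(n=10, d=3), 0.80),
            (point(n=20, d=2), 0.99),
        ]
        sel = _select_from_trace(trace)
        assert sel.n_estimators == 10 and sel.max_depth == 4

    def test_single_seed_degenerate(self):
        sel = _select_from_trace([(point(n=15, d=3), 0.6)])
        assert sel.as_kwargs()["n_estimators"] == 15 and sel.max_depth == 3

    def test_trace_is_recorded(self, separable_xy):
        X, y = separable_xy
        g = HyperParamGrid((5, 10), ("sqrt",), (2,), ("gini",))
        sel = select_stable_hyperparameters(X, y, g, seeds=[1, 2, 3])
        assert len(sel.trace) == 3


class TestTrainEnsemble:
    def test_five_fold_models_and_shared_feature_order(self, small_ensemble):
        assert len(small_ensemble.fold_models) == 5
        assert small_ensemble.feature_names == list(ctag.FEATURE_NAMES)

    def test_determinism_given_master_seed(self, small_bundle, small_matrix):
        g = HyperParamGrid((5, 10), ("sqrt",), (2, 3), ("gini",))
        labels = small_bundle.label_set()
        e1 = train_ensemble(small_matrix, labels, g, n_seeds=2, master_seed=3)
        e2 = train_ensemble(small_matrix, labels, g, n_seeds=2, master_seed=3)
        assert e1.metric_summary().equals(e2.metric_summary())
        for a, b in zip(e1.fold_models, e2.fold_models):
            assert a.params.as_kwargs() == b.params.as_kwargs()
            assert a.test_genes == b.test_genes
            assert a.importance_ranks.equals(b.importance_ranks)

    def test_fold_metrics_satisfy_identities(self, small_ensemble):
        for fm in small_ensemble.fold_models:
            for m in fm.test_metrics.values():
                total = m.tp + m.fp + m.tn + m.fn
                assert m.accuracy == pytest.approx((m.tp + m.tn) / total)
                if m.precision + m.recall > 0:
                    assert m.f1 == pytest.approx(
                        2 * m.precision * m.recall / (m.precision + m.recall)
                    )

    def test_unlabelled_matrix_rejected(self, small_matrix):
        empty = ctag.LabelSet(pd.Series({"NOPE": "TSG", "NOPE2": "OG"}))
        with pytest.raises(ValidationError):
            train_ensemble(small_matrix, empty)


class TestRankFeatures:
    def test_average_of_per_fold_ranks(self, small_ensemble):
        ranked = rank_features(small_ensemble)
        assert set(ranked["feature"]) == set(ctag.FEATURE_NAMES)
        assert ranked["average_rank"].is_monotonic_increasing
        manual = (
            pd.concat([fm.importance_ranks for fm in small_ensemble.fold_models], axis=1)
            .mean(axis=1)
        )
        merged = ranked.set_index("feature")["average_rank"]
        assert np.allclose(merged.sort_index(), manual.sort_index())

    def test_planted_lof_signal_ranks_high(self, small_ensemble):
        top5 = list(rank_features(small_ensemble)["feature"][:5])
        assert any("LOF" in f or "Nonsense" in f or "Frameshift" in f for f in top5)


class TestUnconstrainedBaseline:
    def test_overfits_more_than_stability_ensemble(self, small_bundle, small_matrix,
                                                   small_ensemble):
        base = unconstrained_baseline(small_matrix, small_bundle.label_set(),
                                      small_ensemble)
        assert base["train_accuracy"] == 1.0  # memorises the training split
        assert base["accuracy_gap"] >= 0.0
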