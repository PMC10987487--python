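import numpy as np
import pytest

import netchrono as nc
from netchrono.ordermodel import (Comparator, LabeledPairs,
                                  best_feature_outputs, simplex_grid)


def _pairs_from_arrays(i, j, y):
    return LabeledPairs(np.asarray(i), np.asarray(j), np.asarray(y))


class TestMakeTrainingPairs:
    def test_snapshot_enumeration(self):
        net = nc.TemporalNetwork([(0, 1), (1, 2), (2, 3)], snapshots=[1, 1, 2])
        pairs = nc.make_training_pairs(net, fraction=1.0, seed=0)
        got = {tuple(sorted(p)) for p in zip(pairs.i.tolist(), pairs.j.tolist())}
        assert got == {(0, 2), (1, 2)}

    def test_fraction_count_arithmetic(self):
        net = nc.TemporalNetwork([(i, i + 1) for i in range(1000)])
        pairs = nc.make_training_pairs(net, fraction=0.05, seed=0)
        assert len(pairs) == int(0.05 * 1000 * 999 / 2)

    def test_single_snapshot_rejected(self):
        net = nc.TemporalNetwork([(0, 1), (1, 2)], snapshots=[1, 1])
        with pytest.raises(ValueError):
            nc.make_training_pairs(net, fraction=1.0, seed=0)

    def test_labels_match_arrival_order(self):
        net = nc.TemporalNetwork([(i, i + 1) for i in range(30)])
        pairs = nc.make_training_pairs(net, fraction=0.5, seed=1)
        assert np.array_equal(pairs.y, (pairs.i > pairs.j).astype(int))
        # roughly class-balanced by random orientation
        assert 0.3 < pairs.y.mean() < 0.7


class TestComparator:
    def test_learns_linear_threshold(self):
        rng = np.random.default_rng(0)
        vecs = rng.normal(size=(200, 8))
        score = vecs[:, 3]
        i = rng.integers(0, 200, size=500)
        j = rng.integers(0, 200, size=500)
        keep = i != j
        i, j = i[keep], j[keep]
        y = (score[i] > score[j]).astype(int)
        pairs = _pairs_from_arrays(i, j, y)
        comp = Comparator(seed=1, epochs=250, noise=0.0).fit(vecs, pairs)
        ti = rng.integers(0, 200, size=400)
        tj = rng.integers(0, 200, size=400)
        keep = ti != tj
        ti, tj = ti[keep], tj[keep]
        ty = (score[ti] > score[tj]).astype(int)
        o = comp.predict_proba(vecs, ti, tj)
        acc = np.mean((o > 0.5) == ty)
        assert acc > 0.95

    def test_antisymmetry_by_construction(self):
        rng = np.random.default_rng(2)
        vecs = rng.normal(size=(50, 4))
        pairs = _pairs_from_arrays([0, 1, 2, 3], [1, 2, 3, 4], [0, 1, 0, 1])
        comp = Comparator(seed=0, epochs=5).fit(vecs, pairs)
        i = np.arange(10)
        j = np.arange(10, 20)
        assert np.allclose(comp.predict_proba(vecs, i, j)
                           + comp.predict_proba(vecs, j, i), 1.0)
        assert np.allclose(comp.predict_proba(vecs, i, i), 0.5)

    def test_degenerate_labels_rejected(self):
        vecs = np.random.default_rng(0).normal(size=(10, 4))
        pairs = _pairs_from_arrays([0, 1], [2, 3], [1, 1])
        with pytest.raises(ValueError, match="one class"):
            Comparator(seed=0).fit(vecs, pairs)


class TestBestFeature:
    def test_planted_perfect_feature(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(100, 11))
        order = np.argsort(np.argsort(raw[:, 3]))  # feature 3 = age rank
        i = rng.integers(0, 100, 300)
        j = rng.integers(0, 100, 300)
        keep = raw[i, 3] != raw[j, 3]
        i, j = i[keep], j[keep]
        y = (order[i] > order[j]).astype(int)
        best, acc = nc.select_best_feature(raw, _pairs_from_arrays(i, j, y))
        assert best == 3
        assert acc == 1.0

    def test_random_features_tie_to_lowest_index(self):
        winners = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.normal(size=(60, 4))
            i = rng.integers(0, 60, 200)
            j = rng.integers(0, 60, 200)
            keep = i != j
            y = rng.integers(0, 2, keep.sum())
            best, acc = nc.select_best_feature(raw, _pairs_from_arrays(i[keep], j[keep], y))
            winners.append(best)
            assert abs(acc - 0.5) < 0.15
        assert min(winners) == 0 or len(set(winners)) > 1

    def test_equal_values_count_as_not_newer(self):
        vals = np.array([2.0, 2.0])
        out = best_feature_outputs(vals, np.array([0]), np.array([1]))
        assert out[0] == 0.0


class TestEnsembleWeights:
    def test_grid_points_on_simplex(self):
        grid = simplex_grid(7, 10)
        assert np.allclose(grid.sum(axis=1), 1.0)
        assert np.all(grid >= 0)

    def test_perfect_component_dominates(self):
        rng = np.random.default_rng(3)
        n = 400
        y = rng.integers(0, 2, n)
        outputs = rng.random((n, 7))
        outputs[:, 2] = np.where(y == 1, 0.9, 0.1)  # planted perfect component
        w = nc.fit_ensemble_weights(outputs, y)
        # the perfect component carries the single largest weight and the
        # selected point matches the best vertex (perfect accuracy)
        assert w[2] == w.max() and w[2] >= 0.5
        o = outputs @ w
        assert np.mean(((o > 0.5) & (y == 1)) | ((o < 0.5) & (y == 0))) == 1.0

    def test_identical_components_lexicographic_tiebreak(self):
        n = 100
        y = np.random.default_rng(0).integers(0, 2, n)
        col = np.where(y == 1, 0.8, 0.2)
        outputs = np.tile(col[:, None], (1, 7))
        w = nc.fit_ensemble_weights(outputs, y)
        w2 = nc.fit_ensemble_weights(outputs, y)
        assert np.array_equal(w, w2)
        assert w.sum() == pytest.approx(1.0)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError):
            nc.fit_ensemble_weights(np.empty((0, 7)), np.empty(0))


@pytest.fixture(scope="module")
def trained(ba_small):
    views = nc.build_edge_views(ba_small, dim=16, seed=0)
    model = nc.fit_order_model(ba_small, views, train_fraction=0.3, seed=0,
                               comparator_kwargs={"epochs": 15})
    return ba_small, views, model


class TestEnsemblePredict:

    def test_degenerate_weights_equal_single_component(self, trained):
        net, views, model = trained
        w = model.weights.copy()
        model.weights = np.array([1, 0, 0, 0, 0, 0, 0.0])
        i, j = np.array([0, 5]), np.array([3, 9])
        o = model.predict(views, i, j)
        o1 = model.comparators[0].predict_proba(views.views[0], i, j)
        assert np.allclose(o, o1)
        model.weights = w

    def test_convexity_fixed_point(self):
        outputs = np.full((1, 7), 0.9)
        for w in (np.ones(7) / 7, np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05])):
            assert outputs @ w == pytest.approx(0.9)

    def test_uniform_weights_arithmetic(self):
        outputs = np.array([[1, 1, 1, 1, 1, 1, 0.0]])
        assert outputs @ (np.ones(7) / 7) == pytest.approx(6 / 7)

    def test_pairwise_accuracy_bounds(self, trained):
        net, views, model = trained
        test = nc.sample_test_pairs(net, 500, seed=9,
                                    exclude=model.training_pairs.pair_ids)
        x = nc.pairwise_accuracy(model, views, test)
        assert 0.0 <= x <= 1.0
        with pytest.raises(ValueError):
            nc.pairwise_accuracy(model, views, LabeledPairs(
                np.empty(0, int), np.empty(0, int), np.empty(0, int)))

    def test_ensemble_not_much_worse_than_best_component(self, trained):
        # the weight grid contains the simplex vertices
        net, views, model = trained
        assert model.component_val_acc is not None
        test = nc.sample_test_pairs(net, 800, seed=4,
                                    exclude=model.training_pairs.pair_ids)
        outputs = model.component_outputs(views, test.i, test.j)
        ens = nc.pairwise_accuracy(model, views, test)
        singles = [np.mean(((outputs[:, k] > 0.5) & (test.y == 1))
                           | ((outputs[:, k] < 0.5) & (test.y == 0)))
                   for k in range(7)]
        assert ens >= max(singles) - 0.05


class TestRestoreNetwork:
    def test_borda_decisions_consistent(self, ba_small):
        views = nc.build_edge_views(ba_small, dim=16, seed=0)
        model = nc.fit_order_model(ba_small, views, train_fraction=0.3, seed=0,
                                   comparator_kwargs={"epochs": 10})
        seq = nc.restore_network(model, views)
        e = ba_small.n_edges
        # exactly one decision per unordered pair
        assert seq.borda.sum() == e * (e - 1) // 2
        assert sorted(seq.positions) == list(range(1, e + 1))

    def test_restore_beats_random_null(self, ba_small):
        views = nc.build_edge_views(ba_small, dim=16, seed=0)
        model = nc.fit_order_model(ba_small, views, train_fraction=0.3, seed=0,
                                   comparator_kwargs={"epochs": 20})
        seq = nc.restore_network(model, views)
        truth = np.arange(1, ba_small.n_edges + 1)
        rep = nc.overall_error(truth, seq.positions)
        rng = np.random.default_rng(0)
        null = [nc.overall_error(truth, rng.permutation(ba_small.n_edges) + 1).spearman_rho
                for _ in range(200)]
        assert rep.spearman_rho > np.quantile(null, 0.95)
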