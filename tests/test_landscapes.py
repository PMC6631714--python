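"""Landscape colouring, prediction, cross-validation and map selection."""
import warnings

import numpy as np
import pytest

from gtmdock.experiments import known_map, selfconsistent_landscape_q2
from gtmdock.gtm import GTM
from gtmdock.landscapes import (
    ClassLandscape,
    MapFitness,
    PropertyLandscape,
    cross_validate,
    optimize_map,
)


def _R(rows):
    return np.asarray(rows, dtype=float)


class TestColorRegression:
    def test_constant_property_colours_constant(self):
        R = _R([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.3, 0.3, 0.4]])
        ls = PropertyLandscape(None).fit(R, np.full(3, 4.2))
        assert np.allclose(ls.node_values_[ls.defined_mask_], 4.2)

    def test_single_item_on_one_node(self):
        R = _R([[0.0, 1.0, 0.0]])
        ls = PropertyLandscape(None, min_density=1e-9).fit(R, np.array([2.5]))
        assert ls.node_values_[1] == pytest.approx(2.5)
        assert np.isnan(ls.node_values_[0]) and np.isnan(ls.node_values_[2])

    def test_equal_responsibility_averages(self):
        R = _R([[1.0, 0.0], [1.0, 0.0]])
        ls = PropertyLandscape(None).fit(R, np.array([0.0, 6.0]))
        assert ls.node_values_[0] == pytest.approx(3.0)

    def test_no_populated_nodes_errors(self):
        with pytest.raises(ValueError, match="no populated"):
            PropertyLandscape(None, min_density=10.0).fit(
                _R([[0.5, 0.5]]), np.array([1.0]))


class TestPredict:
    def test_dominating_item_predicts_its_value(self):
        R = _R([[0.99, 0.01], [0.01, 0.99]])
        ls = PropertyLandscape(None).fit(R, np.array([1.0, 9.0]))
        pred = ls.predict(_R([[0.99, 0.01]]))
        assert pred[0] == pytest.approx(1.0, abs=0.2)

    def test_out_of_domain_is_nan_with_zero_coverage(self):
        R = _R([[1.0, 0.0, 0.0]])
        ls = PropertyLandscape(None, min_density=1e-9).fit(R, np.array([2.0]))
        pred, cov = ls.predict_with_coverage(_R([[0.0, 0.0, 1.0]]))
        assert np.isnan(pred[0]) and cov[0] == pytest.approx(0.0)

    def test_uniform_landscape_predicts_constant(self, rng):
        R_train = rng.dirichlet(np.ones(5), size=20)
        ls = PropertyLandscape(None).fit(R_train, np.full(20, 7.0))
        pred = ls.predict(rng.dirichlet(np.ones(5), size=10))
        assert np.allclose(pred, 7.0)

    def test_one_item_per_node_reproduces_y(self):
        R = np.eye(4)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        ls = PropertyLandscape(None, min_density=0.0).fit(R, y)
        assert np.allclose(ls.predict(R), y)


class TestClassLandscape:
    def test_pure_node_winner_and_fuzzy_value(self):
        R = _R([[1.0, 0.0], [1.0, 0.0]])
        ls = ClassLandscape(None).fit(R, np.array([2, 2]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pass
        assert ls.winning_class_[0] == 2
        assert ls.fuzzy_values_[0] == pytest.approx(2.0)

    def test_tie_breaks_to_lower_class_and_flags(self):
        R = _R([[1.0, 0.0], [1.0, 0.0]])
        ls = ClassLandscape(None).fit(R, np.array([1, 2]))
        assert ls.winning_class_[0] == 1
        assert ls.tie_mask_[0]

    def test_fuzzy_value_weighted_mean(self):
        R = np.zeros((4, 1))
        R[:, 0] = 1.0
        labels = np.array([1, 1, 1, 2])
        ls = ClassLandscape(None).fit(R, labels)
        assert ls.fuzzy_values_[0] == pytest.approx(1.25)

    def test_fuzzy_values_bounded_by_label_range(self, rng):
        R = rng.dirichlet(np.ones(6), size=40)
        labels = rng.integers(1, 3, size=40)
        ls = ClassLandscape(None).fit(R, labels)
        vals = ls.fuzzy_values_[ls.defined_mask_]
        assert np.all(vals >= 1.0 - 1e-12) and np.all(vals <= 2.0 + 1e-12)

    def test_single_class_warns(self):
        with pytest.warns(UserWarning, match="single-class"):
            ClassLandscape(None).fit(_R([[1.0, 0.0]]), np.array([1]))

    def test_winner_invariant_under_item_duplication(self, rng):
        R = rng.dirichlet(np.ones(5), size=30)
        labels = rng.integers(1, 4, size=30)
        ls1 = ClassLandscape(None).fit(R, labels)
        ls2 = ClassLandscape(None).fit(np.vstack([R, R]), np.concatenate([labels, labels]))
        assert np.array_equal(ls1.winning_class_, ls2.winning_class_)


class TestCrossValidation:
    def test_exact_predictions_give_q2_of_one(self):
        assert selfconsistent_landscape_q2(seed=0) == pytest.approx(1.0, abs=1e-9)

    def test_mean_predictor_gives_q2_of_zero(self):
        # all items on a single node: every prediction is the training mean
        gtm = known_map(seed=1, noise_precision=1e6)
        image = gtm.node_images()[3] + gtm.mean_
        X = np.tile(image, (30, 1))
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        rep = cross_validate(gtm, X, y, seed=0)
        assert abs(rep.mean_q2) < 0.2  # folds' means differ slightly from 0

    def test_negative_q2_is_reported_for_pure_noise(self):
        # per-node means overfit pure noise, so left-out folds score below
        # the mean predictor; negative Q2 must pass through unclipped
        gtm = known_map(seed=1, noise_precision=1e6)
        images = gtm.node_images() + gtm.mean_
        X = np.repeat(images, 3, axis=0)
        y = np.random.default_rng(8).normal(size=X.shape[0])
        rep = cross_validate(gtm, X, y, seed=0)
        assert min(rep.q2_values) < 0

    def test_fewer_items_than_folds_errors(self):
        gtm = known_map(seed=0)
        with pytest.raises(ValueError):
            cross_validate(gtm, np.zeros((2, 5)), np.zeros(2), folds=3)


def test_map_fitness_is_mean_minus_sd():
    mf = MapFitness({"rmsd": [0.9, 0.8], "energy": [0.7, 0.6]})
    q = np.array([0.9, 0.8, 0.7, 0.6])
    assert mf.fitness == pytest.approx(q.mean() - q.std())
    assert mf.fitness <= max(q)


class TestOptimizeMap:
    def _data(self):
        rng = np.random.default_rng(7)
        gtm = known_map(seed=7, side=4, d=6)
        images = gtm.node_images()
        X = np.repeat(images, 8, axis=0) + rng.normal(0, 0.01, size=(128, 6))
        lat = np.repeat(gtm.node_coords_, 8, axis=0)
        y = lat[:, 0] + 0.5 * lat[:, 1]
        noise = rng.normal(size=X.shape)
        return X, noise, y

    def test_single_candidate_returned(self):
        X, _, y = self._data()
        space = {"n_nodes": [16], "n_rbfs": [9], "rbf_width_factor": [1.0],
                 "regularization": [0.1]}
        best, trace = optimize_map(space, {"d": X}, {"y": y}, budget=5, seed=0)
        assert best == {k: v[0] for k, v in space.items()}
        assert len(trace) == 1 and np.isfinite(trace[0][1])

    def test_structured_descriptor_beats_noise(self):
        X, noise, y = self._data()
        space = {"descriptor": ["structured", "noise"], "n_nodes": [16],
                 "n_rbfs": [9], "rbf_width_factor": [1.0], "regularization": [0.1]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, _ = optimize_map(space, {"structured": X, "noise": noise},
                                   {"y": y}, budget=4, seed=0)
        assert best["descriptor"] == "structured"

    def test_same_seed_identical_trace(self):
        X, noise, y = self._data()
        space = {"descriptor": ["structured", "noise"], "n_nodes": [16, 25],
                 "n_rbfs": [4, 9], "rbf_width_factor": [0.5, 1.0],
                 "regularization": [0.01, 0.1]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, t1 = optimize_map(space, {"structured": X, "noise": noise}, {"y": y},
                                 budget=12, seed=3, population=6)
            _, t2 = optimize_map(space, {"structured": X, "noise": noise}, {"y": y},
                                 budget=12, seed=3, population=6)
        assert t1 == t2

    def test_empty_space_errors(self):
        with pytest.raises(ValueError):
            optimize_map({}, {"d": np.zeros((5, 3))}, {"y": np.zeros(5)})
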