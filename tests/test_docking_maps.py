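"""IRI, Q/R/M/F cross-prediction, native-ranking ROC, AR vectors, screening."""
import itertools

import numpy as np
import pytest

from gtmdock.docking_maps import (
    ar_vector,
    ARParameters,
    color_pk_landscape,
    cross_predict_rmsd,
    half_split,
    iri,
    native_ranking_roc,
    predict_pk,
    qrmf_label,
    scenario_positives,
    screen,
)
from gtmdock.landscapes import PropertyLandscape


def _onehot(rows, k):
    R = np.zeros((len(rows), k))
    for i, j in enumerate(rows):
        R[i, j] = 1.0
    return R


class TestIRI:
    def test_identical_runs_are_fully_reproducible(self, rng):
        R = rng.dirichlet(np.ones(8), size=50)
        assert iri(R, R.copy()).iri == 0.0

    def test_disjoint_runs_score_one(self):
        R_a = _onehot([0, 0, 1], 4)
        R_b = _onehot([2, 3, 3], 4)
        assert iri(R_a, R_b).iri == 1.0

    def test_hand_computed_three_node_case(self):
        # D = {10, 10, 10}, f = {0.5, 0.9, 0.5}, p = 0.85 -> IRI = 10/30
        R_a = np.array([[5.0, 9.0, 5.0]]) / 19.0
        R_a = np.repeat(R_a, 19, axis=0)  # CR_A = (5, 9, 5)
        R_b = np.array([[5.0, 1.0, 5.0]]) / 11.0
        R_b = np.repeat(R_b, 11, axis=0)  # CR_B = (5, 1, 5)
        res = iri(R_a, R_b, p=0.85)
        assert res.iri == pytest.approx(10.0 / 30.0, abs=1e-12)

    def test_monotone_nonincreasing_in_p(self, rng):
        R_a = rng.dirichlet(np.ones(6), size=40)
        R_b = rng.dirichlet(np.ones(6) * 0.2, size=40)
        values = [iri(R_a, R_b, p).iri for p in (0.6, 0.75, 0.85, 0.95)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_p_at_or_below_half_rejected(self, rng):
        R = rng.dirichlet(np.ones(4), size=5)
        for p in (0.5, 0.3):
            with pytest.raises(ValueError):
                iri(R, R, p=p)

    def test_empty_run_rejected(self, rng):
        R = rng.dirichlet(np.ones(4), size=5)
        with pytest.raises(ValueError):
            iri(R, np.zeros((0, 4)))


class TestQRMFLabel:
    def test_constructed_labels(self):
        assert qrmf_label(0.9, 0.9, 0.95) == "Q"
        assert qrmf_label(0.2, 0.5, 0.85) == "R"
        assert qrmf_label(0.1, 0.5, 0.55) == "F"
        assert qrmf_label(0.7, 0.65, 0.7) == "M"

    def test_function_is_total(self):
        vals = [-0.5, 0.1, 0.55, 0.61, 0.7, 0.76, 0.81, 0.9, np.nan]
        for r2, ba, auc in itertools.product(vals, repeat=3):
            assert qrmf_label(r2, ba, auc) in {"Q", "R", "M", "F"}

    def test_boundaries_are_strict(self):
        assert qrmf_label(0.75, 0.75, 0.75) != "Q"
        assert qrmf_label(0.0, 0.0, 0.8) != "R"
        assert qrmf_label(0.6, 0.6, 0.6) == "F"


class TestCrossPredict:
    def _landscape_identity(self, k=4):
        # node k holds RMSD value k: predictions echo the node an item sits on
        R = np.eye(k)
        y = np.arange(k, dtype=float)
        return PropertyLandscape(None, min_density=0.0).fit(R, y)

    def test_perfect_predictions_label_q(self):
        ls = self._landscape_identity(6)
        R_test = np.eye(6)
        observed = np.arange(6, dtype=float)
        v = cross_predict_rmsd(ls, R_test, observed)
        assert (v.r2, v.ba, v.auc) == (pytest.approx(1.0), 1.0, 1.0)
        assert v.label == "Q"

    def test_right_order_wrong_scale_labels_r(self):
        # predictions = 2 x observations: AUC perfect, r2 poor
        k = 20
        R_test = np.eye(k)
        observed = np.linspace(0.2, 5.8, k)
        ls = PropertyLandscape(None, min_density=0.0).fit(np.eye(k), 2.0 * observed)
        v = cross_predict_rmsd(ls, R_test, observed)
        assert v.auc == 1.0 and v.r2 < 0.75
        assert v.label == "R"

    def test_anti_ordered_predictions_label_f(self):
        k = 20
        observed = np.linspace(0.2, 5.8, k)
        ls = PropertyLandscape(None, min_density=0.0).fit(np.eye(k), observed[::-1])
        v = cross_predict_rmsd(ls, np.eye(k), observed)
        assert v.label == "F"

    def test_single_class_test_set_flagged(self):
        ls = self._landscape_identity(4)
        observed = np.array([3.0, 4.0, 5.0, 5.5])  # no native-likes
        with pytest.warns(UserWarning, match="both classes"):
            v = cross_predict_rmsd(ls, np.eye(4), observed)
        assert v.degenerate and np.isnan(v.auc)
        assert v.label in {"Q", "M", "F"}


class TestNativeRankingROC:
    def test_perfect_ranking(self):
        assert native_ranking_roc([1, 1, 0, 0], [0.5, 1.0, 3.0, 4.0]) == 1.0

    def test_constant_scores_give_half(self):
        assert native_ranking_roc([1, 0, 1, 0], [2.0] * 4) == 0.5

    def test_enumerated_pairs(self):
        # natives at scores 1 and 3 vs others at 2 and 4: wins 3 of 4 pairs
        assert native_ranking_roc([1, 0, 1, 0], [1.0, 2.0, 3.0, 4.0]) == 0.75

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(3, 7)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([1.0, 2.0, 3.0], size=n)  # ties included
            auc = native_ranking_roc(labels, scores, ascending=True)
            wins = total = 0.0
            for i, j in itertools.product(range(n), repeat=2):
                if labels[i] == 1 and labels[j] == 0:
                    total += 1
                    if scores[i] < scores[j]:
                        wins += 1
                    elif scores[i] == scores[j]:
                        wins += 0.5
            assert auc == pytest.approx(wins / total, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            native_ranking_roc([1, 1], [1.0, 2.0])


class TestARVector:
    def test_beta_zero_is_plain_mean(self, rng):
        R = rng.dirichlet(np.ones(5), size=8)
        e = rng.normal(size=8)
        ar = ar_vector(R, e, 0.0)
        assert np.allclose(ar.ar, R.mean(axis=0), atol=1e-9)

    def test_large_beta_selects_most_stable_pose(self, rng):
        R = rng.dirichlet(np.ones(5), size=8)
        e = np.arange(8.0)
        ar = ar_vector(R, e, ARParameters(beta=1e6))
        assert np.allclose(ar.ar, R[0], atol=1e-9)

    def test_equal_energies_average_for_any_beta(self, rng):
        R = rng.dirichlet(np.ones(4), size=2)
        for beta in (0.0, 0.3, 5.0, 100.0):
            ar = ar_vector(R, [2.0, 2.0], beta)
            assert np.allclose(ar.ar, R.mean(axis=0), atol=1e-12)

    def test_sums_to_one_and_continuous_in_beta(self, rng):
        R = rng.dirichlet(np.ones(6), size=10)
        e = rng.normal(size=10)
        prev = None
        for beta in np.linspace(0, 2, 21):
            ar = ar_vector(R, e, beta)
            assert ar.ar.sum() == pytest.approx(1.0, abs=1e-9)
            if prev is not None:
                assert np.max(np.abs(ar.ar - prev)) < 0.2
            prev = ar.ar

    def test_negative_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            ar_vector(rng.dirichlet(np.ones(3), size=2), [0.0, 1.0], -0.1)


class TestScreen:
    def test_identical_ar_recovers_pk(self):
        ar = np.array([[0.2, 0.8, 0.0]])
        node_v, _ = color_pk_landscape(ar, [6.5])
        pred, cov = predict_pk(node_v, ar)
        assert pred[0] == pytest.approx(6.5)
        assert cov[0] == pytest.approx(1.0)

    def test_disjoint_colour_compounds_interpolate(self):
        color = np.array([[1.0, 0.0], [0.0, 1.0]])
        node_v, _ = color_pk_landscape(color, [5.0, 9.0])
        pred, _ = predict_pk(node_v, np.array([[0.5, 0.5]]))
        assert pred[0] == pytest.approx(7.0)

    def test_out_of_domain_excluded_and_counted(self):
        color = np.array([[1.0, 0.0, 0.0]])
        test = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.9, 0.1, 0.0]])
        res = screen(color, [7.0], test, ["top", "decoy", "top"], scenario="TvO",
                     min_density=1e-6)
        assert res.n_undefined == 1

    def test_scenario_positive_definitions(self):
        labels = ["top", "weak", "decoy"]
        assert scenario_positives(labels, "TvO").tolist() == [True, False, False]
        assert scenario_positives(labels, "AvD").tolist() == [True, True, False]
        with pytest.raises(ValueError):
            scenario_positives(labels, "XvY")

    def test_beta_zero_equals_plain_average_path(self, rng):
        # screening with AR(beta=0) must equal screening with row means
        R = rng.dirichlet(np.ones(6), size=12)
        e = rng.normal(size=12)
        ar0 = ar_vector(R, e, 0.0).ar
        assert np.allclose(ar0, R.mean(axis=0), atol=1e-12)

    def test_half_split_is_stratified_and_disjoint(self):
        labels = ["top"] * 10 + ["weak"] * 8 + ["decoy"] * 6
        color, test = half_split(labels, seed=4)
        assert len(set(color) & set(test)) == 0
        assert len(color) + len(test) == 24
        labels = np.asarray(labels)
        for lab, n in (("top", 10), ("weak", 8), ("decoy", 6)):
            assert (labels[color] == lab).sum() == n // 2
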