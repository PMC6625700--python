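import math

import numpy as np
import pytest

from acnn.ensemble import (
    EnsembleModel,
    WeakClassifier,
    boost,
    classifier_coefficient,
    decision_score,
    fit_acnn,
    hard_votes,
    init_weights,
    predict_label,
    update_weights,
    weighted_error,
)


# ---------------------------------------------------------------------------
# Independent brute-force boosting oracle (naive, element-by-element)
# ---------------------------------------------------------------------------

def naive_adaboost(pred_rounds, labels):
    """Textbook reweighting computed with python loops and explicit sums."""
    m = len(labels)
    w = [1.0 / m] * m
    history = {"weights": [list(w)], "errors": [], "alphas": []}
    for preds in pred_rounds:
        e = sum(wi for wi, p, y in zip(w, preds, labels) if p != y)
        e = min(max(e, 1e-10), 1 - 1e-10)
        a = 0.5 * math.log((1 - e) / e)
        unnorm = [wi * math.exp(-a * y * p) for wi, p, y in zip(w, preds, labels)]
        z = sum(unnorm)
        w = [u / z for u in unnorm]
        history["errors"].append(e)
        history["alphas"].append(a)
        history["weights"].append(list(w))
    return history


def stub_trainers(pred_rounds):
    return [
        (lambda weights, p=preds: (None, np.asarray(p))) for preds in pred_rounds
    ]


class TestPrimitives:
    def test_init_weights_uniform(self):
        np.testing.assert_array_equal(init_weights(4), [0.25] * 4)
        np.testing.assert_array_equal(init_weights(1), [1.0])
        assert init_weights(7).sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            init_weights(0)

    def test_weighted_error_cases(self):
        labels = np.ones(10, dtype=int)
        preds = labels.copy()
        preds[:3] = -1
        assert weighted_error(preds, labels, init_weights(10)) == pytest.approx(0.3)
        w = [0.7, 0.1, 0.1, 0.1]
        assert weighted_error([-1, 1, 1, 1], [1, 1, 1, 1], w) == pytest.approx(0.7)
        # all correct clips to epsilon rather than zero
        assert weighted_error(labels, labels, init_weights(10)) == pytest.approx(1e-10)

    def test_weighted_error_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            weighted_error([1], [1, -1], [0.5, 0.5])

    def test_classifier_coefficient(self):
        assert classifier_coefficient(0.5) == 0.0
        assert classifier_coefficient(0.1) == pytest.approx(0.5 * math.log(9))
        assert classifier_coefficient(0.1) > classifier_coefficient(0.2)
        with pytest.raises(ValueError):
            classifier_coefficient(0.0)
        with pytest.raises(ValueError):
            classifier_coefficient(1.0)

    def test_update_weights_all_correct_uniform_unchanged(self):
        w = init_weights(5)
        labels = np.array([1, -1, 1, -1, 1])
        out = update_weights(w, 0.8, labels, labels)
        np.testing.assert_allclose(out, w)

    def test_update_weights_hand_example(self):
        # m=2 uniform, sample 1 wrong, alpha = 0.5 ln 3:
        # wrong gets 0.5*sqrt(3), right gets 0.5/sqrt(3) -> (0.75, 0.25)
        out = update_weights([0.5, 0.5], 0.5 * math.log(3), [-1, 1], [1, 1])
        np.testing.assert_allclose(out, [0.75, 0.25])

    def test_update_weights_normalized_nonnegative(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 15))
            w = rng.dirichlet(np.ones(m))
            labels = rng.choice([-1, 1], m)
            preds = rng.choice([-1, 1], m)
            alpha = float(rng.normal())
            out = update_weights(w, alpha, preds, labels)
            assert out.min() >= 0
            assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hard_votes_tie_maps_to_positive(self):
        np.testing.assert_array_equal(hard_votes([0.2, 0.5, 0.9]), [-1, 1, 1])


class TestBoostOracleEquivalence:
    def test_exact_match_with_naive_adaboost(self, rng):
        for trial in range(10):
            m = int(rng.integers(5, 21))
            labels = rng.choice([-1, 1], m)
            pred_rounds = [rng.choice([-1, 1], m) for _ in range(3)]
            ensemble, hist = boost(stub_trainers(pred_rounds), labels)
            oracle = naive_adaboost(pred_rounds, labels)
            np.testing.assert_allclose(hist["alphas"], oracle["alphas"], atol=1e-12)
            np.testing.assert_allclose(hist["errors"], oracle["errors"], atol=1e-12)
            for wv, ov in zip(hist["weights"], oracle["weights"]):
                np.testing.assert_allclose(wv, ov, atol=1e-12)

    def test_perfect_first_member_keeps_distribution(self):
        labels = np.array([1, -1, 1, -1])
        rounds = [labels.copy(), labels.copy(), labels.copy()]
        ensemble, hist = boost(stub_trainers(rounds), labels)
        np.testing.assert_allclose(hist["weights"][1], init_weights(4), atol=1e-8)
        assert hist["alphas"][0] > 10  # near-zero error -> huge coefficient

    def test_weak_member_error_above_half_warns(self):
        labels = np.array([1, 1, 1, -1])
        bad = np.array([-1, -1, -1, -1])
        with pytest.warns(UserWarning, match=">= 0.5"):
            ensemble, hist = boost(stub_trainers([bad, labels, labels]), labels)
        assert ensemble.members[0].alpha < 0

    def test_training_error_bound(self, rng):
        # weighted error of the fused vote never exceeds prod 2 sqrt(e(1-e))
        for trial in range(10):
            m = int(rng.integers(8, 20))
            labels = rng.choice([-1, 1], m)
            rounds = []
            for _ in range(3):
                preds = labels.copy()
                flip = rng.uniform(size=m) < 0.3
                preds[flip] *= -1
                rounds.append(preds)
            ensemble, hist = boost(stub_trainers(rounds), labels)
            agg = sum(
                a * np.asarray(p) for a, p in zip(hist["alphas"], rounds)
            )
            final = np.where(agg >= 0, 1, -1)
            train_err = np.mean(final != labels)
            bound = np.prod(
                [2 * math.sqrt(e * (1 - e)) for e in hist["errors"]]
            )
            assert train_err <= bound + 1e-12


class _StubModel:
    """Callable member standing in for a CNN: fixed probability per patch."""

    def __init__(self, prob):
        self.prob = prob

    def __call__(self, patch):
        return self.prob


def _stub_ensemble(probs, errors):
    members = [
        WeakClassifier(_StubModel(p), classifier_coefficient(e), e)
        for p, e in zip(probs, errors)
    ]
    return EnsembleModel(members)


class TestPrediction:
    def test_unanimous_agreement(self):
        ens = _stub_ensemble([0.9, 0.8, 0.7], [0.1, 0.2, 0.3])
        assert predict_label(ens, None) == 1

    def test_weighted_minority_wins(self):
        # alpha = (2, 0.5, 0.5) with votes (+1, -1, -1) -> +1
        members = [
            WeakClassifier(_StubModel(0.9), 2.0, 1 / (1 + math.exp(4))),
            WeakClassifier(_StubModel(0.1), 0.5, 1 / (1 + math.exp(1))),
            WeakClassifier(_StubModel(0.2), 0.5, 1 / (1 + math.exp(1))),
        ]
        assert predict_label(EnsembleModel(members), None) == 1

    def test_majority_under_equal_alphas(self):
        e = 1 / (1 + math.exp(2))  # alpha exactly 1
        ens = _stub_ensemble([0.9, 0.8, 0.1], [e, e, e])
        assert predict_label(ens, None) == 1

    def test_exact_tie_maps_to_positive(self):
        e = 1 / (1 + math.exp(2))
        members = [
            WeakClassifier(_StubModel(0.9), 1.0, e),
            WeakClassifier(_StubModel(0.1), 1.0, e),
        ]
        assert predict_label(EnsembleModel(members), None) == 1

    def test_decision_score_extremes_and_single_member(self):
        ens = _stub_ensemble([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert decision_score(ens, None) == pytest.approx(1.0)
        neutral = _stub_ensemble([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert decision_score(neutral, None) == pytest.approx(0.0)
        single = _stub_ensemble([0.8], [1 / (1 + math.exp(2))])
        assert decision_score(single, None) == pytest.approx(0.6)

    def test_score_threshold_consistent_when_votes_unanimous(self, rng):
        # the margin-weighted score and the hard-vote label are guaranteed
        # to agree when all members vote the same way (they may differ when
        # a high-coefficient member holds only a slim margin)
        for _ in range(50):
            side = 1 if rng.uniform() < 0.5 else -1
            probs = rng.uniform(0.55, 0.95, 3)
            if side == -1:
                probs = 1 - probs
            errors = rng.uniform(0.05, 0.45, 3)
            ens = _stub_ensemble(list(probs), list(errors))
            score = decision_score(ens, None)
            assert (score > 0) == (predict_label(ens, None) == 1)
            assert predict_label(ens, None) == side

    def test_all_zero_alpha_rejected(self):
        members = [WeakClassifier(_StubModel(0.7), 0.0, 0.5)]
        with pytest.raises(ValueError, match="zero"):
            decision_score(EnsembleModel(members), None)


class TestFitAcnn:
    def test_end_to_end_on_micro_patches(self, rng):
        from acnn.ensemble import WeightedTrainingSet
        from acnn.networks import TrainConfig

        m = 16
        cubes = {
            e: rng.normal(0, 0.05, size=(m, e, e, e)).astype(np.float32)
            for e in (32, 64, 96)
        }
        labels = np.where(np.arange(m) % 2 == 0, 1, -1)
        for e in (32, 64, 96):
            cubes[e][labels == 1, e // 2 - 3 : e // 2 + 3] += 0.4
        ds = WeightedTrainingSet(cubes=cubes, labels=labels)
        cfg = TrainConfig(learning_rate=0.05, epochs=2, batch_size=8)
        ens1, h1 = fit_acnn(ds, cfg, seed=9, profile="tiny")
        assert len(ens1.members) == 3
        assert [m_.input_edge for m_ in ens1.members] == [32, 64, 96]
        assert len(h1["weights"]) == 4
        for w in h1["weights"]:
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
        # reproducibility under the same seed
        ens2, h2 = fit_acnn(ds, cfg, seed=9, profile="tiny")
        np.testing.assert_array_equal(h1["alphas"], h2["alphas"])

    def test_missing_scale_rejected(self):
        from acnn.ensemble import WeightedTrainingSet
        from acnn.networks import TrainConfig

        ds = WeightedTrainingSet(
            cubes={32: np.zeros((4, 32, 32, 32), np.float32)},
            labels=np.array([1, -1, 1, -1]),
        )
        with pytest.raises(ValueError, match="64"):
            fit_acnn(ds, TrainConfig(epochs=1), seed=0)
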