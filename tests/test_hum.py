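"""AUC and HUM estimators checked against brute-force enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicforest import binary_auc, forest_weights, hum


def auc_bruteforce(scores, labels):
    """All (positive, negative) pairs; ties count 1/2."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def hum_enumerate(prob, labels):
    """Fraction of all one-per-class tuples concordant under the argmax rule."""
    prob = np.asarray(prob, float)
    labels = np.asarray(labels, int)
    pred = np.argmax(prob, axis=1)
    groups = [np.flatnonzero(labels == c) for c in range(prob.shape[1])]
    hits = total = 0
    for combo in itertools.product(*groups):
        total += 1
        hits += all(pred[i] == c for c, i in enumerate(combo))
    return hits / total


class TestBinaryAuc:
    def test_perfect_separation(self):
        assert binary_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert binary_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_enumerated_pairs(self):
        # 3 of 4 (pos, neg) pairs concordant
        assert binary_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            binary_auc([0.1, 0.2], [1, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert binary_auc(scores, labels) == pytest.approx(
            auc_bruteforce(scores, labels), abs=1e-12
        )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sign_flip_complement_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(np.linspace(0.01, 0.99, 12))
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        assert binary_auc(scores, labels) + binary_auc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )


class TestHum:
    def test_perfect_classifier_scores_one(self):
        prob = np.eye(3)[np.array([0, 1, 2, 0, 1, 2])]
        labels = np.array([0, 1, 2, 0, 1, 2])
        assert hum(prob, labels) == 1.0

    def test_hand_enumerated_triplets(self):
        # one sample per class; the class-2 row argmaxes to class 0 -> HUM 0
        prob = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.5, 0.3, 0.2]])
        labels = np.array([0, 1, 2])
        assert hum(prob, labels) == 0.0
        # a second, correct class-2 row fixes half of the 2 triplets
        prob2 = np.vstack([prob, [0.1, 0.2, 0.7]])
        labels2 = np.array([0, 1, 2, 2])
        assert hum(prob2, labels2) == 0.5

    def test_chance_level_for_label_free_scores(self):
        rng = np.random.default_rng(42)
        n = 300
        prob = rng.dirichlet([1.0, 1.0, 1.0], size=3 * n)
        labels = np.repeat([0, 1, 2], n)
        # product of three independent ~Bin(n, 1/3)/n proportions
        p = 1.0 / 3
        se = np.sqrt(3) * p**2 * np.sqrt(p * (1 - p) / n)
        assert hum(prob, labels) == pytest.approx(p**3, abs=3 * se + 1e-9)

    def test_absent_class_errors(self):
        with pytest.raises(ValueError, match="absent"):
            hum(np.eye(3)[[0, 1, 0]], np.array([0, 1, 1]))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.sampled_from([3, 4]))
    def test_factorized_form_equals_enumeration(self, seed, n_classes):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 6 if n_classes == 4 else 10, size=n_classes)
        labels = np.repeat(np.arange(n_classes), sizes)
        prob = rng.random((len(labels), n_classes))
        assert hum(prob, labels) == pytest.approx(
            hum_enumerate(prob, labels), abs=1e-12
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sample_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1, 2], 5)
        prob = rng.random((15, 3))
        perm = rng.permutation(15)
        assert hum(prob, labels) == pytest.approx(hum(prob[perm], labels[perm]), abs=1e-12)


class TestForestWeights:
    @pytest.mark.parametrize(
        "h1,h2,a1,a2",
        [(0.5, 0.5, 0.5, 0.5), (0.8, 0.4, 2 / 3, 1 / 3), (0.9, 0.0, 1.0, 0.0)],
    )
    def test_normalization_arithmetic(self, h1, h2, a1, a2):
        w = forest_weights(h1, h2)
        assert w.alpha1 == pytest.approx(a1, abs=1e-12)
        assert w.alpha2 == pytest.approx(a2, abs=1e-12)

    def test_both_zero_degrades_with_warning(self):
        with pytest.warns(UserWarning):
            w = forest_weights(0.0, 0.0)
        assert (w.alpha1, w.alpha2) == (0.5, 0.5)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(1e-6, 1))
    def test_weights_sum_to_one(self, h1, h2):
        w = forest_weights(h1, h2)
        assert w.alpha1 + w.alpha2 == pytest.approx(1.0, abs=1e-12)
        assert w.alpha1 >= 0 and w.alpha2 >= 0
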