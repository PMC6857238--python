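"""Sliding-window scanning, forest-pair weighting and window weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicforest import (
    MultiGrainedScanner,
    WindowSpec,
    default_window_lengths,
    scan,
    t_ability,
    window_count,
    window_weights,
)
from omicforest.scanning import fit_window


class TestWindowCount:
    @pytest.mark.parametrize(
        "M,L,S,expected", [(400, 100, 1, 301), (10, 10, 1, 1), (10, 4, 2, 4)]
    )
    def test_formula(self, M, L, S, expected):
        assert window_count(M, L, S) == expected

    def test_window_longer_than_row_errors(self):
        with pytest.raises(ValueError):
            window_count(10, 11, 1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 5))
    def test_matches_scan_output(self, M, L, S):
        if L > M:
            with pytest.raises(ValueError):
                window_count(M, L, S)
            return
        V = window_count(M, L, S)
        assert V >= 1
        assert scan(np.arange(M, dtype=float), WindowSpec(L, S)).shape == (V, L)


class TestScan:
    def test_unit_stride_windows(self):
        out = scan(np.array([1.0, 2, 3, 4]), WindowSpec(2, 1))
        np.testing.assert_array_equal(out, [[1, 2], [2, 3], [3, 4]])

    def test_full_width_is_identity(self):
        row = np.arange(7, dtype=float)
        np.testing.assert_array_equal(scan(row, WindowSpec(7, 1)), row[None, :])

    def test_worked_example_count(self):
        assert scan(np.zeros(400), WindowSpec(100, 1)).shape == (301, 100)


class TestAbilityAndWeights:
    def test_hand_enumerated_top_third(self):
        v = np.array([0.1, 0.7, 0.2, 0.3, 0.5, 0.2])
        assert t_ability(v, 3) == pytest.approx(0.6)  # mean of top 2

    def test_constant_vector(self):
        assert t_ability(np.full(9, 0.4), 3) == pytest.approx(0.4)

    def test_short_vector_uses_at_least_one(self):
        assert t_ability(np.array([0.2, 0.9]), 3) == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "abilities,beta",
        [
            ((1.0, 1.0, 1.0), (1 / 3, 1 / 3, 1 / 3)),
            ((0.6, 0.3, 0.1), (0.6, 0.3, 0.1)),
            ((2.0, 1.0, 1.0), (0.5, 0.25, 0.25)),
        ],
    )
    def test_normalization(self, abilities, beta):
        np.testing.assert_allclose(window_weights(abilities), beta, atol=1e-12)

    def test_all_zero_degrades_uniform(self):
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(window_weights([0.0, 0.0]), [0.5, 0.5])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-9, 10), min_size=1, max_size=8))
    def test_beta_simplex(self, abilities):
        beta = window_weights(abilities)
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)
        assert (beta >= 0).all()


class TestDefaultWindows:
    def test_reproduces_quarter_grid(self):
        assert default_window_lengths(400) == [100, 200, 300]

    def test_small_feature_count(self):
        lengths = default_window_lengths(39)
        assert lengths == [10, 20, 30]


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(21)
    y = np.repeat([0, 1, 2], 10)
    X = rng.normal(size=(30, 24))
    X[:, :6] += 2.0 * y[:, None]
    return X, y


class TestForestPair:
    def test_weights_normalized_and_oob_hum_recorded(self, toy):
        X, y = toy
        fp = fit_window(X, y, WindowSpec(8, 1), n_trees=30, seed=0)
        assert fp.weights.alpha1 + fp.weights.alpha2 == pytest.approx(1.0, abs=1e-12)
        h1, h2 = fp.oob_hum
        assert 0 <= h1 <= 1 and 0 <= h2 <= 1
        assert fp.weights.alpha1 == pytest.approx(h1 / (h1 + h2), abs=1e-12)

    def test_deterministic_given_seed(self, toy):
        X, y = toy
        a = fit_window(X, y, WindowSpec(8, 1), n_trees=15, seed=3)
        b = fit_window(X, y, WindowSpec(8, 1), n_trees=15, seed=3)
        assert a.weights == b.weights and a.oob_hum == b.oob_hum

    def test_single_class_errors(self, toy):
        X, _ = toy
        with pytest.raises(ValueError):
            fit_window(X, np.zeros(len(X), int), WindowSpec(8, 1), n_trees=5, seed=0)


class TestScannerTransform:
    def test_vector_length_law_and_beta_simplex(self, toy):
        X, y = toy
        sc = MultiGrainedScanner(window_lengths=[5, 9], n_trees=15, seed=1).fit(X, y)
        out = sc.transform(X)
        C = 3
        for L, block in zip(out.window_lengths, out.per_window):
            V = window_count(X.shape[1], L, 1)
            assert block.shape == (len(X), 2 * V * C)
        assert out.beta.sum() == pytest.approx(1.0, abs=1e-12)
        assert (out.beta >= 0).all()

    def test_single_window_has_unit_beta(self, toy):
        X, y = toy
        sc = MultiGrainedScanner(window_lengths=[10], n_trees=15, seed=2).fit(X, y)
        out = sc.transform(X)
        assert out.beta.tolist() == [1.0]

    def test_refit_bit_identical(self, toy):
        X, y = toy
        a = MultiGrainedScanner(n_trees=15, seed=8).fit_transform(X, y)
        b = MultiGrainedScanner(n_trees=15, seed=8).fit_transform(X, y)
        np.testing.assert_array_equal(a.beta, b.beta)
        for pa, pb in zip(a.per_window, b.per_window):
            np.testing.assert_array_equal(pa, pb)

    def test_forced_alpha_zeroes_crf_half(self, toy):
        X, y = toy
        sc = MultiGrainedScanner(
            window_lengths=[8], n_trees=15, seed=4, force_alpha=(1.0, 0.0)
        ).fit(X, y)
        block = sc.transform(X).per_window[0]
        half = block.shape[1] // 2
        assert np.all(block[:, half:] == 0.0)
        assert np.any(block[:, :half] > 0.0)

    def test_unfitted_transform_errors(self, toy):
        X, _ = toy
        with pytest.raises(ValueError, match="not fitted"):
            MultiGrainedScanner().transform(X)
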