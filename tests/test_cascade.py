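"""Cascade growth, early stopping, prediction averaging."""

import numpy as np
import pytest

from omicforest import CascadeForest, MultiGrainedScanner
from omicforest.cascade import CascadeLayer
from omicforest.scanning import ScanOutput


def _scans(effect, seed=0, n_per_class=10, M=24, windows=(6, 12)):
    """Scanner outputs for a train/val split of a planted-signal toy."""
    rng = np.random.default_rng(seed)
    y = np.tile(np.repeat([0, 1, 2], n_per_class), 2)
    X = rng.normal(size=(len(y), M))
    X[:, :6] += effect * y[:, None]
    half = len(y) // 2
    sc = MultiGrainedScanner(window_lengths=list(windows), n_trees=15, seed=seed)
    sc.fit(X[:half], y[:half])
    return sc.transform(X[:half]), y[:half], sc.transform(X[half:]), y[half:]


class TestGrowth:
    def test_layer_input_dimension_law(self):
        scan, y, scan_val, y_val = _scans(effect=2.0)
        cf = CascadeForest(n_trees=15, kfold_k=2, fixed_depth=4, seed=1)
        cf.fit(scan, y, scan_val, y_val)
        C, M = 3, 24
        v = [2 * ((M - L) + 1) * C for L in (6, 12)]
        # layer 1: first window; layer k>=2: 4C + window (k-2) mod T
        assert cf.input_dims_ == [v[0], 4 * C + v[0], 4 * C + v[1], 4 * C + v[0]]

    def test_augmented_blocks_are_probability_vectors(self):
        scan, y, scan_val, y_val = _scans(effect=2.0, seed=3)
        cf = CascadeForest(n_trees=15, kfold_k=2, fixed_depth=2, seed=2)
        cf.fit(scan, y, scan_val, y_val)
        probs = cf.predict_proba(scan_val)
        assert probs.shape == (len(y_val), 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_early_stop_on_separable_data(self):
        scan, y, scan_val, y_val = _scans(effect=6.0, seed=5)
        cf = CascadeForest(n_trees=20, kfold_k=2, seed=4)
        cf.fit(scan, y, scan_val, y_val)
        assert cf.val_scores_[cf.best_depth_ - 1] == 1.0
        # growth halts within one layer of reaching perfect validation accuracy
        assert len(cf.val_scores_) <= cf.best_depth_ + 1

    def test_shuffled_labels_stop_immediately(self):
        scan, y, scan_val, y_val = _scans(effect=2.0, seed=6)
        rng = np.random.default_rng(0)
        cf = CascadeForest(n_trees=15, kfold_k=2, seed=5)
        cf.fit(scan, rng.permutation(y), scan_val, rng.permutation(y_val))
        assert cf.best_depth_ <= 2  # permutation null: no real gain to chase

    def test_stop_tol_monotone_in_depth(self):
        scan, y, scan_val, y_val = _scans(effect=1.0, seed=7)
        depths = []
        for tol in (0.0, 0.05, 0.2, 0.5):
            cf = CascadeForest(n_trees=15, kfold_k=2, stop_tol=tol, seed=6)
            cf.fit(scan, y, scan_val, y_val)
            depths.append(cf.best_depth_)
        assert depths == sorted(depths, reverse=True)

    def test_refit_bit_identical(self):
        scan, y, scan_val, y_val = _scans(effect=2.0, seed=8)
        a = CascadeForest(n_trees=15, kfold_k=2, seed=9).fit(scan, y, scan_val, y_val)
        b = CascadeForest(n_trees=15, kfold_k=2, seed=9).fit(scan, y, scan_val, y_val)
        np.testing.assert_array_equal(a.predict_proba(scan_val), b.predict_proba(scan_val))
        assert a.best_depth_ == b.best_depth_ and a.val_scores_ == b.val_scores_

    def test_missing_validation_errors(self):
        scan, y, _, _ = _scans(effect=2.0)
        with pytest.raises(ValueError, match="validation"):
            CascadeForest(n_trees=5, seed=0).fit(scan, y)

    def test_single_class_errors(self):
        scan, y, scan_val, y_val = _scans(effect=2.0)
        with pytest.raises(ValueError, match="two classes"):
            CascadeForest(n_trees=5, seed=0).fit(scan, np.zeros_like(y), scan_val, y_val)


class _StubForest:
    """predict_proba returns one constant row; classes_ covers all 3 codes."""

    classes_ = np.array([0, 1, 2])

    def __init__(self, row):
        self.row = np.asarray(row, dtype=float)

    def predict_proba(self, X):
        return np.tile(self.row, (len(X), 1))


class TestPredictAveraging:
    def _model(self, rows):
        cf = CascadeForest(n_trees=1, seed=0)
        cf.n_classes_ = 3
        cf.window_lengths_ = [4]
        cf.layers_ = [CascadeLayer([_StubForest(r) for r in rows], 0, 24)]
        cf.best_depth_ = 1
        return cf

    def _scan(self, n=2):
        return ScanOutput([np.zeros((n, 24))], np.array([1.0]), [4], 3)

    def test_unanimous_forests(self):
        cf = self._model([[0, 0, 1]] * 4)
        probs = cf.predict_proba(self._scan())
        np.testing.assert_allclose(probs, [[0, 0, 1]] * 2)
        assert cf.predict(self._scan()).tolist() == [2, 2]

    def test_hand_averaged_disagreement(self):
        cf = self._model([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 0]])
        probs = cf.predict_proba(self._scan(1))
        np.testing.assert_allclose(probs, [[0.5, 0.25, 0.25]], atol=1e-12)
        assert cf.predict(self._scan(1)).tolist() == [0]  # argmax, ties to lowest

    def test_training_sample_recovered_on_separable_data(self):
        scan, y, scan_val, y_val = _scans(effect=6.0, seed=11)
        cf = CascadeForest(n_trees=20, kfold_k=2, fixed_depth=1, seed=10)
        cf.fit(scan, y, scan_val, y_val)
        assert np.mean(cf.predict(scan) == y) == 1.0

    def test_window_mismatch_errors(self):
        cf = self._model([[1, 0, 0]] * 4)
        bad = ScanOutput([np.zeros((2, 24))], np.array([1.0]), [5], 3)
        with pytest.raises(ValueError, match="windows"):
            cf.predict_proba(bad)
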