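"""F-score ranking, oracle equivalence, and the stepwise accuracy sweep."""

import numpy as np
import pandas as pd
import pytest

from supenh.pipeline import featurize_dataset
from supenh.selection import (
    SelectionError,
    apply_selection,
    fscore_rank,
    stepwise_select,
)
from supenh.shallow import EIIPTable
from supenh.synthetic import default_embedding_fixtures


def naive_fscore(X, y):
    """Independent per-feature loop implementation of the F-score."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        xp, xn = X[y == 1, j], X[y == 0, j]
        num = (xp.mean() - X[:, j].mean()) ** 2 + (xn.mean() - X[:, j].mean()) ** 2
        den = xp.var(ddof=1) + xn.var(ddof=1)
        out[j] = np.inf if den == 0 and num > 0 else (0.0 if den == 0 else num / den)
    return out


class TestFScore:
    def test_hand_computed_toy_value(self):
        """Class+ {1,1,3,3}, class- {-1,-1,-3,-3} -> F = (4+4)/(4/3+4/3) = 3."""
        X = np.array([[1.0], [1.0], [3.0], [3.0], [-1.0], [-1.0], [-3.0], [-3.0]])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert fscore_rank(X, y).scores[0] == pytest.approx(3.0, abs=1e-15)

    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.full(8, 0.5), np.arange(8.0)])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert fscore_rank(X, y).scores[0] == 0.0

    def test_zero_within_class_variance_sorts_first(self):
        X = np.column_stack([np.r_[np.ones(4), np.zeros(4)], np.random.default_rng(0).random(8)])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        ranking = fscore_rank(X, y)
        assert np.isinf(ranking.scores[0]) and ranking.order[0] == 0

    def test_matches_naive_loop_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X = rng.standard_normal((20, 50))
            y = rng.permutation(np.r_[np.ones(10, int), np.zeros(10, int)])
            ours = fscore_rank(X, y).scores
            assert np.allclose(ours, naive_fscore(X, y), rtol=1e-12, atol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        y = rng.permutation(np.r_[np.ones(15, int), np.zeros(15, int)])
        scaled = X.copy()
        scaled[:, 2] *= -17.5
        assert fscore_rank(scaled, y).scores[2] == pytest.approx(
            fscore_rank(X, y).scores[2], rel=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(SelectionError):
            fscore_rank(np.random.rand(4, 3), np.ones(4, int))

    def test_planted_features_recovered_at_top(self, planted_dataset, embedding_fixtures):
        _, Xs, _ = featurize_dataset(planted_dataset, embedding_fixtures, EIIPTable())
        ranking = fscore_rank(Xs, planted_dataset.labels())
        top20 = {ranking.feature_names[i] for i in ranking.top(20)}
        planted = {f"{p}_mid_{k}" for p in ("comp", "eiip") for k in ("AAA", "GGG")}
        assert planted <= top20


class TestStepwiseSweep:
    @staticmethod
    def _separable(n=60, p=25, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.permutation(np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)])
        X = rng.standard_normal((n, p))
        X[:, 0] += 6.0 * y  # one decisive feature
        return X, y

    def test_perfectly_separable_chooses_earliest_max(self):
        X, y = self._separable()
        ranking = fscore_rank(X, y)
        sweep = stepwise_select(X, y, ranking, step=10, split_seed=0)
        accs = dict(sweep.accuracies)
        assert accs[sweep.chosen_dim] == max(accs.values()) == 1.0
        assert sweep.chosen_dim == min(n for n, a in sweep.accuracies if a == 1.0)

    def test_step_larger_than_feature_count(self):
        X, y = self._separable(p=7)
        sweep = stepwise_select(X, y, fscore_rank(X, y), step=50, split_seed=0)
        assert [n for n, _ in sweep.accuracies] == [7]

    def test_final_n_covers_all_features(self):
        X, y = self._separable(p=23)
        sweep = stepwise_select(X, y, fscore_rank(X, y), step=10, split_seed=0)
        assert [n for n, _ in sweep.accuracies] == [10, 20, 23]

    def test_invalid_step_rejected(self):
        X, y = self._separable()
        with pytest.raises(SelectionError):
            stepwise_select(X, y, fscore_rank(X, y), step=0)


class TestApplySelection:
    def test_columns_in_rank_order_names_preserved(self):
        X = pd.DataFrame(
            {"a": [1.0, 1, 5, 5], "b": [0.1, 0.2, 0.1, 0.2], "c": [9.0, 9, 0, 0]},
        )
        y = np.array([1, 1, 0, 0])
        ranking = fscore_rank(X, y)
        picked = apply_selection(X, ranking, 2)
        assert list(picked.columns) == [ranking.feature_names[i] for i in ranking.top(2)]
        assert list(picked.index) == list(X.index)

    def test_n_equals_total_is_column_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 6))
        y = rng.permutation(np.r_[np.ones(10, int), np.zeros(10, int)])
        ranking = fscore_rank(X, y)
        out = apply_selection(X, ranking, 6)
        assert sorted(map(tuple, out.T)) == sorted(map(tuple, X.T))

    def test_out_of_range_rejected(self):
        X = np.random.rand(8, 3)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        ranking = fscore_rank(X, y)
        with pytest.raises(SelectionError):
            apply_selection(X, ranking, 4)
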