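"""Soft voting: exactness, bounds, order invariance, combination search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supenh.ensemble import (
    CombinationSearchResult,
    SoftVotingEnsemble,
    combination_search,
    member_label,
    soft_vote,
)
from supenh.models import FeatureMismatchError, TrainedModel


class _Stub:
    def __init__(self, proba):
        self.proba = np.asarray(proba, dtype=float)

    def predict_proba(self, X):
        return self.proba[: len(X)]


def stub(kind, space, proba):
    return TrainedModel(
        kind=kind, space=space, feature_names=("f0", "f1"), estimator=_Stub(proba)
    )


class TestSoftVote:
    def test_mean_of_two(self):
        assert soft_vote([[0.6], [0.8]])[0] == pytest.approx(0.7)

    def test_single_member_is_identity(self):
        p = np.array([0.1, 0.7, 0.4])
        assert np.array_equal(soft_vote([p]), p)

    def test_three_member_hand_mean(self):
        assert soft_vote([[0.2], [0.5], [0.9]])[0] == pytest.approx(1.6 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            soft_vote([[0.5, 0.5], [0.5]])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([[1.2], [0.5]])

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=1, max_value=8),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_exactness_bounds_and_permutation_invariance(self, n_members, n_samples, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random((n_members, n_samples))
        vote = soft_vote(list(probs))
        # exact brute-force per-sample mean
        expected = np.array([probs[:, i].sum() / n_members for i in range(n_samples)])
        assert np.allclose(vote, expected, atol=1e-15)
        assert np.all(vote >= probs.min(axis=0) - 1e-15)
        assert np.all(vote <= probs.max(axis=0) + 1e-15)
        perm = rng.permutation(n_members)
        assert np.allclose(vote, soft_vote(list(probs[perm])), atol=1e-15)


class TestEnsemblePredict:
    def test_unanimous_members(self):
        ens = SoftVotingEnsemble([stub("deep", "deep", [1.0]), stub("SVM", "shallow", [1.0])])
        proba, label = ens.predict({"deep": np.zeros((1, 2)), "shallow": np.zeros((1, 2))})
        assert proba[0] == 1.0 and label[0] == 1

    def test_exact_half_goes_to_positive_class(self):
        ens = SoftVotingEnsemble([stub("deep", "deep", [0.49]), stub("SVM", "shallow", [0.51])])
        proba, label = ens.predict({"deep": np.zeros((1, 2)), "shallow": np.zeros((1, 2))})
        assert proba[0] == pytest.approx(0.5) and label[0] == 1

    def test_missing_feature_space_rejected(self):
        ens = SoftVotingEnsemble([stub("deep", "deep", [0.5])])
        with pytest.raises(FeatureMismatchError, match="deep"):
            ens.predict({"shallow": np.zeros((1, 2))})

    def test_label_string(self):
        ens = SoftVotingEnsemble(
            [stub("deep", "deep", [0.5]), stub("LightGBM", "shallow", [0.5]),
             stub("SVM", "shallow", [0.5])]
        )
        assert ens.label == "D+L+S"


class TestCombinationSearch:
    @staticmethod
    def _setup(probas):
        """probas: dict kind -> score vector over 8 validation samples."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        feats = {"deep": np.zeros((8, 2)), "shallow": np.zeros((8, 2))}
        deep = stub("deep", "deep", probas["deep"])
        shallow = [stub(k, "shallow", v) for k, v in probas.items() if k != "deep"]
        return deep, shallow, feats, y

    def test_degrading_member_is_excluded(self):
        deep, shallow, feats, y = self._setup(
            {
                "deep": [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1],
                "LightGBM": [0.9, 0.9, 0.8, 0.7, 0.3, 0.2, 0.1, 0.1],
                "SVM": [0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9],  # adversarial
            }
        )
        result = combination_search(deep, shallow, feats, y)
        assert result.best_label == "D+L"
        assert [lbl for lbl, _ in result.evaluated] == ["D+L", "D+L+S"]

    def test_single_shallow_member_single_candidate(self):
        deep, shallow, feats, y = self._setup(
            {"deep": [0.9] * 4 + [0.1] * 4, "SVM": [0.8] * 4 + [0.2] * 4}
        )
        result = combination_search(deep, shallow, feats, y)
        assert len(result.evaluated) == 1 and result.best_label == "D+S"

    def test_best_attains_max_of_its_own_table(self):
        rng = np.random.default_rng(0)
        deep, shallow, feats, y = self._setup(
            {k: rng.random(8) for k in ("deep", "LightGBM", "SVM", "GBDT", "XGBoost")}
        )
        result = combination_search(deep, shallow, feats, y)
        accs = {lbl: m["acc"] for lbl, m in result.evaluated}
        assert accs[result.best_label] == max(accs.values())

    def test_exhaustive_covers_all_subsets(self):
        deep, shallow, feats, y = self._setup(
            {"deep": [0.6] * 8, "LightGBM": [0.5] * 8, "SVM": [0.4] * 8, "GBDT": [0.55] * 8}
        )
        result = combination_search(deep, shallow, feats, y, exhaustive=True)
        assert len(result.evaluated) == 2**3 - 1

    def test_table_frame_schema(self):
        deep, shallow, feats, y = self._setup(
            {"deep": [0.9] * 4 + [0.1] * 4, "SVM": [0.8] * 4 + [0.2] * 4}
        )
        frame = combination_search(deep, shallow, feats, y).to_frame()
        assert list(frame.columns) == ["members", "auroc", "acc", "aupr", "f1", "recall", "precision"]
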