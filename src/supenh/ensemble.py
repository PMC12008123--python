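"""Soft-voting ensemble and the incremental member-combination search.

The ensemble prediction for a sample is the unweighted arithmetic mean of
its members' class-1 probabilities,

    p(y|x) = (1/N) * sum_i p_i(y|x),

so it always lies between the member minimum and maximum and is invariant
to member order.  Hard labels use threshold 0.5 with ties (exactly 0.5)
going to the positive class.

The combination search mirrors how the final model is assembled: starting
from the deep model, shallow members are added one at a time in validation-
accuracy rank order (deep+top1, deep+top2, ...), each candidate set is
scored by soft vote on validation data, and the best set is the accuracy
argmax with the smallest set winning ties.  An exhaustive-subset mode over
the ranked members is available but off by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from supenh.bank import ALGORITHM_LETTERS
from supenh.metrics import evaluate_scores
from supenh.models import FeatureMismatchError, TrainedModel

logger = logging.getLogger(__name__)


def soft_vote(probabilities: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-sample unweighted mean of member class-1 probabilities."""
    arrays = [np.asarray(p, dtype=float) for p in probabilities]
    if not arrays:
        raise ValueError("need at least one member probability vector")
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"member probability vectors differ in length: {sorted(lengths)}")
    stacked = np.vstack(arrays)
    if stacked.min() < 0.0 or stacked.max() > 1.0:
        raise ValueError("member probabilities must lie in [0, 1]")
    return stacked.mean(axis=0)


def member_label(member: TrainedModel) -> str:
    if member.space == "deep":
        return "D"
    return ALGORITHM_LETTERS.get(member.kind, member.kind[0].upper())


@dataclass
class SoftVotingEnsemble:
    """Ordered members, each bound to a named feature space.

    Deep members consume the "deep" feature matrix, shallow members the
    (selected) "shallow" matrix; ``predict`` takes a mapping from space
    name to feature matrix so each member sees its own inputs.
    """

    members: list[TrainedModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    @property
    def label(self) -> str:
        return "+".join(member_label(m) for m in self.members)

    def member_probabilities(self, features: dict[str, object]) -> list[np.ndarray]:
        probs = []
        for m in self.members:
            if m.space not in features:
                raise FeatureMismatchError(
                    f"no feature matrix supplied for space {m.space!r} (member {m.kind!r})"
                )
            probs.append(m.predict_proba(features[m.space]))
        return probs

    def predict(self, features: dict[str, object]) -> tuple[np.ndarray, np.ndarray]:
        """(probability, label) per sample; label 1 iff probability >= 0.5."""
        proba = soft_vote(self.member_probabilities(features))
        return proba, (proba >= 0.5).astype(int)


@dataclass
class CombinationSearchResult:
    """Validation metrics per evaluated member set, plus the winner."""

    evaluated: list[tuple[str, dict[str, float]]]
    best_label: str
    best_members: list[TrainedModel]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"members": label, **metrics} for label, metrics in self.evaluated]
        return pd.DataFrame(rows)[["members", "auroc", "acc", "aupr", "f1", "recall", "precision"]]


def combination_search(
    deep: TrainedModel,
    ranked_shallow: list[TrainedModel],
    features_val: dict[str, object],
    y_val,
    exhaustive: bool = False,
) -> CombinationSearchResult:
    """Search soft-vote member sets built around the deep model.

    Default mode evaluates the nested chain deep+top1, deep+top1+top2, ...
    with shallow members in rank order; ``exhaustive=True`` scores every
    non-empty subset of the ranked shallow members instead.  The winner
    maximizes validation accuracy, smallest member count first on ties.
    """
    if not ranked_shallow:
        raise ValueError("need at least one ranked shallow member")
    y_val = np.asarray(y_val, dtype=int)
    # member probabilities are fixed per model; compute once
    proba_cache: dict[str, np.ndarray] = {}
    for member in [deep, *ranked_shallow]:
        proba_cache[member.kind] = member.predict_proba(features_val[member.space])

    if exhaustive:
        candidate_sets = [
            [deep, *combo]
            for r in range(1, len(ranked_shallow) + 1)
            for combo in itertools.combinations(ranked_shallow, r)
        ]
    else:
        candidate_sets = [
            [deep, *ranked_shallow[: i + 1]] for i in range(len(ranked_shallow))
        ]

    evaluated: list[tuple[str, dict[str, float]]] = []
    best_idx, best_key = 0, None
    for idx, members in enumerate(candidate_sets):
        proba = soft_vote([proba_cache[m.kind] for m in members])
        report = evaluate_scores(y_val, proba)
        label = "+".join(member_label(m) for m in members)
        evaluated.append((label, report.as_dict()))
        key = (-report.acc, len(members))  # max ACC, then smallest set
        if best_key is None or key < best_key:
            best_key, best_idx = key, idx
    best_members = candidate_sets[best_idx]
    best_label = evaluated[best_idx][0]
    logger.info("combination search winner: %s (val ACC %.4f)", best_label, -best_key[0])
    return CombinationSearchResult(evaluated, best_label, best_members)
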