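"""F-score feature ranking and the stepwise top-k accuracy sweep.

The F-score of feature j compares between-class mean separation with
within-class spread:

    F(j) = [ (xbar+ - xbar)^2 + (xbar- - xbar)^2 ]
           / [ s2+(j) + s2-(j) ]

where xbar+/xbar-/xbar are the positive-class, negative-class and overall
means and s2+/s2- the unbiased within-class sample variances.  Larger is
more discriminative.  Features with zero pooled within-class variance but
separated means score +inf and sort first; globally constant features score
0.  Ties break deterministically by feature index.

The stepwise sweep re-sorts features by descending F-score, then trains a
baseline classifier on the top n = step, 2*step, ... features using an
internal stratified 80/20 split and records held-out accuracy; the chosen
dimensionality is the sweep argmax (earliest n on ties).  Selection is
meant for the interpretable shallow features only — the deep embedding
features go to the deep model unselected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    """Invalid inputs to ranking or selection."""


@dataclass
class FScoreRanking:
    """Per-feature F-scores plus the descending-score feature order."""

    scores: np.ndarray
    order: np.ndarray  # permutation of feature indices, best first
    feature_names: tuple[str, ...]
    class_means: dict[str, np.ndarray]  # "pos", "neg", "all"
    class_sizes: tuple[int, int]  # (n_pos, n_neg)

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in self.order],
                "score": self.scores[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


@dataclass
class SelectionSweep:
    """Accuracy trace of the stepwise top-n sweep and the chosen n."""

    step: int
    accuracies: list[tuple[int, float]]  # (n_features, held-out ACC)
    chosen_dim: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracies, columns=["n_features", "acc"])


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"f{i}" for i in range(arr.shape[1]))


def fscore_rank(X, y) -> FScoreRanking:
    """Rank features of X (samples x features) by F-score against binary y."""
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    if Xm.shape[0] != len(y):
        raise SelectionError("X and y have different numbers of samples")
    if set(np.unique(y)) != {0, 1}:
        raise SelectionError("both classes (0 and 1) must be present")
    pos, neg = Xm[y == 1], Xm[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise SelectionError("need >= 2 samples per class for within-class variances")
    m_pos, m_neg, m_all = pos.mean(axis=0), neg.mean(axis=0), Xm.mean(axis=0)
    numer = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numer / denom
    # zero within-class variance: separated means -> +inf; constant feature -> 0
    scores = np.where(denom == 0, np.where(numer > 0, np.inf, 0.0), scores)
    order = np.argsort(-scores, kind="stable")  # stable => index tie-break
    return FScoreRanking(
        scores=scores,
        order=order,
        feature_names=names,
        class_means={"pos": m_pos, "neg": m_neg, "all": m_all},
        class_sizes=(len(pos), len(neg)),
    )


def default_baseline_classifier(seed: int = 0):
    """The baseline used to score candidate feature subsets (a scaled SVM)."""
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))


def stepwise_select(
    X,
    y,
    ranking: FScoreRanking,
    step: int = 10,
    classifier=None,
    split_seed: int = 0,
) -> SelectionSweep:
    """Sweep top-n feature subsets (n = step, 2*step, ..., total) by held-out ACC.

    An internal stratified 80/20 split of (X, y) is made once; for each n
    the baseline classifier is retrained on the top-n columns and scored on
    the held-out part.  chosen_dim is the accuracy argmax, earliest n on
    ties.  The final n always equals the total feature count even when the
    total is not a multiple of step.
    """
    if step < 1:
        raise SelectionError(f"step must be >= 1, got {step}")
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    total = Xm.shape[1]
    base = classifier if classifier is not None else default_baseline_classifier(split_seed)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xm, y, train_size=0.8, stratify=y, random_state=split_seed, shuffle=True
    )
    ns = list(range(step, total + 1, step))
    if not ns or ns[-1] != total:
        ns.append(total)
    accuracies: list[tuple[int, float]] = []
    for n in ns:
        cols = ranking.top(n)
        model = clone(base)
        try:
            model.fit(X_tr[:, cols], y_tr)
        except Exception as exc:  # abort naming the offending subset size
            raise RuntimeError(f"baseline classifier failed at n={n}: {exc}") from exc
        acc = float((model.predict(X_te[:, cols]) == y_te).mean())
        accuracies.append((n, acc))
    accs = np.array([a for _, a in accuracies])
    chosen = accuracies[int(np.argmax(accs))][0]  # argmax returns first max
    return SelectionSweep(step=step, accuracies=accuracies, chosen_dim=chosen)


def apply_selection(X, ranking: FScoreRanking, n: int):
    """Keep the top-n ranked columns (in rank order), rows untouched."""
    Xm, names = _as_matrix(X)
    total = Xm.shape[1]
    if not 1 <= n <= total:
        raise SelectionError(f"n must be in [1, {total}], got {n}")
    cols = ranking.top(n)
    if isinstance(X, pd.DataFrame):
        return X.iloc[:, cols]
    return Xm[:, cols]
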