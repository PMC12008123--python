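"""Bank of classical classifiers over the selected shallow features.

Six algorithms are available — SVM, LightGBM, XGBoost, GBDT, RF and
ExtraTree — each fitted with library-default hyperparameters and a pinned
seed on one thread, so training is bitwise reproducible.  The SVM is wrapped
with a standard scaler and emits probabilities via Platt calibration
(``probability=True``).  After training, members are ranked by validation
accuracy (ties broken by AUROC, then name) to drive the ensemble
combination search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from supenh.metrics import roc_pr_curves
from supenh.models import TrainedModel

logger = logging.getLogger(__name__)

ALGORITHM_NAMES = ("SVM", "LightGBM", "XGBoost", "GBDT", "RF", "ExtraTree")

#: Single-letter labels used in combination-search tables ("D" is the deep model).
ALGORITHM_LETTERS = {
    "SVM": "S",
    "LightGBM": "L",
    "XGBoost": "X",
    "GBDT": "G",
    "RF": "R",
    "ExtraTree": "E",
}


class BankConfigError(ValueError):
    """Unknown algorithm name or empty bank."""


@dataclass(frozen=True)
class ShallowBankConfig:
    """Which algorithms to train and with what seed/overrides."""

    algorithms: tuple[str, ...] = ALGORITHM_NAMES
    seed: int = 0
    overrides: dict = field(default_factory=dict)  # algorithm -> kwargs

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise BankConfigError("algorithm list must be non-empty")
        unknown = set(self.algorithms) - set(ALGORITHM_NAMES)
        if unknown:
            raise BankConfigError(
                f"unknown algorithms {sorted(unknown)!r}; choose from {ALGORITHM_NAMES}"
            )


def make_estimator(name: str, seed: int, **overrides):
    """Fresh unfitted estimator for one bank algorithm."""
    if name == "SVM":
        # Platt-calibrated probabilities (the SVM's standard calibration route)
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(
                SVC(kernel="rbf", random_state=seed, **overrides), ensemble=False
            ),
        )
    if name == "LightGBM":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **overrides)
    if name == "XGBoost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **overrides
        )
    if name == "GBDT":
        return GradientBoostingClassifier(random_state=seed, **overrides)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **overrides)
    if name == "ExtraTree":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **overrides)
    raise BankConfigError(f"unknown algorithm {name!r}")


def train_shallow_bank(
    X_train, y_train, config: ShallowBankConfig | None = None
) -> dict[str, TrainedModel]:
    """Fit every requested algorithm on the selected shallow features.

    A failing algorithm is logged and omitted; the others are unaffected.
    """
    config = config or ShallowBankConfig()
    if isinstance(X_train, pd.DataFrame):
        names = tuple(map(str, X_train.columns))
        Xm = X_train.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_train, dtype=float)
        names = tuple(f"f{i}" for i in range(Xm.shape[1]))
    y = np.asarray(y_train, dtype=int)
    bank: dict[str, TrainedModel] = {}
    for name in config.algorithms:
        est = make_estimator(name, config.seed, **config.overrides.get(name, {}))
        try:
            est.fit(Xm, y)
        except Exception as exc:
            logger.error("algorithm %s failed to train: %s", name, exc)
            continue
        bank[name] = TrainedModel(
            kind=name,
            space="shallow",
            feature_names=names,
            estimator=est,
            metadata={"seed": config.seed},
        )
    if not bank:
        raise RuntimeError("every bank algorithm failed to train")
    return bank


def rank_shallow_bank(
    models: dict[str, TrainedModel], X_val, y_val
) -> list[tuple[str, float, float]]:
    """Order bank members by validation accuracy, descending.

    Returns (name, acc, auroc) tuples; exact accuracy ties are broken by
    AUROC (descending), then algorithm name, so the order is total and
    deterministic.
    """
    if not models:
        raise BankConfigError("empty model bank")
    y = np.asarray(y_val, dtype=int)
    scored = []
    for name, model in models.items():
        proba = model.predict_proba(X_val)
        acc = float(((proba >= 0.5).astype(int) == y).mean())
        auroc, _ = roc_pr_curves(y, proba)
        scored.append((name, acc, auroc))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return scored
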