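"""Common trained-model wrapper with a feature-space guard.

Every trained member of the ensemble — the deep network and each shallow
algorithm — is wrapped so that prediction (a) always returns the
probability of class 1 as a flat vector in [0, 1], and (b) refuses feature
matrices whose columns do not match the ones it was fitted on, instead of
silently misaligning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FeatureMismatchError(ValueError):
    """Prediction-time features do not match the fitted feature space."""


@dataclass
class TrainedModel:
    """A fitted classifier bound to a named feature space.

    ``estimator`` must expose ``predict_proba`` returning either a flat
    class-1 probability vector or an (n, 2) column matrix.
    """

    kind: str  # "deep" or the shallow algorithm name
    space: str  # "deep" | "shallow"
    feature_names: tuple[str, ...]
    estimator: object
    metadata: dict = field(default_factory=dict)

    def _check(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = tuple(map(str, X.columns))
            if cols != self.feature_names:
                raise FeatureMismatchError(
                    f"model {self.kind!r} was fitted on {len(self.feature_names)} named "
                    f"features; got a matrix with mismatched columns "
                    f"(first difference near index "
                    f"{next((i for i, (a, b) in enumerate(zip(cols, self.feature_names)) if a != b), min(len(cols), len(self.feature_names)))})"
                )
            return X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise FeatureMismatchError(
                f"model {self.kind!r} expects {len(self.feature_names)} features, "
                f"got shape {X.shape}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Probability of class 1 per row, guaranteed in [0, 1]."""
        arr = self._check(X)
        with warnings.catch_warnings():
            # lightgbm invents feature names even for array fits; harmless
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            proba = np.asarray(self.estimator.predict_proba(arr), dtype=float)
        if proba.ndim == 2:
            proba = proba[:, 1]
        return np.clip(proba, 0.0, 1.0)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Hard labels: 1 iff probability >= threshold."""
        return (self.predict_proba(X) >= threshold).astype(int)
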