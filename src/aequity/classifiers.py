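"""Classifier backends behind a minimal fit/predict_proba contract.

The audit itself never needs a classifier; these backends exist for the
end-to-end experiments (train on a curated cohort, score a frozen test
set, evaluate the fairness panel). Scores are probabilities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

__all__ = ["Classifier", "make_classifier", "BACKENDS"]

BACKENDS = ("logistic", "gbt", "mlp")


@dataclass
class Classifier:
    """fit/predict_proba wrapper with a decision threshold."""

    backend: str
    model: Any = field(repr=False)
    threshold: float = 0.5
    _fitted: bool = False

    def fit(self, latents: np.ndarray, labels: np.ndarray) -> "Classifier":
        self.model.fit(np.asarray(latents), np.asarray(labels, dtype=int))
        self._fitted = True
        return self

    def predict_proba(self, latents: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier is not fitted")
        p = self.model.predict_proba(np.asarray(latents))[:, 1]
        return np.clip(p, 0.0, 1.0)


def make_classifier(backend: str = "logistic", seed: int = 0, threshold: float = 0.5) -> Classifier:
    if backend == "logistic":
        model = LogisticRegression(max_iter=2000)
    elif backend == "gbt":
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(
            n_estimators=200,
            num_leaves=15,
            learning_rate=0.1,
            random_state=seed,
            verbosity=-1,
            deterministic=True,
            force_row_wise=True,
        )
    elif backend == "mlp":
        model = MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=500, random_state=seed, early_stopping=False
        )
    else:
        raise ValueError(f"unknown backend '{backend}' (have {BACKENDS})")
    return Classifier(backend=backend, model=model, threshold=threshold)
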