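"""Classical machine-learning baseline harness (SVM, RF, AdaBoost, k-NN, MLP).

Each baseline is fitted on flattened feature vectors of the training windows
and scored on the test windows, mirroring how the sequence model is
benchmarked against standard classifiers.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["baseline_suite"]


def _models(seed: int) -> dict:
    return {
        "svm": make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "adaboost": AdaBoostClassifier(random_state=seed),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier()),
        "mlp": make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                          random_state=seed),
        ),
    }


def baseline_suite(features: np.ndarray, labels: np.ndarray,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   seed: int = 0) -> dict[str, float]:
    """Accuracy table on a fixed split; features flattened per window."""
    X = np.asarray(features, dtype=float).reshape(len(features), -1)
    y = np.asarray(labels)
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("degenerate split: fewer than two classes in training")
    table = {}
    for name, model in _models(seed).items():
        model.fit(X[train_idx], y[train_idx])
        table[name] = float(np.mean(model.predict(X[test_idx]) == y[test_idx]))
    return table
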