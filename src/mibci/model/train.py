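"""Training, Monte-Carlo-dropout inference, and checkpointing for the S4D net.

The optimizer is Adam with two parameter groups: the SSM parameters (A, dt)
at a reduced rate with no weight decay, everything else at the base rate —
standard practice for structured state-space models. Early stopping tracks
validation accuracy; the best parameters are restored at the end.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .autograd import Adam, softmax
from .s4d import S4DConfig, S4DNetwork

__all__ = ["TrainConfig", "PredictionResult", "S4DClassifier",
           "train_network", "mc_dropout_predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    ssm_learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 60
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.ssm_learning_rate <= 0:
            raise ValueError("learning rates must be > 0")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class PredictionResult:
    """Monte-Carlo-dropout prediction for one batch of windows."""

    probs: np.ndarray              # deterministic (dropout off) per-class probs
    mc_mean: np.ndarray
    mc_sd: np.ndarray
    predictive_entropy: np.ndarray
    n_passes: int


def _accuracy(net: S4DNetwork, X: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> float:
    correct = 0
    for i in range(0, len(X), batch_size):
        probs = net.predict_proba(X[i:i + batch_size])
        correct += int(np.sum(np.argmax(probs, axis=1) == y[i:i + batch_size]))
    return correct / len(X)


def train_network(net: S4DNetwork, X_train: np.ndarray, y_train: np.ndarray,
                  X_val: np.ndarray, y_val: np.ndarray,
                  cfg: TrainConfig = TrainConfig()) -> dict:
    """Minimize cross-entropy; early-stop on validation accuracy.

    Returns a history dict; the network is left holding the best-validation
    parameters. ``y_*`` are integer class indices.
    """
    if len(np.unique(y_train)) < net.config.num_classes:
        raise ValueError("a class is missing from the training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.param_groups(cfg.learning_rate, cfg.ssm_learning_rate))
    history = {"loss": [], "val_accuracy": []}
    best_acc, best_state, since_best = -1.0, net.state_dict(), 0
    n = len(X_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = net.forward(X_train[idx], training=True, rng=rng)
            loss = logits.softmax_cross_entropy(y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_acc = _accuracy(net, X_val, y_val)
        history["loss"].append(epoch_loss / n)
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, net.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.early_stopping_patience:
                break
    net.load_state_dict(best_state)
    history["best_val_accuracy"] = best_acc
    return history


def mc_dropout_predict(net: S4DNetwork, X: np.ndarray, n_passes: int = 20,
                       seed: int = 0) -> PredictionResult:
    """Mean and spread over ``n_passes`` stochastic forward passes.

    Dropout stays enabled at inference; with dropout_rate 0 the passes are
    identical and the spread is exactly zero.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    rng = np.random.default_rng(seed)
    use_dropout = net.config.dropout_rate > 0
    passes = np.stack([
        net.predict_proba(X, training=use_dropout, rng=rng)
        for _ in range(n_passes)
    ])
    mc_mean = passes.mean(axis=0)
    mc_sd = passes.std(axis=0)
    ent = -np.sum(mc_mean * np.log2(mc_mean + 1e-300), axis=1)
    return PredictionResult(
        probs=net.predict_proba(X), mc_mean=mc_mean, mc_sd=mc_sd,
        predictive_entropy=ent, n_passes=n_passes,
    )


def save_checkpoint(path, net: S4DNetwork, classes: list[str],
                    feature_spec_hash: str = "", history: dict | None = None,
                    csp: dict | None = None,
                    normalization_stats: dict | None = None) -> None:
    """Single-file .npz archive: config JSON + parameter arrays + metadata."""
    meta = {
        "config": asdict(net.config), "n_features": net.n_features,
        "classes": list(classes), "feature_spec_hash": feature_spec_hash,
        "history": history or {}, "csp": csp,
        "normalization_stats": None if normalization_stats is None else {
            k: {"mean": np.asarray(v[0]).tolist(),
                "sd": np.asarray(v[1]).tolist()}
            for k, v in normalization_stats.items()},
    }
    arrays = {f"param/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[S4DNetwork, dict]:
    """Rebuild the network and return (network, metadata)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    net = S4DNetwork(S4DConfig(**meta["config"]), meta["n_features"])
    net.load_state_dict(state)
    if meta.get("normalization_stats"):
        meta["normalization_stats"] = {
            k: (np.array(v["mean"]), np.array(v["sd"]))
            for k, v in meta["normalization_stats"].items()}
    return net, meta


class S4DClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style front end over the S4D network.

    ``fit(X, y)`` expects X of shape (n_windows, n_feature_channels,
    n_times). A validation split for early stopping is carved from the
    training data (stratified, ``val_fraction``) unless explicit
    ``X_val``/``y_val`` are passed to ``fit``.
    """

    def __init__(self, hidden_dim: int = 256, num_layers: int = 3,
                 dropout_rate: float = 0.4, state_dim: int = 64,
                 bidirectional: bool = True, learning_rate: float = 1e-3,
                 ssm_learning_rate: float = 1e-4, batch_size: int = 32,
                 max_epochs: int = 60, early_stopping_patience: int = 10,
                 val_fraction: float = 0.15, seed: int = 0):
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        self.dropout_rate = dropout_rate
        self.state_dim = state_dim
        self.bidirectional = bidirectional
        self.learning_rate = learning_rate
        self.ssm_learning_rate = ssm_learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        cfg = S4DConfig(
            num_classes=len(self.classes_), hidden_dim=self.hidden_dim,
            num_layers=self.num_layers, dropout_rate=self.dropout_rate,
            state_dim=self.state_dim, bidirectional=self.bidirectional,
        )
        self.network_ = S4DNetwork(cfg, n_features=X.shape[1], seed=self.seed)
        if X_val is None:
            rng = np.random.default_rng(self.seed + 1)
            val_mask = np.zeros(len(y_idx), dtype=bool)
            for c in range(len(self.classes_)):
                rows = np.flatnonzero(y_idx == c)
                k = max(int(round(self.val_fraction * len(rows))), 1)
                val_mask[rng.choice(rows, size=k, replace=False)] = True
            X_val, y_val_idx = X[val_mask], y_idx[val_mask]
            X, y_idx = X[~val_mask], y_idx[~val_mask]
        else:
            y_val_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        self.history_ = train_network(
            self.network_, X, y_idx, X_val, y_val_idx,
            TrainConfig(
                learning_rate=self.learning_rate,
                ssm_learning_rate=self.ssm_learning_rate,
                batch_size=self.batch_size, max_epochs=self.max_epochs,
                early_stopping_patience=self.early_stopping_patience,
                seed=self.seed,
            ),
        )
        return self

    def predict_proba(self, X):
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        out = []
        for i in range(0, len(X), 64):
            out.append(self.network_.predict_proba(X[i:i + 64]))
        return np.concatenate(out)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def predict_with_uncertainty(self, X, n_passes: int = 20) -> PredictionResult:
        return mc_dropout_predict(self.network_, np.asarray(X, dtype=float),
                                  n_passes=n_passes, seed=self.seed)
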