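"""Conformational-state classifiers: a 1D-CNN estimator plus decision-tree
and random-forest baselines.

`Conv1DClassifier` follows the scikit-learn estimator contract (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``) on 2D feature matrices of
flattened per-residue coordinates. Internally the features are treated as a
length-3R sequence with one channel, standardized by a fixed affine first
layer, and passed through convolution/pooling blocks into a softmax head.
The trained network exposes per-layer weights and activations, logit
gradients, and epsilon-rule relevance propagation for the explanation
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from . import network as nn
from .synthdata import STATES

#: Fixed class order used throughout: (active, intermediate, inactive).
STATE_ORDER = STATES


@dataclass
class ModelConfig:
    """Architecture and optimization settings for the 1D-CNN."""

    conv_blocks: tuple = ((24, 7, 3), (48, 7, 3))
    dense_units: tuple = (64,)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 25
    batch_size: int = 64
    early_stop_patience: int = 5
    seed: int = 0

    def validate(self, input_length: int | None = None) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout={self.dropout} must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for filters, kernel, pool in self.conv_blocks:
            if kernel < 1:
                raise ValueError(f"kernel size {kernel} must be >= 1")
            if input_length is not None and kernel > input_length:
                raise ValueError(
                    f"kernel size {kernel} exceeds input length "
                    f"{input_length}")


def split_data(X, y, val_fraction=0.2, seed=0):
    """Stratified train/validation split; every class present in both."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to split")
    X_tr, X_va, y_tr, y_va = train_test_split(
        np.asarray(X), y, test_size=val_fraction, stratify=y,
        random_state=seed)
    return (X_tr, y_tr), (X_va, y_va)


class Conv1DClassifier(BaseEstimator, ClassifierMixin):
    """1D convolutional softmax classifier over flattened coordinates.

    Parameters
    ----------
    conv_blocks : sequence of (filters, kernel_size, pool_size)
    dense_units : sequence of int
    dropout : float
        Dropout after each dense hidden layer.
    class_weight : dict or None
        Per-class loss multipliers (weighted-loss mitigation); sample losses
        are scaled by their class's weight.
    standardize : bool
        Fit a per-feature affine standardization on the training data and
        apply it as the (fixed) first network layer.
    val_fraction : float
        Internal stratified holdout used only for early stopping.
    epochs, batch_size, learning_rate, early_stop_patience, random_state :
        Usual optimization knobs; all randomness flows from random_state.
    """

    def __init__(self, conv_blocks=((24, 7, 3), (48, 7, 3)),
                 dense_units=(64,), dropout=0.2, learning_rate=1e-3,
                 epochs=25, batch_size=64, early_stop_patience=5,
                 val_fraction=0.1, class_weight=None, standardize=True,
                 use_bias=False, random_state=0):
        self.use_bias = use_bias
        self.conv_blocks = conv_blocks
        self.dense_units = dense_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stop_patience = early_stop_patience
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.standardize = standardize
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _encode_labels(self, y):
        y = np.asarray(y)
        present = set(np.unique(y).tolist())
        if present <= set(STATE_ORDER):
            classes = [c for c in STATE_ORDER if c in present]
        else:
            classes = sorted(present)
        self.classes_ = np.asarray(classes)
        lut = {c: i for i, c in enumerate(classes)}
        return np.asarray([lut[v] for v in y], dtype=np.int64)

    def _build(self, n_features, n_classes, mu, sigma, rng):
        layers = []
        if self.standardize:
            w = (1.0 / sigma).astype(np.float32)
            b = (-mu / sigma).astype(np.float32)
            layers.append(nn.ElementwiseAffine(w[None, :, None] * np.ones(
                (1, n_features, 1), np.float32),
                b[None, :, None] * np.ones((1, n_features, 1), np.float32)))
        length, channels = n_features, 1
        for filters, kernel, pool in self.conv_blocks:
            if kernel > length:
                raise ValueError(
                    f"kernel size {kernel} exceeds sequence length {length}")
            layers.append(nn.Conv1D(channels, filters, kernel, rng,
                                    use_bias=self.use_bias))
            length = length - kernel + 1
            layers.append(nn.ReLU())
            if pool > 1:
                layers.append(nn.MaxPool1D(pool))
                length //= pool
            channels = filters
        layers.append(nn.Flatten())
        width = length * channels
        for units in self.dense_units:
            layers.append(nn.Dense(width, units, rng,
                                    use_bias=self.use_bias))
            layers.append(nn.ReLU())
            if self.dropout > 0:
                layers.append(nn.Dropout(self.dropout, rng))
            width = units
        layers.append(nn.Dense(width, n_classes, rng,
                                use_bias=self.use_bias))
        return nn.SequentialNet(layers)

    def _as_sequence(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError("X must be 2D (samples x features)")
        return X[:, :, None]

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        y_idx = self._encode_labels(y)
        n, n_features = X.shape
        self.n_features_in_ = n_features
        rng = np.random.default_rng(self.random_state)

        if self.class_weight is not None:
            missing = [c for c in self.classes_
                       if c not in self.class_weight]
            if missing:
                raise ValueError(f"class_weight missing classes {missing}")
            w_by_class = np.asarray(
                [self.class_weight[c] for c in self.classes_],
                dtype=np.float32)
        else:
            w_by_class = np.ones(len(self.classes_), dtype=np.float32)

        # Internal holdout for early stopping (never the external split).
        use_val = (self.early_stop_patience > 0 and self.val_fraction > 0
                   and np.bincount(y_idx).min() >= 2 and n >= 20)
        if use_val:
            idx_tr, idx_va = train_test_split(
                np.arange(n), test_size=self.val_fraction, stratify=y_idx,
                random_state=int(rng.integers(2**31)))
        else:
            idx_tr, idx_va = np.arange(n), np.array([], dtype=int)

        mu = X[idx_tr].mean(axis=0)
        sigma = X[idx_tr].std(axis=0)
        sigma[sigma < 1e-8] = 1.0
        self.net_ = self._build(n_features, len(self.classes_), mu, sigma,
                                rng)
        opt = nn.Adam(self.net_, lr=self.learning_rate)

        Xtr = self._as_sequence(X[idx_tr])
        ytr = y_idx[idx_tr]
        Xva = self._as_sequence(X[idx_va]) if len(idx_va) else None
        yva = y_idx[idx_va] if len(idx_va) else None

        best_loss, best_state, patience = np.inf, None, 0
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(ytr))
            losses = []
            for start in range(0, len(order), self.batch_size):
                sel = order[start:start + self.batch_size]
                logits = self.net_.forward(Xtr[sel], training=True)
                loss, grad = nn.weighted_cross_entropy(
                    logits, ytr[sel], w_by_class[ytr[sel]])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {epoch}; "
                        f"lr={self.learning_rate}, batch={len(sel)}")
                self.net_.backward(grad)
                opt.step()
                losses.append(loss)
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if Xva is not None:
                logits = self.net_.forward(Xva, training=False)
                val_loss, _ = nn.weighted_cross_entropy(
                    logits, yva, w_by_class[yva])
                record["val_loss"] = val_loss
                record["val_acc"] = float(
                    (logits.argmax(axis=1) == yva).mean())
                if val_loss < best_loss - 1e-5:
                    best_loss, patience = val_loss, 0
                    best_state = [p.copy() for layer in self.net_.layers
                                  for p, _ in layer.params_and_grads()]
                else:
                    patience += 1
            self.history_.append(record)
            if Xva is not None and patience >= self.early_stop_patience:
                break
        if best_state is not None:
            pairs = [p for layer in self.net_.layers
                     for p, _ in layer.params_and_grads()]
            for p, best in zip(pairs, best_state):
                p[...] = best
        return self

    # -- inference ---------------------------------------------------------

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_logits(self._as_sequence(X))

    def predict_proba(self, X):
        return nn.softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, directory):
        """Write a self-describing checkpoint: config.json + weights.npz
        (+ the training log as JSON lines)."""
        import json
        from pathlib import Path
        check_is_fitted(self, "net_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"params": {k: v for k, v in self.get_params().items()},
                "classes": [str(c) for c in self.classes_],
                "n_features_in": int(self.n_features_in_)}
        (directory / "config.json").write_text(json.dumps(meta, indent=1))
        arrays = {}
        for i, layer in enumerate(self.net_.layers):
            for name in ("W", "b", "w"):
                if hasattr(layer, name):
                    arrays[f"{i}.{name}"] = getattr(layer, name)
        np.savez(directory / "weights.npz", **arrays)
        if getattr(self, "history_", None):
            lines = "\n".join(json.dumps(rec) for rec in self.history_)
            (directory / "train_log.jsonl").write_text(lines + "\n")
        return directory

    @classmethod
    def load(cls, directory):
        """Rebuild a fitted classifier from :meth:`save` output."""
        import json
        from pathlib import Path
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        params = meta["params"]
        for key in ("conv_blocks", "dense_units"):
            params[key] = tuple(tuple(b) if isinstance(b, list) else b
                                for b in params[key])
        clf = cls(**params)
        clf.classes_ = np.asarray(meta["classes"])
        clf.n_features_in_ = meta["n_features_in"]
        rng = np.random.default_rng(clf.random_state)
        mu = np.zeros(clf.n_features_in_, dtype=np.float32)
        sigma = np.ones(clf.n_features_in_, dtype=np.float32)
        clf.net_ = clf._build(clf.n_features_in_, len(clf.classes_),
                              mu, sigma, rng)
        with np.load(directory / "weights.npz") as data:
            for key in data.files:
                idx, name = key.split(".")
                getattr(clf.net_.layers[int(idx)], name)[...] = data[key]
        clf.history_ = []
        return clf

    def class_index(self, label) -> int:
        idx = np.where(self.classes_ == label)[0]
        if not len(idx):
            raise ValueError(f"unknown class {label!r}")
        return int(idx[0])

    def input_gradient(self, X, target) -> np.ndarray:
        """d logit[target] / d input features (chain rule through the
        internal standardization), shape (n, n_features)."""
        check_is_fitted(self, "net_")
        g = self.net_.input_gradient(self._as_sequence(X),
                                     self.class_index(target))
        return g[:, :, 0]

    def relevance(self, X, target, eps_scale=1e-6):
        """Epsilon-rule LRP input relevances toward ``target``'s logit.

        Returns (relevances (n, n_features), target logits (n,)).
        """
        check_is_fitted(self, "net_")
        R, logit = self.net_.relprop(self._as_sequence(X),
                                     self.class_index(target),
                                     eps_scale=eps_scale)
        return R[:, :, 0], logit


def train_cnn(train, cfg: ModelConfig, class_weights=None):
    """Fit a :class:`Conv1DClassifier` from a (X, y) pair and ModelConfig."""
    X, y = train
    cfg.validate(input_length=np.asarray(X).shape[1])
    clf = Conv1DClassifier(
        conv_blocks=cfg.conv_blocks, dense_units=cfg.dense_units,
        dropout=cfg.dropout, learning_rate=cfg.learning_rate,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        early_stop_patience=cfg.early_stop_patience,
        class_weight=class_weights, random_state=cfg.seed)
    return clf.fit(X, y)


def train_tree(train, depth_limit=None, seed=0) -> DecisionTreeClassifier:
    """CART decision tree baseline (Gini impurity splits)."""
    X, y = train
    tree = DecisionTreeClassifier(max_depth=depth_limit, random_state=seed)
    return tree.fit(X, y)


def gini_importance(model) -> np.ndarray:
    """Total normalized impurity decrease per feature (sums to 1)."""
    return model.feature_importances_


def train_forest(train, n_trees=100, seed=0,
                 bootstrap=True) -> RandomForestClassifier:
    """Bagged random-forest baseline with random feature subsets."""
    X, y = train
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    bootstrap=bootstrap)
    return forest.fit(X, y)
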