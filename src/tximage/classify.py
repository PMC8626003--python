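"""CNN image classifier and the classical baselines (RF, SVM, FCNN).

The CNN is the two-conv-block architecture used throughout the pipeline:

    input -> [conv(32, 3x3) + ReLU + maxpool(2x2) + dropout]
          -> [conv(64, 3x3) + ReLU + maxpool(2x2) + dropout]
          -> flatten -> dense(256) + ReLU -> dense(1) + sigmoid

trained with Adam on class-weighted binary cross entropy and early stopping
on a validation split, which is how severe class imbalance (e.g. 490 cases
vs 60 controls) is handled. Baselines consume raw feature vectors: random
forest and SVM with library defaults, and a small fully connected network
(200-200-10-1, dropout 0.5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.utils.class_weight import compute_class_weight as _sk_class_weight

from . import nn
from .image import ImageStack

__all__ = [
    "CNNConfig",
    "FCNNConfig",
    "TrainedClassifier",
    "compute_class_weights",
    "build_cnn",
    "train_cnn",
    "train_baseline",
    "predict",
]

log = logging.getLogger(__name__)


@dataclass
class CNNConfig:
    input_size: int = 380
    conv_depths: tuple[int, ...] = (32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.25
    dense_units: int = 256
    epochs: int = 500
    early_stopping_patience: int = 20
    validation_fraction: float = 0.1
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "binary_cross_entropy"
    seed: int = 0

    def __post_init__(self):
        if self.pool_size != 2:
            raise ValueError("only 2x2 pooling is supported")
        if any(d < 1 for d in self.conv_depths) or self.dense_units < 1:
            raise ValueError("layer sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class FCNNConfig:
    hidden_units: tuple[int, ...] = (200, 200, 10)
    dropout_rate: float = 0.5
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 20
    validation_fraction: float = 0.1
    seed: int = 0


@dataclass
class TrainedClassifier:
    kind: str  # cnn | rf | svm | fcnn
    model: object
    history: dict = field(default_factory=dict)
    class_weights: dict | None = None
    config: object | None = None

    def predict_proba(self, X) -> np.ndarray:
        if self.kind in ("rf", "svm"):
            return self.model.predict_proba(X)[:, 1]
        if self.kind == "cnn":
            X = X.as_nhwc() if isinstance(X, ImageStack) else np.asarray(X)
            if X.ndim == 3:
                X = X[..., None]
            return self.model.predict_proba(X)
        return self.model.predict_proba(np.asarray(X, dtype=np.float32))


def compute_class_weights(labels) -> dict[int, float]:
    """Balanced class weights: w_c = n_samples / (2 * n_c)."""
    y = np.asarray(labels).astype(int).ravel()
    classes = np.unique(y)
    if set(classes.tolist()) != {0, 1}:
        raise ValueError(f"need both classes present, found labels {classes.tolist()}")
    w = _sk_class_weight("balanced", classes=classes, y=y)
    return {int(c): float(wi) for c, wi in zip(classes, w)}


def _min_input_size(cfg: CNNConfig) -> int:
    # invert: two rounds of (s - k + 1) // 2 must leave at least 1
    s = 1
    for _ in cfg.conv_depths:
        s = 2 * s + cfg.kernel_size - 1
    return s


def build_cnn(cfg: CNNConfig) -> nn.Network:
    """Instantiate the two-conv-block CNN for ``cfg.input_size`` square inputs."""
    s = cfg.input_size
    for _ in cfg.conv_depths:
        s = (s - cfg.kernel_size + 1) // 2
    if s < 1:
        raise ValueError(
            f"input_size {cfg.input_size} too small for {len(cfg.conv_depths)} "
            f"conv+pool blocks; minimum is {_min_input_size(cfg)}"
        )
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    size = cfg.input_size
    for depth in cfg.conv_depths:
        layers += [
            nn.Conv2D(in_ch, depth, cfg.kernel_size, rng),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Dropout(cfg.dropout_rate),
        ]
        size = (size - cfg.kernel_size + 1) // 2
        in_ch = depth
    layers += [
        nn.Flatten(),
        nn.Dense(in_ch * size * size, cfg.dense_units, rng),
        nn.ReLU(),
        nn.Dense(cfg.dense_units, 1, rng),
    ]
    return nn.Network(layers)


MIN_VAL_PER_CLASS = 5  # below this the monitored loss is too noisy to trust


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    """Indices (train, val); val holds ~frac of each class.

    Returns an empty validation set when any class would contribute fewer
    than MIN_VAL_PER_CLASS samples: early stopping on a couple of minority
    samples restores essentially random weights, which is worse than
    training for the full epoch budget.
    """
    val = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_val = max(1, int(round(frac * idx.size)))
        if n_val < MIN_VAL_PER_CLASS:
            return np.arange(y.size), np.array([], dtype=int)
        val.extend(rng.permutation(idx)[:n_val])
    val = np.sort(np.array(val, dtype=int))
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


def _fit_network(net, X, y, *, epochs, batch_size, lr, w_pos, w_neg, patience, val_frac, seed):
    rng = np.random.default_rng(seed)
    history = {"loss": [], "val_loss": []}
    if epochs <= 0:
        return history
    if val_frac > 0 and y.size >= 10 and len(np.unique(y)) == 2:
        tr, va = _stratified_split(y, val_frac, rng)
    else:
        tr, va = np.arange(y.size), np.array([], dtype=int)
    opt = nn.Adam(net.params, net.grads, lr=lr)
    best_val = np.inf
    best_weights = None
    wait = 0
    for epoch in range(epochs):
        order = rng.permutation(tr)
        losses = []
        for i in range(0, order.size, batch_size):
            b = order[i : i + batch_size]
            z = net.forward_logits(X[b], train=True, rng=rng)
            loss, dz = nn.weighted_bce_with_logits(z, y[b], w_pos, w_neg)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}; reduce the learning rate")
            net.backward(dz)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if va.size:
            zv = net.forward_logits(X[va])
            val_loss, _ = nn.weighted_bce_with_logits(zv, y[va], w_pos, w_neg)
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-6:
                best_val, best_weights, wait = val_loss, net.get_weights(), 0
            else:
                wait += 1
                if wait >= patience:
                    log.info("early stopping at epoch %d (best val loss %.4f)", epoch, best_val)
                    break
    if best_weights is not None:
        net.set_weights(best_weights)
    return history


def train_cnn(
    model: nn.Network,
    images: ImageStack,
    labels,
    cfg: CNNConfig,
    weights: dict[int, float] | None = None,
) -> TrainedClassifier:
    """Train the CNN with class-weighted BCE, Adam and early stopping."""
    y = np.asarray(labels).astype(int).ravel()
    if weights is None and cfg.epochs > 0:
        weights = compute_class_weights(y)
    X = images.as_nhwc().astype(np.float32)
    history = _fit_network(
        model,
        X,
        y,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        w_pos=weights[1] if weights else 1.0,
        w_neg=weights[0] if weights else 1.0,
        patience=cfg.early_stopping_patience,
        val_frac=cfg.validation_fraction,
        seed=cfg.seed + 1,
    )
    return TrainedClassifier("cnn", model, history, weights, cfg)


def predict(clf: TrainedClassifier, inputs) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels; positive iff probability > 0.5.

    A probability of exactly 0.5 is classified as control (the decision rule
    is defined only by strict inequalities; the tie goes to the negative
    class).
    """
    proba = clf.predict_proba(inputs)
    return proba, (proba > 0.5).astype(int)


def build_fcnn(n_features: int, cfg: FCNNConfig) -> nn.Network:
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    prev = n_features
    for units in cfg.hidden_units:
        layers += [nn.Dense(prev, units, rng), nn.ReLU(), nn.Dropout(cfg.dropout_rate)]
        prev = units
    layers.append(nn.Dense(prev, 1, rng))
    return nn.Network(layers)


def train_baseline(kind: str, features, labels, cfg=None, seed: int = 0) -> TrainedClassifier:
    """Fit a classical baseline on samples x features vectors.

    rf and svm use the library defaults (resolved hyperparameters are logged
    for auditability); fcnn follows FCNNConfig.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int).ravel()
    if kind == "rf":
        model = RandomForestClassifier(random_state=seed).fit(X, y)
        log.info("rf resolved params: %s", json.dumps(model.get_params(), default=str))
        return TrainedClassifier("rf", model)
    if kind == "svm":
        model = SVC(probability=True, random_state=seed).fit(X, y)
        log.info("svm resolved params: %s", json.dumps(model.get_params(), default=str))
        return TrainedClassifier("svm", model)
    if kind == "fcnn":
        cfg = cfg or FCNNConfig(seed=seed)
        net = build_fcnn(X.shape[1], cfg)
        weights = compute_class_weights(y) if len(np.unique(y)) == 2 else {0: 1.0, 1: 1.0}
        history = _fit_network(
            net,
            X.astype(np.float32),
            y,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            w_pos=weights[1],
            w_neg=weights[0],
            patience=cfg.early_stopping_patience,
            val_frac=cfg.validation_fraction,
            seed=cfg.seed + 1,
        )
        return TrainedClassifier("fcnn", net, history, weights, cfg)
    raise ValueError(f"unknown baseline kind {kind!r}")


def save_checkpoint(clf: TrainedClassifier, out_dir, extra: dict | None = None) -> Path:
    """Write config JSON + weights (npz) + a model card recording provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(clf.config) if clf.config is not None else {}
    (out_dir / "config.json").write_text(json.dumps({"kind": clf.kind, "config": cfg}, default=str))
    if isinstance(clf.model, nn.Network):
        np.savez(out_dir / "weights.npz", *clf.model.get_weights())
    else:
        import pickle

        (out_dir / "model.pkl").write_bytes(pickle.dumps(clf.model))
    card = {
        "kind": clf.kind,
        "class_weights": clf.class_weights,
        "seed": getattr(clf.config, "seed", None),
        **(extra or {}),
    }
    (out_dir / "model-card.txt").write_text("\n".join(f"{k}: {v}" for k, v in card.items()) + "\n")
    return out_dir


def load_checkpoint(out_dir) -> TrainedClassifier:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "config.json").read_text())
    kind = meta["kind"]
    if kind == "cnn":
        raw = {k: v for k, v in meta["config"].items()}
        raw["conv_depths"] = tuple(raw["conv_depths"])
        cfg = CNNConfig(**raw)
        net = build_cnn(cfg)
        data = np.load(out_dir / "weights.npz")
        net.set_weights([data[k] for k in data.files])
        return TrainedClassifier(kind, net, config=cfg)
    if kind == "fcnn":
        raise NotImplementedError("fcnn checkpoints require the feature count; retrain instead")
    import pickle

    model = pickle.loads((out_dir / "model.pkl").read_bytes())
    return TrainedClassifier(kind, model)

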