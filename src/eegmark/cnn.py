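"""The channels-by-time convolutional EEG classifier.

Architecture: six blocks of [Conv2D (200 filters, kernels (2,2) in the first
three blocks and (1,2) in the last three, 'same' padding, ReLU) -> max-pool
(1,2) along time -> dropout (0.3 after blocks 1-5, 0.5 after block 6)],
then flatten -> dense -> single sigmoid output.  Pooling never touches the
10-channel axis, so per-channel relevance stays meaningful for Grad-CAM.

Training uses class-weighted binary cross-entropy, the Adamax optimizer
(default learning rate 5e-5), and early stopping on validation loss with a
patience of 70 epochs (maximum 900), restoring the best-validation weights.
Class weights default to 2:3 for HC:MDD and 17:20 for responder tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from eegmark.nn import (
    Adamax, Conv2D, Dense, Dropout, Flatten, MaxPoolTime, Sequential,
    weighted_bce_from_logits,
)
from eegmark.preprocess import NormStats, SegmentSet

__all__ = [
    "ModelSpec", "TrainConfig", "TrainedClassifier", "HyperGrid",
    "build_model", "train", "predict_segments", "random_search",
    "DIAGNOSIS_CLASS_WEIGHTS", "RESPONSE_CLASS_WEIGHTS",
]

#: Loss-weight ratio HC:MDD for the diagnosis task.
DIAGNOSIS_CLASS_WEIGHTS: tuple[float, float] = (2.0, 3.0)
#: Loss-weight ratio responder:non-responder for the prediction task.
RESPONSE_CLASS_WEIGHTS: tuple[float, float] = (17.0, 20.0)


@dataclass(frozen=True)
class ModelSpec:
    """Network hyperparameters; defaults are the full-scale configuration."""

    n_blocks: int = 6
    filters: int = 200
    kernel_schedule: tuple[tuple[int, int], ...] = (
        (2, 2), (2, 2), (2, 2), (1, 2), (1, 2), (1, 2))
    pool_size: int = 2
    dropout_schedule: tuple[float, ...] = (0.3, 0.3, 0.3, 0.3, 0.3, 0.5)
    dense_units: int = 64
    input_shape: tuple[int, int, int] = (10, 500, 1)

    def __post_init__(self) -> None:
        if len(self.kernel_schedule) != self.n_blocks:
            raise ValueError("one kernel per block required")
        if len(self.dropout_schedule) != self.n_blocks:
            raise ValueError("one dropout rate per block required")
        if any(not 0.0 <= d < 1.0 for d in self.dropout_schedule):
            raise ValueError("dropout rates must lie in [0, 1)")
        if any(kh not in (1, 2) for kh, _ in self.kernel_schedule):
            raise ValueError("kernel heights must be 1 or 2")
        t = self.input_shape[1]
        for _ in range(self.n_blocks):
            t //= self.pool_size
            if t < 1:
                raise ValueError("pooling schedule collapses the time axis")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults are the full-scale configuration."""

    learning_rate: float = 5e-5
    max_epochs: int = 900
    early_stop_patience: int = 70
    class_weights: tuple[float, float] = DIAGNOSIS_CLASS_WEIGHTS
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.early_stop_patience < self.max_epochs:
            raise ValueError("patience must be below max_epochs")


@dataclass
class TrainedClassifier:
    """Fitted network bound to the normalization statistics it was trained with."""

    network: Sequential
    spec: ModelSpec
    norm_stats: NormStats | None = None
    history: dict = field(default_factory=dict)
    stopped_epoch: int = 0


def build_model(spec: ModelSpec, seed: int) -> TrainedClassifier:
    """Construct an untrained network with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = spec.input_shape[2]
    t = spec.input_shape[1]
    for b in range(spec.n_blocks):
        layers.append(Conv2D(in_ch, spec.filters, spec.kernel_schedule[b], rng))
        layers.append(MaxPoolTime(spec.pool_size))
        layers.append(Dropout(spec.dropout_schedule[b]))
        in_ch = spec.filters
        t //= spec.pool_size
    layers.append(Flatten())
    flat = spec.filters * spec.input_shape[0] * t
    layers.append(Dense(flat, spec.dense_units, rng, relu=True))
    layers.append(Dense(spec.dense_units, 1, rng, relu=False))
    return TrainedClassifier(network=Sequential(layers), spec=spec)


def _as_input(data: np.ndarray) -> np.ndarray:
    # segments (n, 10, 500) -> network input (n, 1, 10, 500)
    return np.ascontiguousarray(data[:, None, :, :], dtype=np.float32)


def _sample_weights(labels: np.ndarray, class_weights: tuple[float, float]
                    ) -> np.ndarray:
    w0, w1 = class_weights
    scale = 2.0 / (w0 + w1)  # mean class weight 1 keeps the step size comparable
    return np.where(labels == 1, w1 * scale, w0 * scale)


def _evaluate(network: Sequential, x: np.ndarray, y: np.ndarray,
              weights: np.ndarray, batch_size: int) -> tuple[float, float]:
    total_loss, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        sl = slice(i, i + batch_size)
        logits = network.forward(x[sl], training=False)
        loss, _ = weighted_bce_from_logits(logits, y[sl], weights[sl])
        total_loss += loss * len(y[sl])
        correct += int(((logits >= 0).astype(int) == y[sl]).sum())
    n = len(y)
    return total_loss / n, correct / n


def train(model: TrainedClassifier, train_segs: SegmentSet, val_segs: SegmentSet,
          cfg: TrainConfig) -> TrainedClassifier:
    """Fit the network with early stopping on (weighted) validation loss.

    Train and validation sets must be normalized with train-derived statistics
    and must not share subjects (structural leakage guard).
    """
    overlap = set(np.unique(train_segs.subject_ids)) & set(
        np.unique(val_segs.subject_ids))
    if overlap:
        raise ValueError(f"subjects present in both train and val: {sorted(overlap)}")
    if not (train_segs.normalized and val_segs.normalized):
        raise ValueError("segments must be normalized with train-set statistics")
    if train_segs.labels is None or val_segs.labels is None:
        raise ValueError("labelled segments required")

    net = model.network
    x_tr = _as_input(train_segs.data)
    y_tr = train_segs.labels.astype(np.float64)
    w_tr = _sample_weights(y_tr, cfg.class_weights)
    x_va = _as_input(val_segs.data)
    y_va = val_segs.labels.astype(np.float64)
    w_va = _sample_weights(y_va, cfg.class_weights)

    opt = Adamax(net.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_loss, best_weights, wait = np.inf, net.get_weights(), 0
    stopped = cfg.max_epochs

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = net.forward(x_tr[idx], training=True, rng=rng)
            loss, dlogits = weighted_bce_from_logits(logits, y_tr[idx], w_tr[idx])
            net.backward(dlogits)
            opt.step(net.grads)
            ep_loss += loss * len(idx)
            ep_correct += int(((logits >= 0).astype(int) == y_tr[idx]).sum())
        val_loss, val_acc = _evaluate(net, x_va, y_va, w_va, cfg.batch_size)
        history["train_loss"].append(ep_loss / len(x_tr))
        history["train_acc"].append(ep_correct / len(x_tr))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss - 1e-12:
            best_loss, best_weights, wait = val_loss, net.get_weights(), 0
        else:
            wait += 1
            if wait >= cfg.early_stop_patience:
                stopped = epoch
                break

    net.set_weights(best_weights)
    model.history = history
    model.stopped_epoch = stopped if stopped <= len(history["val_loss"]) else len(
        history["val_loss"])
    return model


def predict_segments(model: TrainedClassifier, segs: SegmentSet) -> np.ndarray:
    """Per-segment positive-class probabilities; deterministic (dropout off)."""
    if not segs.normalized:
        raise ValueError("segments must be normalized with the model's norm_stats")
    expected = model.spec.input_shape[:2]
    if segs.data.shape[1:] != expected:
        raise ValueError(
            f"segment shape {segs.data.shape[1:]} != model input {expected}")
    x = _as_input(segs.data)
    probs = np.empty(len(x))
    for i in range(0, len(x), 256):
        logits = model.network.forward(x[i:i + 256], training=False)
        probs[i:i + 256] = expit(logits)
    return probs


@dataclass(frozen=True)
class HyperGrid:
    """Candidate values for the seeded random hyperparameter search."""

    filters: tuple[int, ...] = (50, 100, 200)
    dense_units: tuple[int, ...] = (32, 64, 128)
    dropout: tuple[float, ...] = (0.2, 0.3, 0.5)
    learning_rate: tuple[float, ...] = (1e-5, 5e-5, 1e-4)
    n_draws: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        for name in ("filters", "dense_units", "dropout", "learning_rate"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty candidate list: {name}")


def random_search(grid: HyperGrid, train_segs: SegmentSet, val_segs: SegmentSet,
                  base_spec: ModelSpec = ModelSpec(),
                  base_cfg: TrainConfig = TrainConfig(),
                  search_epochs: int = 10
                  ) -> tuple[ModelSpec, TrainConfig]:
    """Sample ``n_draws`` configurations, train each briefly, return the best.

    Best = highest validation accuracy; ties broken by lower validation loss,
    then by draw order.
    """
    rng = np.random.default_rng(grid.seed)
    draws = []
    for _ in range(grid.n_draws):
        draws.append((
            int(rng.choice(grid.filters)),
            int(rng.choice(grid.dense_units)),
            float(rng.choice(grid.dropout)),
            float(rng.choice(grid.learning_rate)),
        ))
    patience = min(base_cfg.early_stop_patience, max(search_epochs - 1, 1))
    results = []
    for order, (f, d, p, lr) in enumerate(draws):
        spec = replace(base_spec, filters=f, dense_units=d,
                       dropout_schedule=(p,) * (base_spec.n_blocks - 1) + (0.5,))
        cfg = replace(base_cfg, learning_rate=lr, max_epochs=search_epochs,
                      early_stop_patience=patience)
        model = build_model(spec, seed=base_cfg.seed)
        model = train(model, train_segs, val_segs, cfg)
        val_acc = model.history["val_acc"][-1]
        val_loss = min(model.history["val_loss"])
        results.append((-val_acc, val_loss, order, spec, cfg))
    results.sort(key=lambda r: r[:3])
    _, _, _, spec, cfg = results[0]
    return spec, replace(cfg, max_epochs=base_cfg.max_epochs,
                         early_stop_patience=base_cfg.early_stop_patience)
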