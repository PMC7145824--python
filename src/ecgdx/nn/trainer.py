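"""Optimization loop: average binary cross-entropy, Adam, plateau
learning-rate schedule, best-on-validation checkpointing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ecgdx.nn.resnet import ResNet1d

LOSS_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 50
    plateau_patience: int = 7
    lr_reduction_factor: float = 10.0
    batch_size: int = 32
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "max_epochs", "plateau_patience",
                     "lr_reduction_factor", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plateau_patience >= self.max_epochs:
            raise ValueError("plateau_patience must be smaller than max_epochs")


@dataclass
class TrainResult:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_state: Optional[dict] = None


def multilabel_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy over records and classes.

    Predictions are clipped to [eps, 1 - eps] (eps = 1e-7) so that
    saturated sigmoids do not produce infinities.
    """
    p = np.clip(np.asarray(predictions, dtype=np.float64), LOSS_EPS, 1.0 - LOSS_EPS)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class PlateauSchedule:
    """Reduce the learning rate by ``factor`` after ``patience``
    consecutive epochs without a strictly lower validation loss."""

    def __init__(self, lr: float, patience: int, factor: float) -> None:
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr /= self.factor
                self.bad_epochs = 0
        return self.lr


class Adam:
    def __init__(self, params, cfg: TrainConfig) -> None:
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.adam_beta1**self.t
        b2t = 1.0 - c.adam_beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= c.adam_beta1
            m += (1 - c.adam_beta1) * p.grad
            v *= c.adam_beta2
            v += (1 - c.adam_beta2) * p.grad**2
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + c.adam_eps)


def _predict_batched(net: ResNet1d, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    out = [
        net.forward(x[i : i + batch_size], training=False)
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(out, axis=0)


def predict(net: ResNet1d, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Inference-mode class probabilities (dropout off, running BN stats)."""
    return _predict_batched(net, x, batch_size)


def train(
    net: ResNet1d,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    verbose: bool = False,
) -> TrainResult:
    """Train for up to ``max_epochs``; keep the weights with the lowest
    validation loss.  Fully reproducible for a fixed config and seed
    (single-threaded BLAS determinism is the tested contract)."""
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    y_train = np.asarray(y_train, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), cfg)
    sched = PlateauSchedule(cfg.learning_rate, cfg.plateau_patience, cfg.lr_reduction_factor)
    result = TrainResult()
    n = len(x_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            net.zero_grad()
            p = net.forward(xb, training=True)
            loss = multilabel_loss(p, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            # d(mean BCE)/dz for a sigmoid head collapses to (p - y)/N.
            dz = (p - yb) / p.size
            net.backward(dz)
            opt.step(sched.lr)
            batch_losses.append(loss)
        val_p = _predict_batched(net, x_val)
        val_loss = multilabel_loss(val_p, y_val)
        result.train_losses.append(float(np.mean(batch_losses)))
        result.val_losses.append(val_loss)
        result.lr_history.append(sched.lr)
        if result.best_epoch < 0 or val_loss < result.val_losses[result.best_epoch]:
            result.best_epoch = epoch
            result.best_state = net.state_dict()
        sched.step(val_loss)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}  train {result.train_losses[-1]:.4f}  "
                f"val {val_loss:.4f}  lr {sched.lr:g}"
            )
    if result.best_state is not None:
        net.load_state_dict(result.best_state)
    return result
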