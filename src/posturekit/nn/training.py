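"""Windowed many-to-many training of the sequence classifiers.

Sessions are cut into fixed-length non-overlapping windows with a
per-timestep target, split 7:3 into training and validation windows
chronologically (the first 70% train, the rest validate, so no future
context leaks backwards), and optimized with Adam at the configured
learning rate and weight decay.  Everything is deterministic given the
config seed and the model's build seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..features import FeatureMatrix
from .layers import Adam, Sequential
from .losses import cross_entropy, cross_entropy_grad, one_hot


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.00001
    epochs: int = 150
    batch_size: int = 10
    split_ratio: float = 0.7
    seed: int = 0
    window_length: int = 400
    device: str = "cpu"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.epochs < 0 or self.batch_size < 1 or self.window_length < 1:
            raise ValueError("epochs, batch_size and window_length must be positive")


@dataclass(frozen=True)
class ProbabilitySequence:
    """Per-timestep class probabilities in the fixed 7-class order."""

    probs: np.ndarray  # (n, 7)
    rate: float

    def __post_init__(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 7:
            raise ValueError("probs must be an (n, 7) matrix")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]


@dataclass
class TrainingResult:
    model: Sequential
    history: pd.DataFrame  # columns epoch, train_loss, val_loss
    config: TrainingConfig

    @property
    def final_train_loss(self) -> float:
        return float(self.history["train_loss"].iloc[-1])

    @property
    def final_val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[-1])


def make_windows(values: np.ndarray, labels: np.ndarray, window_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Cut aligned (n, F) features / (n,) labels into non-overlapping
    windows; a trailing remainder shorter than one window is dropped."""
    n = values.shape[0]
    n_win = n // window_length
    if n_win < 1:
        raise ValueError(f"sequence of {n} samples is shorter than one window ({window_length})")
    used = n_win * window_length
    X = values[:used].reshape(n_win, window_length, values.shape[1])
    Y = labels[:used].reshape(n_win, window_length)
    return X, Y


def _epoch_val_loss(model: Sequential, X: np.ndarray, Y1h: np.ndarray, batch_size: int) -> float:
    total, count = 0.0, 0
    for lo in range(0, X.shape[0], batch_size):
        probs = model.forward(X[lo : lo + batch_size], train=False)
        res = cross_entropy(Y1h[lo : lo + batch_size], probs)
        total += res.total
        count += res.n_samples
    return total / count


def train(
    model: Sequential,
    features: FeatureMatrix,
    labels: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> TrainingResult:
    """Optimize ``model`` on one session's features and label track."""
    labels = np.asarray(labels)
    if features.n_samples != labels.shape[0]:
        raise ValueError("features and labels must be aligned")
    if config.window_length > features.n_samples:
        raise ValueError("window_length exceeds the sequence length")
    X, Y = make_windows(features.values, labels, config.window_length)
    n_win = X.shape[0]
    n_train = int(round(config.split_ratio * n_win))
    if n_train < 1 or n_train >= n_win:
        raise ValueError(
            f"split_ratio {config.split_ratio} leaves an empty train or "
            f"validation split for {n_win} windows"
        )
    Xtr, Ytr = X[:n_train], one_hot(Y[:n_train])
    Xva, Yva = X[n_train:], one_hot(Y[n_train:])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7121]))
    opt = Adam(model.params(), lr=config.learning_rate, weight_decay=config.weight_decay)
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_train)
        total, count = 0.0, 0
        for lo in range(0, n_train, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            probs = model.forward(xb, train=True)
            res = cross_entropy(yb, probs)
            model.zero_grads()
            model.backward(cross_entropy_grad(yb, probs))
            opt.step(model.grads())
            total += res.total
            count += res.n_samples
        rows.append(
            {
                "epoch": epoch,
                "train_loss": total / count,
                "val_loss": _epoch_val_loss(model, Xva, Yva, config.batch_size),
            }
        )
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    return TrainingResult(model=model, history=history, config=config)


def predict(
    model: Sequential,
    features: FeatureMatrix,
    chunk: int = 2000,
    context: int = 200,
) -> ProbabilitySequence:
    """Per-timestep class probabilities for a whole session.

    Long sessions are scored in chunks with ``context`` samples of
    left run-in (discarded from the output) so the recurrent state has
    warmed up by the first retained sample; this bounds memory while
    leaving chunk-boundary effects negligible.
    """
    values = features.values
    if values.shape[1] != 12:
        raise ValueError("feature matrix must have 12 columns")
    n = values.shape[0]
    if n <= chunk + context:
        probs = model.forward(values[None, :, :], train=False)[0]
        return ProbabilitySequence(probs=probs, rate=features.rate)
    out = np.empty((n, 7))
    starts = list(range(0, n, chunk))
    for s in starts:
        lo = max(0, s - context)
        hi = min(n, s + chunk)
        probs = model.forward(values[None, lo:hi, :], train=False)[0]
        out[s:hi] = probs[s - lo :]
    return ProbabilitySequence(probs=out, rate=features.rate)
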