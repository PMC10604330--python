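"""Cross-entropy between true label distributions and predictions.

The loss is the double sum -sum_i sum_j p_ij ln q_ij over samples i
and classes j, with the predicted probabilities clamped below at a
small epsilon before the logarithm so a saturated softmax cannot
produce an infinite loss.  Training logs report the per-sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_CLAMP_EPS = 1e-12


@dataclass(frozen=True)
class CrossEntropyResult:
    total: float  # nats, summed over samples
    mean: float  # nats per sample
    n_samples: int


def one_hot(labels: np.ndarray, n_classes: int = 7) -> np.ndarray:
    labels = np.asarray(labels)
    out = np.zeros((*labels.shape, n_classes))
    np.put_along_axis(out, labels[..., None], 1.0, axis=-1)
    return out


def cross_entropy(true: np.ndarray, predicted: np.ndarray, eps: float = LOG_CLAMP_EPS) -> CrossEntropyResult:
    """Eq.-style double-sum cross-entropy in nats.

    ``true`` may be integer labels (...,) or a distribution (..., 7);
    ``predicted`` is a probability array of matching shape.  Leading
    axes are flattened, so windows of sequences are scored per
    timestep.
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true)
    if true.shape != predicted.shape:
        if true.shape == predicted.shape[:-1]:
            true = one_hot(true, predicted.shape[-1])
        else:
            raise ValueError(f"shape mismatch: true {true.shape} vs predicted {predicted.shape}")
    q = np.clip(predicted, eps, 1.0)
    per_sample = -(true * np.log(q)).sum(axis=-1)
    total = float(per_sample.sum())
    n = int(per_sample.size)
    return CrossEntropyResult(total=total, mean=total / n, n_samples=n)


def cross_entropy_grad(true_onehot: np.ndarray, predicted: np.ndarray, eps: float = LOG_CLAMP_EPS) -> np.ndarray:
    """d(mean loss)/d(predicted); zero where the clamp is active."""
    q = np.clip(predicted, eps, 1.0)
    n = int(np.prod(predicted.shape[:-1]))
    grad = -(true_onehot / q) / n
    grad[predicted < eps] = 0.0
    return grad
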