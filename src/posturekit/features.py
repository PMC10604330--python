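"""Network input features: angles, angular velocities, accelerations.

Each session becomes an n x 12 matrix, joint-major: for each of
(pelvis, hip, knee, ankle) the angle (deg), angular velocity (deg/s)
and angular acceleration (deg/s^2).  Derivatives use central
differences on interior samples and first-order one-sided differences
at the two boundaries, which keeps the feature matrix aligned
sample-for-sample with the label track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .synth import JOINTS, KinematicSession

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{joint}_{quantity}" for joint in JOINTS for quantity in ("angle", "vel", "acc")
)
N_FEATURES = len(FEATURE_NAMES)  # 12


@dataclass
class NormalizationStats:
    """Per-column z-score statistics, fit on the training split only."""

    mean: np.ndarray  # (12,)
    sd: np.ndarray  # (12,), constant columns stored as 1.0

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (n, 12)
    rate: float
    normalization_stats: NormalizationStats | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must have {N_FEATURES} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def differentiate(angles: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """First and second time derivatives of an (n, k) angle track.

    Central differences inside, one-sided at the ends; the acceleration
    is the same operator applied to the velocity.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    dt = 1.0 / rate
    velocity = np.gradient(angles, dt, axis=0, edge_order=1)
    acceleration = np.gradient(velocity, dt, axis=0, edge_order=1)
    return velocity, acceleration


DEFAULT_SMOOTH_CUTOFF_HZ = 6.0


def smooth_angles(
    angles: np.ndarray, rate: float, cutoff_hz: float | None = DEFAULT_SMOOTH_CUTOFF_HZ, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, the standard pre-conditioning
    for lower-limb kinematics before numerical differentiation.

    Without it, double differencing amplifies sensor noise by the
    square of the sampling rate, so acceleration channels at 100 Hz
    would be dominated by noise that a real acquisition system's
    derivative computation does not contain.  ``cutoff_hz=None``
    disables smoothing; cutoffs at or above Nyquist are a no-op.
    """
    if cutoff_hz is None or cutoff_hz <= 0 or cutoff_hz >= rate / 2:
        return angles
    b, a = butter(order, cutoff_hz / (rate / 2))
    return filtfilt(b, a, angles, axis=0)


def build_feature_matrix(
    session: KinematicSession, smooth_cutoff_hz: float | None = DEFAULT_SMOOTH_CUTOFF_HZ
) -> FeatureMatrix:
    """Assemble the n x 12 input in joint-major column order.

    Angles are low-pass filtered (zero phase) before differentiation;
    the angle columns carry the filtered signal so all three channels
    per joint describe the same trajectory.
    """
    angles = smooth_angles(session.angles, session.rate, smooth_cutoff_hz)
    vel, acc = differentiate(angles, session.rate)
    cols = []
    for j in range(4):
        cols += [angles[:, j], vel[:, j], acc[:, j]]
    return FeatureMatrix(values=np.stack(cols, axis=1), rate=session.rate)


def resample(session: KinematicSession, new_rate: float) -> KinematicSession:
    """Integer decimation to a divisor rate (keep every k-th sample).

    No anti-alias filter is applied: the decimated stream stands in for
    a sensor natively sampling at the lower rate.
    """
    if new_rate <= 0:
        raise ValueError("new_rate must be > 0")
    ratio = session.rate / new_rate
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9:
        raise ValueError(f"new_rate {new_rate} must divide the session rate {session.rate}")
    if k == 1:
        return session
    return KinematicSession(
        rate=new_rate,
        angles=session.angles[::k].copy(),
        labels=session.labels[::k].copy(),
        subject_id=session.subject_id,
    )


def fit_normalizer(train: FeatureMatrix) -> NormalizationStats:
    if train.n_samples < 2:
        raise ValueError("need more than one row to fit normalization statistics")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return NormalizationStats(mean=mean, sd=sd)


def apply_normalizer(m: FeatureMatrix, stats: NormalizationStats) -> FeatureMatrix:
    return FeatureMatrix(values=stats.apply(m.values), rate=m.rate, normalization_stats=stats)


@dataclass
class ChannelCorrelations:
    """Pearson correlations between the 12 input channels.

    ``undefined`` lists zero-variance columns; their off-diagonal
    entries are NaN by construction and flagged rather than silently
    propagated into downstream summaries.
    """

    matrix: np.ndarray  # (12, 12), diagonal exactly 1
    undefined: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=FEATURE_NAMES, columns=FEATURE_NAMES)

    def pairs_above(self, threshold: float = 0.3) -> list[tuple[str, str, float]]:
        """Channel pairs whose |r| exceeds ``threshold`` (upper triangle)."""
        out = []
        for i in range(N_FEATURES):
            for j in range(i + 1, N_FEATURES):
                r = self.matrix[i, j]
                if np.isfinite(r) and abs(r) > threshold:
                    out.append((FEATURE_NAMES[i], FEATURE_NAMES[j], float(r)))
        return out


def channel_correlations(m: FeatureMatrix) -> ChannelCorrelations:
    if m.n_samples <= 2:
        raise ValueError("need more than 2 samples for correlations")
    sd = m.values.std(axis=0)
    undefined = tuple(int(i) for i in np.where(sd == 0)[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m.values, rowvar=False)
    for i in undefined:
        corr[i, :] = np.nan
        corr[:, i] = np.nan
    np.fill_diagonal(corr, 1.0)
    return ChannelCorrelations(matrix=corr, undefined=undefined)
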