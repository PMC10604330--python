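"""Decoding, event extraction and transition-time scoring.

The detector's output is a per-timestep probability sequence; decoding
takes the argmax, a debounce pass suppresses label runs shorter than a
minimum duration, and every remaining label change becomes a
:class:`TransitionEvent` timestamped at the first sample of the new
run.  Predicted events are matched one-to-one to ground-truth events
with the same target label, and the timing error DeltaT = |t_true -
t_pred| feeds the transition-time accuracy

    accuracy = (1 - (sum DeltaT + penalties) / protocol_time) * 100%

where the DeltaT sum is grouped into entries into steady postures,
activity starts (stw, sd) and activity ends (spw, su), and each
unmatched true event contributes a fixed time penalty (a detector that
reports nothing must not score well).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion

from .labels import LABEL_NAMES, N_CLASSES, category_of
from .nn.training import ProbabilitySequence

DEFAULT_UNMATCHED_PENALTY = 2.0  # seconds per missed true transition
CATEGORIES = ("steady", "start", "end")


@dataclass(frozen=True)
class TransitionEvent:
    time: float  # seconds, first sample of the new run
    from_label: int
    to_label: int

    @property
    def category(self) -> str:
        return category_of(self.to_label)


def decode_labels(probs: ProbabilitySequence | np.ndarray) -> np.ndarray:
    """Argmax decode; ties break to the lowest class index."""
    p = probs.probs if isinstance(probs, ProbabilitySequence) else np.asarray(probs)
    return np.argmax(p, axis=1).astype(np.int8)


def run_length_encode(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, run_length) pairs of a label track."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [(int(labels[lo]), int(hi - lo)) for lo, hi in zip(bounds[:-1], bounds[1:])]


def debounce(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb label runs shorter than ``min_run`` samples.

    A short run is absorbed into the run before it; a short run at the
    very start (no predecessor) is absorbed into the run after it.
    Merging can fuse equal-label neighbours whose combined length then
    counts as one run.  ``min_run = 1`` is the identity.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    labels = np.asarray(labels)
    if min_run == 1 or labels.size == 0:
        return labels.copy()
    merged: list[list[int]] = []  # [label, length]
    carry = 0  # samples from short leading runs awaiting a keeper
    carry_label = int(labels[0])
    for lab, length in run_length_encode(labels):
        length += carry
        carry = 0
        if merged and merged[-1][0] == lab:
            merged[-1][1] += length
        elif length < min_run:
            if merged:
                merged[-1][1] += length
            else:
                carry = length
                carry_label = lab
        else:
            merged.append([lab, length])
    if carry:
        if merged:
            merged[0][1] += carry
        else:  # every run was short: the track collapses to one run
            merged.append([carry_label, carry])
    return np.repeat([lab for lab, _ in merged], [ln for _, ln in merged]).astype(labels.dtype)


def extract_transitions(labels: np.ndarray, rate: float) -> list[TransitionEvent]:
    """One event per label change, at time = (first index of new run)/rate."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("label track is empty")
    change = np.flatnonzero(np.diff(labels)) + 1
    return [
        TransitionEvent(time=float(i / rate), from_label=int(labels[i - 1]), to_label=int(labels[i]))
        for i in change
    ]


@dataclass
class MatchResult:
    matched: list[tuple[TransitionEvent, TransitionEvent, float]]  # (true, pred, |dt|)
    unmatched_true: list[TransitionEvent]
    unmatched_pred: list[TransitionEvent]

    @property
    def delta_ts(self) -> np.ndarray:
        return np.array([dt for _, _, dt in self.matched])

    def delta_ts_by_category(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {c: [] for c in CATEGORIES}
        for true_ev, _, dt in self.matched:
            out[true_ev.category].append(dt)
        return {c: np.array(v) for c, v in out.items()}


def default_max_gap(true_events: list[TransitionEvent]) -> float:
    """Half the shortest spacing between consecutive true events that
    share a target label, so a predicted event can never be matched to
    the wrong occurrence of that label.

    Only same-target-label events compete during matching, so the
    spacing that matters is within each label's own event sequence
    (tens of seconds apart in cyclic protocols), not the 0.5-1 s
    spacing between a transition event and the steady-state entry that
    follows it.  A cap that tight would censor exactly the late
    detections the timing error is meant to measure.
    """
    by_label: dict[int, list[float]] = {}
    for ev in true_events:
        by_label.setdefault(ev.to_label, []).append(ev.time)
    gaps = [
        np.diff(sorted(times)).min()
        for times in by_label.values()
        if len(times) >= 2
    ]
    return float(min(gaps) / 2.0) if gaps else np.inf


def match_transitions(
    true_events: list[TransitionEvent],
    predicted_events: list[TransitionEvent],
    max_gap: float | None = None,
) -> MatchResult:
    """Greedy nearest-in-time one-to-one matching of events with the
    same target label, restricted to |dt| <= max_gap."""
    if max_gap is None:
        max_gap = default_max_gap(true_events)
    candidates = []
    for ti, te in enumerate(true_events):
        for pi, pe in enumerate(predicted_events):
            if te.to_label == pe.to_label:
                dt = abs(te.time - pe.time)
                if dt <= max_gap:
                    candidates.append((dt, ti, pi))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = []
    for dt, ti, pi in candidates:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matched.append((true_events[ti], predicted_events[pi], dt))
    matched.sort(key=lambda m: m[0].time)
    unmatched_true = [ev for i, ev in enumerate(true_events) if i not in used_t]
    unmatched_pred = [ev for i, ev in enumerate(predicted_events) if i not in used_p]
    return MatchResult(matched, unmatched_true, unmatched_pred)


def transition_time_accuracy(
    match: MatchResult,
    protocol_time: float,
    penalty: float = DEFAULT_UNMATCHED_PENALTY,
) -> float:
    """Percent accuracy: 100 * (1 - (sum DeltaT + penalties)/protocol_time),
    clipped to [0, 100]."""
    if protocol_time <= 0:
        raise ValueError("protocol_time must be > 0")
    total = float(sum(dt for _, _, dt in match.matched))
    total += penalty * len(match.unmatched_true)
    return float(np.clip((1.0 - total / protocol_time) * 100.0, 0.0, 100.0))


def classification_report(true_labels: np.ndarray, predicted_labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Timestep accuracy (percent) and the 7x7 confusion matrix
    (rows = true class, columns = predicted class)."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label tracks must have equal length")
    acc = float(np.mean(true_labels == predicted_labels) * 100.0)
    conf = _sk_confusion(true_labels, predicted_labels, labels=np.arange(N_CLASSES))
    return acc, conf


@dataclass
class TransitionTimingReport:
    """Everything the timing evaluation produces for one session."""

    match: MatchResult
    transition_time_accuracy: float  # percent
    classification_accuracy: float  # percent
    confusion: np.ndarray  # (7, 7)
    rate: float
    protocol_time: float
    subject_id: str = ""

    @property
    def mean_delta_t(self) -> float:
        dts = self.match.delta_ts
        return float(dts.mean()) if dts.size else float("nan")

    def category_summary(self) -> pd.DataFrame:
        rows = []
        for cat, dts in self.match.delta_ts_by_category().items():
            rows.append(
                {
                    "category": cat,
                    "n_matched": int(dts.size),
                    "mean_dt_s": float(dts.mean()) if dts.size else np.nan,
                    "sd_dt_s": float(dts.std(ddof=1)) if dts.size > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=LABEL_NAMES, columns=LABEL_NAMES)

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {
                "true_time_s": te.time,
                "pred_time_s": pe.time,
                "delta_t_s": dt,
                "to_label": LABEL_NAMES[te.to_label],
                "category": te.category,
                "status": "matched",
            }
            for te, pe, dt in self.match.matched
        ]
        rows += [
            {
                "true_time_s": ev.time,
                "pred_time_s": np.nan,
                "delta_t_s": np.nan,
                "to_label": LABEL_NAMES[ev.to_label],
                "category": ev.category,
                "status": "unmatched_true",
            }
            for ev in self.match.unmatched_true
        ]
        rows += [
            {
                "true_time_s": np.nan,
                "pred_time_s": ev.time,
                "delta_t_s": np.nan,
                "to_label": LABEL_NAMES[ev.to_label],
                "category": ev.category,
                "status": "unmatched_pred",
            }
            for ev in self.match.unmatched_pred
        ]
        return pd.DataFrame(
            rows,
            columns=["true_time_s", "pred_time_s", "delta_t_s", "to_label", "category", "status"],
        )

    def summary(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "transition_time_accuracy_pct": self.transition_time_accuracy,
            "classification_accuracy_pct": self.classification_accuracy,
            "mean_delta_t_s": self.mean_delta_t,
            "n_matched": len(self.match.matched),
            "n_unmatched_true": len(self.match.unmatched_true),
            "n_unmatched_pred": len(self.match.unmatched_pred),
        }


def score_predictions(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    rate: float,
    protocol_time: float | None = None,
    min_run: int | None = None,
    max_gap: float | None = None,
    penalty: float = DEFAULT_UNMATCHED_PENALTY,
    subject_id: str = "",
) -> TransitionTimingReport:
    """Full scoring pipeline: debounce, extract, match, both accuracies.

    ``min_run`` defaults to 0.2 s worth of samples, well below the
    shortest real transition (0.5 s) so genuine events survive while
    single-sample flicker is removed.  ``protocol_time`` defaults to
    the full session duration.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if min_run is None:
        min_run = max(1, int(round(0.2 * rate)))
    if protocol_time is None:
        protocol_time = len(true_labels) / rate
    smoothed = debounce(predicted_labels, min_run)
    true_events = extract_transitions(true_labels, rate)
    pred_events = extract_transitions(smoothed, rate)
    match = match_transitions(true_events, pred_events, max_gap=max_gap)
    tt_acc = transition_time_accuracy(match, protocol_time, penalty=penalty)
    cls_acc, conf = classification_report(true_labels, smoothed)
    return TransitionTimingReport(
        match=match,
        transition_time_accuracy=tt_acc,
        classification_accuracy=cls_acc,
        confusion=conf,
        rate=rate,
        protocol_time=protocol_time,
        subject_id=subject_id,
    )


@dataclass
class GroupStats:
    name: str
    n: int
    mean: float
    sd: float


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def delta_t_group_stats(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> tuple[list[GroupStats], list[PairwiseTest]]:
    """Per-group mean +/- sample SD and pairwise Welch t-tests.

    A pair in which both groups have zero variance (or too few values)
    is reported as degenerate rather than raising.
    """
    stats_out = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        stats_out.append(
            GroupStats(
                name=name,
                n=int(vals.size),
                mean=float(vals.mean()) if vals.size else float("nan"),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            )
        )
    tests = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
                if a.size >= 2 and b.size >= 2 and np.array_equal(a, b):
                    t, p, degenerate = 0.0, 1.0, False
                else:
                    t, p, degenerate = float("nan"), float("nan"), True
            else:
                res = sps.ttest_ind(a, b, equal_var=False)
                t, p, degenerate = float(res.statistic), float(res.pvalue), False
            tests.append(
                PairwiseTest(
                    group_a=names[i],
                    group_b=names[j],
                    t_statistic=t,
                    p_value=p,
                    significant=bool(p < alpha) if np.isfinite(p) else False,
                    degenerate=degenerate,
                )
            )
    return stats_out, tests
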