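"""Activity protocols: scripted stand-walk-stand-sit cycles.

A :class:`ProtocolScript` is the ground-truth timeline a simulated
subject follows.  The default cycle mimics a common clinical protocol:
stand still for 15 s, walk for 15-20 s at a self-selected pace, stand
again for 15 s, then sit for 15 s, with short transition phases
inserted at every activity change (sit-down/stand-up take about one
second; starting and stopping walking take half a second to a second).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import Label

#: Default duration (seconds) of each transition class; a tuple means
#: uniform sampling from that range per occurrence.
DEFAULT_TRANSITION_DURATIONS: dict[Label, float | tuple[float, float]] = {
    Label.SD: 1.0,
    Label.SU: 1.0,
    Label.STW: (0.5, 1.0),
    Label.SPW: (0.5, 1.0),
}

STAND_DURATION = 15.0
SIT_DURATION = 15.0
DEFAULT_WALK_RANGE = (15.0, 20.0)


@dataclass(frozen=True)
class ProtocolScript:
    """An ordered timeline of labelled segments.

    ``timeline`` contains every segment, transitions included, as
    ``(label, duration_s)`` pairs; ``segments`` is the activity-only
    view.  ``total_time`` is the exact sum of all timeline durations.
    """

    timeline: tuple[tuple[Label, float], ...]

    def __post_init__(self) -> None:
        if not self.timeline:
            raise ValueError("protocol timeline is empty")
        for lab, dur in self.timeline:
            if dur <= 0:
                raise ValueError(f"segment {lab.name} has non-positive duration {dur}")
        labs = [lab for lab, _ in self.timeline]
        for a, b in zip(labs, labs[1:]):
            if a == b:
                raise ValueError("consecutive segments must differ in label")

    @property
    def segments(self) -> tuple[tuple[Label, float], ...]:
        from .labels import STEADY

        return tuple((lab, d) for lab, d in self.timeline if lab in STEADY)

    @property
    def transition_durations(self) -> dict[Label, list[float]]:
        from .labels import STEADY

        out: dict[Label, list[float]] = {}
        for lab, d in self.timeline:
            if lab not in STEADY:
                out.setdefault(lab, []).append(d)
        return out

    @property
    def total_time(self) -> float:
        return float(sum(d for _, d in self.timeline))


def _draw(spec: float | tuple[float, float], rng: np.random.Generator) -> float:
    if isinstance(spec, tuple):
        lo, hi = spec
        return float(rng.uniform(lo, hi))
    return float(spec)


def make_protocol(
    n_cycles: int,
    rng_seed: int = 0,
    walk_duration_range: tuple[float, float] = DEFAULT_WALK_RANGE,
    transition_durations: dict[Label, float | tuple[float, float]] | None = None,
    stand_duration: float = STAND_DURATION,
    sit_duration: float = SIT_DURATION,
) -> ProtocolScript:
    """Build ``n_cycles`` stand-walk-stand-sit cycles.

    Each cycle is stand(15) - stw - walk(U[15,20]) - spw - stand(15) -
    sd - sit(15) - su.  Sitting is always entered from standing and
    exited back to standing.  Walk durations and the stw/spw transition
    durations are drawn per occurrence from their ranges with a
    dedicated RNG, so the script is reproducible from ``rng_seed``.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    lo, hi = walk_duration_range
    if not (10.0 <= lo <= hi <= 30.0):
        raise ValueError(f"walk_duration_range must lie within [10, 30] s, got {walk_duration_range}")
    trans = dict(DEFAULT_TRANSITION_DURATIONS)
    if transition_durations:
        trans.update(transition_durations)

    rng = np.random.default_rng(rng_seed)
    timeline: list[tuple[Label, float]] = []
    for _ in range(n_cycles):
        timeline.append((Label.STANDING, stand_duration))
        timeline.append((Label.STW, _draw(trans[Label.STW], rng)))
        timeline.append((Label.WALKING, float(rng.uniform(lo, hi))))
        timeline.append((Label.SPW, _draw(trans[Label.SPW], rng)))
        timeline.append((Label.STANDING, stand_duration))
        timeline.append((Label.SD, _draw(trans[Label.SD], rng)))
        timeline.append((Label.SITTING, sit_duration))
        timeline.append((Label.SU, _draw(trans[Label.SU], rng)))
    return ProtocolScript(timeline=tuple(timeline))
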