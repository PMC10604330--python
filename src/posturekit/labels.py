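"""The seven-class posture/transition label scheme.

Three steady postures (standing, walking, sitting) plus four short
transition classes inserted between them: ``sd`` (sitting down),
``su`` (standing up), ``stw`` (starting to walk), ``spw`` (stopping
walking).  Integer codes are fixed; every label track and probability
matrix in the package uses this order.
"""

from __future__ import annotations

from enum import IntEnum


class Label(IntEnum):
    """Posture / transition classes, in the canonical class order."""

    STANDING = 0
    WALKING = 1
    SD = 2  # sitting down (stand -> sit)
    SITTING = 3
    SU = 4  # standing up (sit -> stand)
    STW = 5  # starting to walk (stand -> walk)
    SPW = 6  # stopping walking (walk -> stand)


#: Class names in index order, used for CSV headers and reports.
LABEL_NAMES: tuple[str, ...] = (
    "standing",
    "walking",
    "sd",
    "sitting",
    "su",
    "stw",
    "spw",
)

N_CLASSES = len(LABEL_NAMES)

#: Steady postures (the three main activities).
STEADY = frozenset({Label.STANDING, Label.WALKING, Label.SITTING})
#: Transitions that begin an activity (start walking, start sitting down).
START_TRANSITIONS = frozenset({Label.STW, Label.SD})
#: Transitions that end an activity (stop walking, stand back up).
END_TRANSITIONS = frozenset({Label.SPW, Label.SU})


def category_of(to_label: int) -> str:
    """Map the target label of a transition event onto the three
    timing-error categories used by the transition-time accuracy metric.

    Entries into steady states count towards the stand/walk/sit sum,
    entries into ``stw``/``sd`` towards the start-walk/sit sum and
    entries into ``spw``/``su`` towards the end-walk/sit sum.
    """
    lab = Label(to_label)
    if lab in STEADY:
        return "steady"
    if lab in START_TRANSITIONS:
        return "start"
    return "end"
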