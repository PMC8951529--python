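"""The behaviour ethogram: the three cattle states classified by the pipeline.

The canonical ordering (eating < rumination < other) is fixed and used
everywhere labels are encoded as integers: confusion-matrix axes, one-hot
columns, majority-vote tie-breaking and classifier tie-breaking all follow it.
"""

from __future__ import annotations

from enum import Enum


class BehaviourState(str, Enum):
    """One of the three behaviour states reported by the muzzle halter."""

    EATING = "eating"
    RUMINATION = "rumination"
    OTHER = "other"


#: Canonical state order; index in this tuple is the integer code.
STATES: tuple[BehaviourState, ...] = (
    BehaviourState.EATING,
    BehaviourState.RUMINATION,
    BehaviourState.OTHER,
)

#: Canonical label strings in canonical order.
LABELS: tuple[str, ...] = tuple(s.value for s in STATES)

#: Label string -> integer code.
LABEL_INDEX: dict[str, int] = {s.value: i for i, s in enumerate(STATES)}


def encode_labels(labels) -> "list[int]":
    """Map label strings to canonical integer codes."""
    return [LABEL_INDEX[str(l)] for l in labels]
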