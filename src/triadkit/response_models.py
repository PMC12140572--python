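"""Response models for the triad task.

Each strategy maps a displayed triad to the predicted odd-one-out position:

* **OS** (overall similarity): the odd stimulus is the one excluded from the
  pair closest in the full 2-D space (scaled Euclidean distance).
* **UD** (unidimensional, chroma or brightness): the pair closest on a single
  fixed dimension determines the odd stimulus.
* **ID** (identity): the pair exactly identical on one dimension determines
  the odd stimulus; with no identical pair the model abstains.  Coordinates
  recovered by similarity scaling are generic floats, so under such a space
  this model abstains everywhere — by design, identity means *exact* equality
  and no near-identity tolerance is applied.
* **Bias** (left/middle/right): always the same key, regardless of stimuli.

Distance ties make OS/UD abstain rather than guess, so scoring is
deterministic; an abstention can never match a response.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .stimulus_space import (
    DIMENSIONS,
    DesignViolationError,
    StimulusSpace,
    TriadInstance,
    resolve_identity,
)

__all__ = [
    "Strategy",
    "ABSTAIN",
    "UD_STRATEGIES",
    "BIAS_STRATEGIES",
    "BLOCK_STRATEGIES",
    "predict_os",
    "predict_ud",
    "predict_id",
    "predict",
    "PredictionTable",
    "build_prediction_table",
]

#: Sentinel for "this strategy makes no prediction on this trial".
ABSTAIN = None


class Strategy(str, Enum):
    UD_CHROMA = "UD_CHROMA"
    UD_BRIGHTNESS = "UD_BRIGHTNESS"
    OS = "OS"
    ID = "ID"
    BIAS_LEFT = "BIAS_LEFT"
    BIAS_MIDDLE = "BIAS_MIDDLE"
    BIAS_RIGHT = "BIAS_RIGHT"

    @property
    def family(self) -> str:
        """Reporting family: UD dimensions collapse, as do the three biases."""
        if self in UD_STRATEGIES:
            return "UD"
        if self in BIAS_STRATEGIES:
            return "Bias"
        return self.value


UD_STRATEGIES = (Strategy.UD_CHROMA, Strategy.UD_BRIGHTNESS)
BIAS_STRATEGIES = (Strategy.BIAS_LEFT, Strategy.BIAS_MIDDLE, Strategy.BIAS_RIGHT)
#: Strategies that can be fit to a single block (bias is participant-level only).
BLOCK_STRATEGIES = (Strategy.UD_CHROMA, Strategy.UD_BRIGHTNESS, Strategy.OS, Strategy.ID)

_BIAS_POSITION = {Strategy.BIAS_LEFT: 1, Strategy.BIAS_MIDDLE: 2, Strategy.BIAS_RIGHT: 3}


def _pairs(instance: TriadInstance) -> list[tuple[int, int, int]]:
    """(a, b, odd-position) for the three pairs of an arrangement."""
    l, m, r = instance
    return [(l, m, 3), (l, r, 2), (m, r, 1)]


def _odd_by_min(instance: TriadInstance, keyfun) -> Optional[int]:
    scored = [(keyfun(a, b), odd) for a, b, odd in _pairs(instance)]
    best = min(k for k, _ in scored)
    winners = [odd for k, odd in scored if k == best]
    return winners[0] if len(winners) == 1 else ABSTAIN


def predict_os(instance: TriadInstance, space: StimulusSpace) -> Optional[int]:
    """Odd position under overall similarity; abstains on an exact tie."""
    return _odd_by_min(instance, lambda a, b: space.distance(a, b))


def predict_ud(instance: TriadInstance, space: StimulusSpace, dimension: str) -> Optional[int]:
    """Odd position under a unidimensional strategy on ``dimension``."""
    if dimension not in DIMENSIONS:
        raise ValueError(f"dimension must be one of {DIMENSIONS}, got {dimension!r}")
    return _odd_by_min(instance, lambda a, b: abs(space.value(a, dimension)
                                                 - space.value(b, dimension)))


def predict_id(instance: TriadInstance, space: StimulusSpace) -> Optional[int]:
    """Odd position under the identity strategy.

    Uses the designed identity pair (see
    :func:`triadkit.stimulus_space.resolve_identity`); abstains when no pair
    is exactly identical on either dimension, and raises
    :class:`DesignViolationError` when the identity is irresolvably ambiguous.
    """
    resolved = resolve_identity(instance.members, space)
    if resolved is None:
        return ABSTAIN
    _, pair = resolved
    (odd,) = instance.members - pair
    return instance.position_of(odd)


def predict(strategy: Strategy, instance: TriadInstance, space: StimulusSpace) -> Optional[int]:
    strategy = Strategy(strategy)
    if strategy is Strategy.OS:
        return predict_os(instance, space)
    if strategy is Strategy.UD_CHROMA:
        return predict_ud(instance, space, "chroma")
    if strategy is Strategy.UD_BRIGHTNESS:
        return predict_ud(instance, space, "brightness")
    if strategy is Strategy.ID:
        return predict_id(instance, space)
    return _BIAS_POSITION[strategy]


class PredictionTable:
    """Cached strategy x arrangement -> predicted odd position (or abstain)."""

    def __init__(self, entries: dict[tuple[Strategy, TriadInstance], Optional[int]]):
        self.entries = entries

    def predict(self, strategy: Strategy, instance: TriadInstance) -> Optional[int]:
        key = (Strategy(strategy), instance)
        if key not in self.entries:
            raise KeyError(f"instance {tuple(instance)} not covered by this table")
        return self.entries[key]

    @property
    def instances(self) -> list[TriadInstance]:
        return sorted({inst for _, inst in self.entries})

    def to_frame(self) -> pd.DataFrame:
        """Long-form export; abstentions become empty fields on write."""
        rows = [
            {"strategy": s.value, "left": i.left, "middle": i.middle,
             "right": i.right, "predicted_position": p}
            for (s, i), p in sorted(self.entries.items(),
                                    key=lambda kv: (kv[0][0].value, kv[0][1]))
        ]
        df = pd.DataFrame(rows)
        df["predicted_position"] = df["predicted_position"].astype("Int64")
        return df


def build_prediction_table(space: StimulusSpace,
                           instances: Iterable[TriadInstance]) -> PredictionTable:
    instances = list(instances)
    if not instances:
        raise ValueError("instances must be nonempty")
    entries = {
        (s, inst): predict(s, inst, space)
        for inst in instances for s in Strategy
    }
    return PredictionTable(entries)
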