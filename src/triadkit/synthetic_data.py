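"""Synthetic participants for the triad and similarity-rating tasks.

The generator reproduces the statistical structure the analysis assumes:

* **Design**: 96 trials in 12 blocks of 8; each block holds one arrangement
  of each logical triad, and each of the 48 arrangements occurs exactly
  twice per session, in randomized order.
* **Responses**: each block, a strategy is drawn from a per-condition
  mixture (strategy use is taken to drift at the block level — the middle
  ground between erratic strategy execution and inconsistent strategy
  selection); each trial follows that strategy's prediction except with
  lapse probability epsilon, where the response is uniform over the three
  positions.  Abstaining predictions are likewise answered uniformly.  A
  small fraction of participants press one fixed key throughout (bias).
* **Ratings**: pairwise similarity on a 1-9 scale over two 56-trial blocks
  (every pair twice per block, left/right counterbalanced), generated as a
  clamped, rounded affine function of scaled distance plus Gaussian noise.

Default mixtures put per-block UD probability at 0.12 (100 ms) versus 0.02
(2000 ms) with a small ID component and lapse 0.05 — prevalences of the
order observed empirically in this paradigm — and allocate participants
29/17 (about 2:1, the short condition being noisier).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .response_models import BIAS_STRATEGIES, PredictionTable, Strategy, build_prediction_table
from .stimulus_space import DESIGN_TRIADS, StimulusSpace, TriadInstance, enumerate_instances
from .strategy_fit import BLOCKS_PER_SESSION, TRIALS_PER_BLOCK, TrialRecord

__all__ = ["SimConfig", "substream", "generate_design", "generate_responses",
           "generate_ratings", "simulate_experiment"]

SHORT_MS = 100
LONG_MS = 2000

_DEFAULT_MIXTURES: dict[int, dict[Strategy, float]] = {
    SHORT_MS: {Strategy.UD_CHROMA: 0.06, Strategy.UD_BRIGHTNESS: 0.06,
               Strategy.OS: 0.875, Strategy.ID: 0.005},
    LONG_MS: {Strategy.UD_CHROMA: 0.01, Strategy.UD_BRIGHTNESS: 0.01,
              Strategy.OS: 0.975, Strategy.ID: 0.005},
}


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for synthetic sessions and ratings."""

    n_participants: Mapping[int, int] = field(
        default_factory=lambda: {SHORT_MS: 29, LONG_MS: 17})
    mixtures: Mapping[int, Mapping[Strategy, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in _DEFAULT_MIXTURES.items()})
    lapse: float = 0.05
    bias_prob: float = 0.02
    rating_intercept: float = 9.5
    rating_slope: float = 1.5
    rating_noise_sd: float = 1.0
    n_raters: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        if not 0.0 <= self.bias_prob <= 1.0:
            raise ValueError("bias_prob must be in [0, 1]")
        for cond, mix in self.mixtures.items():
            probs = np.array(list(mix.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture for {cond} ms must be a probability vector")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one root seed."""
    hashed = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *hashed]))


def generate_design(participant: str, rng: np.random.Generator) -> list[TriadInstance]:
    """Randomized 96-trial sequence honouring the block constraints."""
    slots: dict[tuple[int, int, int], list[TriadInstance]] = {}
    for triad in DESIGN_TRIADS:
        arrangements = enumerate_instances([triad]) * 2  # each arrangement twice
        rng.shuffle(arrangements)
        slots[triad] = arrangements
    order: list[TriadInstance] = []
    for block in range(BLOCKS_PER_SESSION):
        block_instances = [slots[t][block] for t in DESIGN_TRIADS]
        rng.shuffle(block_instances)
        order.extend(block_instances)
    return order


def generate_responses(design: Sequence[TriadInstance], participant: str,
                       condition_ms: int, config: SimConfig,
                       rng: np.random.Generator,
                       table: PredictionTable) -> list[TrialRecord]:
    """Responses for one participant under the block-level strategy mixture."""
    mix = config.mixtures[condition_ms]
    strategies = list(mix)
    probs = np.array([mix[s] for s in strategies], dtype=float)

    is_bias = rng.random() < config.bias_prob
    bias_strategy = BIAS_STRATEGIES[rng.integers(3)] if is_bias else None

    trials: list[TrialRecord] = []
    for block in range(BLOCKS_PER_SESSION):
        strategy = bias_strategy if is_bias else strategies[
            rng.choice(len(strategies), p=probs)]
        for trial_in_block in range(TRIALS_PER_BLOCK):
            inst = design[block * TRIALS_PER_BLOCK + trial_in_block]
            pred = table.predict(strategy, inst)
            if pred is None or rng.random() < config.lapse:
                response = int(rng.integers(1, 4))
            else:
                response = pred
            trials.append(TrialRecord(
                participant=participant, condition_ms=condition_ms,
                block=block + 1, trial=trial_in_block + 1,
                instance=inst, response=response))
    return trials


def simulate_experiment(space: StimulusSpace, config: SimConfig,
                        seed: int | None = None) -> tuple[list[TrialRecord], dict[str, int]]:
    """Full two-condition experiment; returns trials and participant->condition map."""
    seed = config.seed if seed is None else seed
    table = build_prediction_table(space, enumerate_instances(
        [tuple(t) for t in DESIGN_TRIADS]))
    trials: list[TrialRecord] = []
    condition_of: dict[str, int] = {}
    counter = 0
    for cond in sorted(config.n_participants):
        for _ in range(config.n_participants[cond]):
            counter += 1
            pid = f"p{counter:03d}"
            condition_of[pid] = cond
            design = generate_design(pid, substream(seed, "design", pid))
            trials.extend(generate_responses(
                design, pid, cond, config, substream(seed, "responses", pid), table))
    return trials, condition_of


def generate_ratings(space: StimulusSpace, config: SimConfig,
                     seed: int | None = None) -> pd.DataFrame:
    """Similarity-rating tables for ``config.n_raters`` synthetic raters.

    Long form: ``participant, block, left, right, rating``.  Each block
    presents all 28 pairs twice with left/right counterbalanced; ratings are
    ``clamp(round(intercept - slope * distance + noise), 1, 9)``, so the
    noise-free mean rating decreases strictly with scaled distance.
    """
    ids = space.ids
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rows = []
    seed = config.seed if seed is None else seed
    for r in range(config.n_raters):
        pid = f"r{r + 1:03d}"
        rng = substream(seed, "ratings", pid)
        for block in (1, 2):
            presentations = [(a, b) for a, b in pairs] + [(b, a) for a, b in pairs]
            rng.shuffle(presentations)
            for left, right in presentations:
                mean = (config.rating_intercept
                        - config.rating_slope * space.distance(left, right))
                noisy = mean + rng.normal(0.0, config.rating_noise_sd)
                rows.append({"participant": pid, "block": block,
                             "left": left, "right": right,
                             "rating": int(np.clip(np.round(noisy), 1, 9))})
    return pd.DataFrame(rows)
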