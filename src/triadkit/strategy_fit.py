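"""Scoring responses against strategy predictions.

A participant contributes 96 odd-one-out responses (12 blocks of 8 trials,
one arrangement of each logical triad per block).  For each strategy the
match count is the number of trials whose response equals the strategy's
(non-abstaining) prediction.  The best-fitting strategy is the argmax after
collapsing the two UD dimensions (a unidimensional responder uses one
dimension, so the family count is the max, not the sum) and the three bias
keys.  The same scoring applied to each 8-trial block separately — with bias
excluded, since key bias is only identifiable once stimulus positions have
been counterbalanced over the whole session — gives the more sensitive
by-block prevalence analysis; blocks where strategy families tie for first
place are removed, and per-participant strategy proportions are computed
over the remaining blocks.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .response_models import (
    BIAS_STRATEGIES,
    BLOCK_STRATEGIES,
    UD_STRATEGIES,
    PredictionTable,
    Strategy,
)
from .stimulus_space import TriadInstance

__all__ = [
    "TrialRecord",
    "ParticipantFit",
    "BlockFit",
    "PrevalenceSummary",
    "TIED",
    "score_participant",
    "score_blocks",
    "summarize_prevalence",
    "ud_distribution",
]

TIED = "TIED"

TRIALS_PER_BLOCK = 8
BLOCKS_PER_SESSION = 12


@dataclass(frozen=True)
class TrialRecord:
    """One odd-one-out response in context."""

    participant: str
    condition_ms: int
    block: int
    trial: int
    instance: TriadInstance
    response: int  # chosen odd position, 1|2|3

    def __post_init__(self) -> None:
        if self.response not in (1, 2, 3):
            raise ValueError(f"response must be 1, 2 or 3, got {self.response}")


@dataclass
class ParticipantFit:
    participant: str
    counts: dict[Strategy, int]
    winner: str  # family: UD | OS | ID | Bias
    winner_detail: Optional[str]  # winning dimension / bias key
    tied: bool

    @property
    def family_counts(self) -> dict[str, int]:
        return _collapse(self.counts)


@dataclass
class BlockFit:
    participant: str
    block: int
    counts: dict[Strategy, int]
    winner: str  # UD | OS | ID | TIED

    @property
    def tied(self) -> bool:
        return self.winner == TIED


def _collapse(counts: Mapping[Strategy, int]) -> dict[str, int]:
    """Collapse raw strategy counts to family counts (UD/Bias via max)."""
    fam: dict[str, int] = {}
    for s, c in counts.items():
        fam[s.family] = max(fam.get(s.family, -1), c)
    return fam


def _count_matches(trials: Sequence[TrialRecord], table: PredictionTable,
                   strategies: Iterable[Strategy]) -> dict[Strategy, int]:
    counts = {s: 0 for s in strategies}
    for t in trials:
        for s in counts:
            if table.predict(s, t.instance) == t.response:
                counts[s] += 1
    return counts


def score_participant(trials: Sequence[TrialRecord], table: PredictionTable) -> ParticipantFit:
    """Best-fitting strategy over a participant's full session."""
    pids = {t.participant for t in trials}
    if len(pids) != 1:
        raise ValueError(f"trials must come from one participant, got {sorted(pids)}")
    counts = _count_matches(trials, table, Strategy)
    fam = _collapse(counts)
    best = max(fam.values())
    winners = sorted(f for f, c in fam.items() if c == best)
    winner = winners[0]
    detail: Optional[str] = None
    if winner == "UD":
        detail = max(UD_STRATEGIES, key=lambda s: counts[s]).value
    elif winner == "Bias":
        detail = max(BIAS_STRATEGIES, key=lambda s: counts[s]).value
    return ParticipantFit(participant=pids.pop(), counts=counts, winner=winner,
                          winner_detail=detail, tied=len(winners) > 1)


def score_blocks(trials: Sequence[TrialRecord], table: PredictionTable) -> list[BlockFit]:
    """Best-fitting strategy per 8-trial block (bias excluded)."""
    by_block: dict[tuple[str, int], list[TrialRecord]] = {}
    for t in trials:
        by_block.setdefault((t.participant, t.block), []).append(t)
    fits = []
    for (pid, block), ts in sorted(by_block.items()):
        if len(ts) != TRIALS_PER_BLOCK:
            raise ValueError(
                f"participant {pid} block {block}: expected {TRIALS_PER_BLOCK} trials, got {len(ts)}")
        counts = _count_matches(ts, table, BLOCK_STRATEGIES)
        fam = _collapse(counts)
        best = max(fam.values())
        winners = [f for f, c in fam.items() if c == best]
        fits.append(BlockFit(participant=pid, block=block, counts=counts,
                             winner=winners[0] if len(winners) == 1 else TIED))
    return fits


@dataclass
class PrevalenceSummary:
    """Condition-level mean proportions of UD/OS/ID blocks.

    Proportions are computed per participant over that participant's
    non-tied blocks (each participant weighted equally within condition),
    mirroring a "mean proportion of blocks" analysis with tied blocks
    removed.
    """

    proportions: pd.DataFrame  # index: condition_ms; columns UD, OS, ID
    n_participants: dict[int, int]
    n_tied_removed: int
    n_blocks_total: int
    excluded_participants: list[str] = field(default_factory=list)

    @property
    def tie_rate(self) -> float:
        return self.n_tied_removed / self.n_blocks_total if self.n_blocks_total else 0.0


def participant_proportions(block_fits: Sequence[BlockFit]) -> pd.DataFrame:
    """Per-participant proportions of non-tied blocks won by each family."""
    rows = []
    for pid in sorted({f.participant for f in block_fits}):
        wins = Counter(f.winner for f in block_fits
                       if f.participant == pid and not f.tied)
        total = sum(wins.values())
        if total == 0:
            rows.append({"participant": pid, "UD": np.nan, "OS": np.nan,
                         "ID": np.nan, "n_blocks": 0})
            continue
        rows.append({"participant": pid,
                     **{f: wins.get(f, 0) / total for f in ("UD", "OS", "ID")},
                     "n_blocks": total})
    return pd.DataFrame(rows).set_index("participant")


def summarize_prevalence(block_fits: Sequence[BlockFit],
                         condition_of: Mapping[str, int]) -> PrevalenceSummary:
    """Mean UD/OS/ID block proportions per condition.

    ``condition_of`` maps participant id to presentation time in ms.  Bias
    participants are expected to have been excluded upstream.  Participants
    with no non-tied blocks are dropped with a warning.
    """
    per = participant_proportions(block_fits)
    excluded = list(per.index[per["n_blocks"] == 0])
    if excluded:
        warnings.warn(f"participants with zero non-tied blocks excluded: {excluded}",
                      stacklevel=2)
        per = per[per["n_blocks"] > 0]
    per = per.copy()
    per["condition_ms"] = [condition_of[p] for p in per.index]
    props = per.groupby("condition_ms")[["UD", "OS", "ID"]].mean()
    n_by_cond = per.groupby("condition_ms").size().to_dict()
    n_tied = sum(1 for f in block_fits if f.tied)
    return PrevalenceSummary(
        proportions=props,
        n_participants={int(k): int(v) for k, v in n_by_cond.items()},
        n_tied_removed=n_tied,
        n_blocks_total=len(block_fits),
        excluded_participants=excluded,
    )


def ud_distribution(block_fits: Sequence[BlockFit],
                    condition_of: Mapping[str, int]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """How UD responding is distributed over participants and over blocks.

    Returns ``(per_participant, trajectory)``: UD-block counts per
    participant (histogram source), and the proportion of participants whose
    block at each serial position was best fit by UD, by condition.
    """
    rows = []
    for pid in sorted({f.participant for f in block_fits}):
        n_ud = sum(1 for f in block_fits if f.participant == pid and f.winner == "UD")
        n_ok = sum(1 for f in block_fits if f.participant == pid and not f.tied)
        rows.append({"participant": pid, "condition_ms": condition_of[pid],
                     "ud_blocks": n_ud, "non_tied_blocks": n_ok})
    per_participant = pd.DataFrame(rows).set_index("participant")

    traj_rows = []
    conds = sorted({condition_of[f.participant] for f in block_fits})
    for cond in conds:
        for block in sorted({f.block for f in block_fits}):
            here = [f for f in block_fits
                    if condition_of[f.participant] == cond and f.block == block
                    and not f.tied]
            if here:
                traj_rows.append({
                    "condition_ms": cond, "block": block,
                    "ud_prop": sum(f.winner == "UD" for f in here) / len(here),
                    "n": len(here)})
    trajectory = pd.DataFrame(traj_rows)
    return per_participant, trajectory
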