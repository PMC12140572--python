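"""CSV round-tripping for trials, ratings and coordinates."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .mds import SimilarityMatrix, mean_ratings_to_matrix
from .stimulus_space import StimulusSpace, TriadInstance
from .strategy_fit import TrialRecord

__all__ = [
    "SchemaError",
    "trials_to_frame", "frame_to_trials", "write_trials", "read_trials",
    "write_ratings", "read_ratings", "ratings_matrix_to_long",
    "write_coords", "read_coords",
]

TRIALS_COLUMNS = ["participant", "condition_ms", "block", "trial",
                  "left", "middle", "right", "response_pos"]
RATINGS_COLUMNS = ["participant", "block", "left", "right", "rating"]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"participant": t.participant, "condition_ms": t.condition_ms,
         "block": t.block, "trial": t.trial, "left": t.instance.left,
         "middle": t.instance.middle, "right": t.instance.right,
         "response_pos": t.response}
        for t in trials
    ], columns=TRIALS_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    _require_columns(df, TRIALS_COLUMNS, "trials table")
    out = []
    for idx, row in df.iterrows():
        try:
            response = int(row["response_pos"])
            if response not in (1, 2, 3):
                raise ValueError
            out.append(TrialRecord(
                participant=str(row["participant"]),
                condition_ms=int(row["condition_ms"]),
                block=int(row["block"]), trial=int(row["trial"]),
                instance=TriadInstance(int(row["left"]), int(row["middle"]),
                                       int(row["right"])),
                response=response))
        except (TypeError, ValueError):
            raise SchemaError(f"trials table row {idx}: malformed values "
                              f"{dict(row)}") from None
    return out


def write_trials(trials: Sequence[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path))


def write_ratings(ratings: pd.DataFrame, path) -> None:
    _require_columns(ratings, RATINGS_COLUMNS, "ratings table")
    ratings[RATINGS_COLUMNS].to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RATINGS_COLUMNS, "ratings table")
    bad = df.index[(df["rating"] < 1) | (df["rating"] > 9) | df["rating"].isna()]
    if len(bad):
        raise SchemaError(f"ratings table rows {list(bad[:5])}: rating outside 1-9")
    return df


def ratings_matrix_to_long(m: SimilarityMatrix) -> pd.DataFrame:
    """Matrix-form mean ratings as one long-form presentation per pair."""
    rows = []
    for i, a in enumerate(m.ids):
        for b in m.ids[i + 1:]:
            j = m.ids.index(b)
            rows.append({"participant": "mean", "block": 1, "left": a,
                         "right": b, "rating": m.values[i, j]})
    return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


def long_to_matrix(ratings: pd.DataFrame) -> SimilarityMatrix:
    return mean_ratings_to_matrix(ratings)


def write_coords(space: StimulusSpace, path) -> None:
    pd.DataFrame(
        [{"stimulus": i, "chroma": c, "brightness": b}
         for i, (c, b) in sorted(space.coords.items())]
    ).to_csv(path, index=False)


def read_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["stimulus", "chroma", "brightness"], "coordinates table")
    return df
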