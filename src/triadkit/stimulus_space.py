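"""The eight-stimulus design space for the triad (odd-one-out) task.

The stimuli are colored squares of fixed hue varying in Munsell chroma
(saturation, 4-12) and brightness (value, 2-6).  Psychologically, two units
of chroma are equivalent to one unit of brightness, so all distances are
computed after multiplying chroma by a weight of 0.5.

Eight logical triads are drawn from this set; each triad contains a pair of
stimuli identical on one dimension, and each logical triad can be laid out
left-to-right in six physical arrangements (48 arrangements in total).

The shipped coordinate file (``data/stimulus_space_reconstructed.csv``) is a
reconstruction, not a direct transcription: the exact published coordinates
were not available in machine-readable form, so the values were recovered by
enumerating integer Munsell grid placements and keeping the unique layout
consistent with every published design fact (coordinate ranges, the quoted
identity pairs, the worked-example predictions, quadrant membership, and the
reported misfit pattern of the rating-derived space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DESIGN_TRIADS",
    "CHROMA_RANGE",
    "BRIGHTNESS_RANGE",
    "DEFAULT_CHROMA_WEIGHT",
    "StimulusSpace",
    "LogicalTriad",
    "TriadInstance",
    "Quadrant",
    "DesignViolationError",
    "DiagnosabilityWarning",
    "load_space",
    "default_space",
    "design_triads",
    "enumerate_instances",
    "quadrant_partition",
    "filter_triads_excluding_quadrant",
]

#: The eight logical triads of the design, as stimulus-id triples.
DESIGN_TRIADS: tuple[tuple[int, int, int], ...] = (
    (1, 3, 7), (1, 5, 7), (2, 4, 8), (2, 6, 8),
    (1, 2, 3), (1, 2, 4), (5, 7, 8), (6, 7, 8),
)

CHROMA_RANGE = (4.0, 12.0)
BRIGHTNESS_RANGE = (2.0, 6.0)

#: Chroma multiplier equating 2 chroma units with 1 brightness unit.
DEFAULT_CHROMA_WEIGHT = 0.5

DIMENSIONS = ("chroma", "brightness")


class DesignViolationError(ValueError):
    """A stimulus table or triad breaks a structural requirement of the design."""


class DiagnosabilityWarning(UserWarning):
    """A triad subset can no longer discriminate the response strategies."""


class TriadInstance(NamedTuple):
    """One physical left/middle/right arrangement of a logical triad."""

    left: int
    middle: int
    right: int

    @property
    def members(self) -> frozenset[int]:
        return frozenset(self)

    def position_of(self, stimulus: int) -> int:
        """1-based display position of ``stimulus`` in this arrangement."""
        return self.index(stimulus) + 1


@dataclass(frozen=True)
class StimulusSpace:
    """Stimulus ids mapped to 2-D (chroma, brightness) coordinates.

    ``chroma_weight`` scales chroma before any distance computation so that
    the two axes are in common psychological units.  Spaces derived from
    similarity scaling are already in those units and use a weight of 1.
    """

    coords: Mapping[int, tuple[float, float]]
    chroma_weight: float = DEFAULT_CHROMA_WEIGHT

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", dict(self.coords))

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.coords))

    def value(self, stimulus: int, dimension: str) -> float:
        c, b = self.coords[stimulus]
        if dimension == "chroma":
            return c
        if dimension == "brightness":
            return b
        raise ValueError(f"unknown dimension {dimension!r}")

    def scaled(self, stimulus: int) -> np.ndarray:
        """Coordinates in common units: (chroma * weight, brightness)."""
        c, b = self.coords[stimulus]
        return np.array([c * self.chroma_weight, b], dtype=float)

    def scaled_matrix(self, ids: Sequence[int] | None = None) -> np.ndarray:
        ids = self.ids if ids is None else tuple(ids)
        return np.vstack([self.scaled(i) for i in ids])

    def distance(self, a: int, b: int, metric: str = "euclidean") -> float:
        diff = self.scaled(a) - self.scaled(b)
        if metric == "euclidean":
            return float(np.hypot(*diff))
        if metric == "cityblock":
            return float(np.abs(diff).sum())
        raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class LogicalTriad:
    """Three distinct stimuli with a designed identity pair.

    ``identity_dimension`` is the dimension on which ``identity_pair`` shares
    a coordinate.  Where a triad happens to contain an identical pair on each
    dimension (the design permits this: an identity pair of one triad can
    reappear as a side effect in another), the designed identity is the one
    on the dimension the triad does *not* span, i.e. the dimension with the
    smaller within-triad scaled range.
    """

    members: frozenset[int]
    identity_dimension: str
    identity_pair: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise DesignViolationError(f"triad must have 3 distinct members, got {set(self.members)}")


def _identical_pairs(members: Iterable[int], space: StimulusSpace) -> dict[str, list[frozenset[int]]]:
    ms = sorted(members)
    out: dict[str, list[frozenset[int]]] = {d: [] for d in DIMENSIONS}
    for i, a in enumerate(ms):
        for b in ms[i + 1:]:
            for dim in DIMENSIONS:
                if space.value(a, dim) == space.value(b, dim):
                    out[dim].append(frozenset((a, b)))
    return out


def resolve_identity(members: Iterable[int], space: StimulusSpace) -> tuple[str, frozenset[int]] | None:
    """The designed identity (dimension, pair) of a triad, or None.

    Raises :class:`DesignViolationError` when the identity is ambiguous: two
    identical pairs on the same dimension, or identical pairs on both
    dimensions with equal within-triad scaled ranges.
    """
    members = tuple(members)
    pairs = _identical_pairs(members, space)
    for dim, found in pairs.items():
        if len(found) > 1:
            raise DesignViolationError(
                f"triad {sorted(members)} has multiple identical pairs on {dim}")
    present = [d for d in DIMENSIONS if pairs[d]]
    if not present:
        return None
    if len(present) == 1:
        dim = present[0]
        return dim, pairs[dim][0]
    # Identical pair on each dimension: take the non-spanned (narrow) one.
    X = space.scaled_matrix(members)
    ranges = X.max(axis=0) - X.min(axis=0)  # columns: scaled chroma, brightness
    if ranges[0] == ranges[1]:
        raise DesignViolationError(
            f"triad {sorted(members)}: identity ambiguous between dimensions")
    dim = DIMENSIONS[int(np.argmin(ranges))]
    return dim, pairs[dim][0]


def make_logical_triad(members: Iterable[int], space: StimulusSpace) -> LogicalTriad:
    members = frozenset(members)
    resolved = resolve_identity(members, space)
    if resolved is None:
        raise DesignViolationError(
            f"triad {sorted(members)} has no identical pair on either dimension")
    dim, pair = resolved
    return LogicalTriad(members=members, identity_dimension=dim, identity_pair=pair)


def design_triads(space: StimulusSpace) -> list[LogicalTriad]:
    """The eight logical triads of the design, identity structure derived
    from (and validated against) ``space``."""
    return [make_logical_triad(t, space) for t in DESIGN_TRIADS]


def load_space(coord_table, chroma_weight: float = DEFAULT_CHROMA_WEIGHT) -> StimulusSpace:
    """Load and validate a design-space coordinate table.

    ``coord_table`` is a CSV path or DataFrame with columns
    ``stimulus, chroma, brightness`` and one row per stimulus id 1-8.
    """
    df = coord_table if isinstance(coord_table, pd.DataFrame) else pd.read_csv(coord_table)
    required = {"stimulus", "chroma", "brightness"}
    if not required.issubset(df.columns):
        raise DesignViolationError(f"coordinate table needs columns {sorted(required)}")
    for col in ("chroma", "brightness"):
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number) \
                or pd.to_numeric(df[col], errors="coerce").isna().any():
            raise DesignViolationError(f"non-numeric entry in column {col!r}")
    ids = sorted(int(s) for s in df["stimulus"])
    if ids != list(range(1, 9)):
        missing = sorted(set(range(1, 9)) - set(ids))
        if missing:
            raise DesignViolationError(f"missing stimulus {missing}")
        raise DesignViolationError(f"unexpected stimulus ids {ids}")
    coords = {}
    for _, row in df.iterrows():
        c, b = float(row["chroma"]), float(row["brightness"])
        if not CHROMA_RANGE[0] <= c <= CHROMA_RANGE[1]:
            raise DesignViolationError(
                f"stimulus {int(row['stimulus'])}: chroma {c} outside {CHROMA_RANGE}")
        if not BRIGHTNESS_RANGE[0] <= b <= BRIGHTNESS_RANGE[1]:
            raise DesignViolationError(
                f"stimulus {int(row['stimulus'])}: brightness {b} outside {BRIGHTNESS_RANGE}")
        coords[int(row["stimulus"])] = (c, b)
    space = StimulusSpace(coords, chroma_weight=chroma_weight)
    design_triads(space)  # assert: every design triad resolves to one identity pair
    return space


def default_space() -> StimulusSpace:
    """The packaged reconstruction of the design coordinates."""
    with resources.as_file(resources.files("triadkit.data")
                           / "stimulus_space_reconstructed.csv") as p:
        return load_space(p)


def enumerate_instances(triads: Sequence) -> list[TriadInstance]:
    """Every ordered left/middle/right arrangement of each triad (6 apiece)."""
    from itertools import permutations

    out: list[TriadInstance] = []
    for t in triads:
        members = sorted(t.members if isinstance(t, LogicalTriad) else t)
        if len(set(members)) != 3:
            raise DesignViolationError(f"triad with duplicate members: {members}")
        out.extend(TriadInstance(*p) for p in permutations(members))
    return out


@dataclass(frozen=True)
class Quadrant:
    """One quarter of the design space (split at the coordinate midpoints)."""

    label: str  # LCLB | LCHB | HCLB | HCHB
    members: frozenset[int] = field(default_factory=frozenset)


def quadrant_partition(space: StimulusSpace) -> dict[str, Quadrant]:
    """Assign stimuli to quadrants split at the midpoints of the design ranges.

    A stimulus sitting exactly on a midpoint inherits the undecided
    coordinate's side from its nearest (scaled-distance) neighbour that is
    not itself on a midpoint.
    """
    cmid = sum(CHROMA_RANGE) / 2
    bmid = sum(BRIGHTNESS_RANGE) / 2
    offmid = [i for i in space.ids
              if space.value(i, "chroma") != cmid and space.value(i, "brightness") != bmid]

    def side(stim: int) -> str:
        c, b = space.coords[stim]
        if c == cmid or b == bmid:
            nn = min((j for j in offmid if j != stim),
                     key=lambda j: float(np.linalg.norm(space.scaled(stim) - space.scaled(j))))
            cn, bn = space.coords[nn]
            c = cn if c == cmid else c
            b = bn if b == bmid else b
        return ("H" if c > cmid else "L") + "C" + ("H" if b > bmid else "L") + "B"

    labels = ("LCLB", "LCHB", "HCLB", "HCHB")
    members: dict[str, set[int]] = {lab: set() for lab in labels}
    for i in space.ids:
        members[side(i)].add(i)
    return {lab: Quadrant(lab, frozenset(members[lab])) for lab in labels}


def filter_triads_excluding_quadrant(triads: Sequence[LogicalTriad],
                                     quadrant: Quadrant) -> list[LogicalTriad]:
    """Triads containing no member of ``quadrant``.

    Warns when the remaining set lacks either a chroma-identity or a
    brightness-identity triad, since a subset with identities on only one
    dimension cannot separate overall-similarity from unidimensional
    responding.
    """
    kept = [t for t in triads if not (t.members & quadrant.members)]
    dims = {t.identity_dimension for t in kept}
    if dims != set(DIMENSIONS):
        warnings.warn(
            f"removing quadrant {quadrant.label} leaves triads with identities "
            f"only on {sorted(dims) or 'no dimension'}; strategies are no longer "
            "diagnosable in this subset", DiagnosabilityWarning, stacklevel=2)
    return kept
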