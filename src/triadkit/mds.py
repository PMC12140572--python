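"""Non-metric multidimensional scaling and Procrustes alignment.

Recovers a psychological stimulus configuration from mean pairwise
similarity ratings.  The scaling follows Kruskal's formulation: starting
from the classical (Torgerson) metric solution, the configuration is moved
to minimize stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where ``d_ij`` are configuration distances (Euclidean or city-block) and
``dhat_ij`` is the monotone (isotonic) regression of those distances on the
rank order of the input dissimilarities.  Stress is reported multiplied by
100, the convention of the classical implementations of this algorithm.

Comparing the Euclidean and city-block fits operationalizes the
integral/separable distinction: integral dimension pairs are those whose
similarity structure a Euclidean metric fits better.

The gradient of stress with respect to the configuration treats the
isotonic fit as fixed (it is the minimizer of the inner least-squares
problem, so this is the standard Kruskal descent direction); city-block
distances contribute sign subgradients, with 0 at exact coordinate ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression

from .response_models import PredictionTable, build_prediction_table
from .stimulus_space import StimulusSpace, TriadInstance

__all__ = [
    "SimilarityMatrix",
    "MDSSolution",
    "ProcrustesResult",
    "load_similarity_matrix",
    "default_similarity_matrix",
    "mean_ratings_to_matrix",
    "similarity_to_dissimilarity",
    "classical_scaling",
    "nonmetric_mds",
    "procrustes_fit",
    "respace_prediction_table",
]

RATING_SCALE = (1.0, 9.0)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric mean ratings (1-9 scale) between the eight stimuli."""

    ids: tuple[int, ...]
    values: np.ndarray  # (n, n), diagonal unused

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")
        off = ~np.eye(len(self.ids), dtype=bool)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        vals = v[off]
        if np.isnan(vals).any() or (vals < RATING_SCALE[0]).any() or (vals > RATING_SCALE[1]).any():
            raise ValueError(f"ratings must lie in {RATING_SCALE}")


def load_similarity_matrix(path_or_df) -> SimilarityMatrix:
    """Read a matrix-form similarity CSV (first column: stimulus ids)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    df = df.set_index(df.columns[0])
    ids = tuple(int(i) for i in df.index)
    values = df.to_numpy(dtype=float)
    np.fill_diagonal(values, 0.0)
    return SimilarityMatrix(ids=ids, values=values)


def default_similarity_matrix() -> SimilarityMatrix:
    """The packaged mean pairwise similarity ratings of the eight stimuli."""
    with resources.as_file(resources.files("triadkit.data") / "similarity_ratings.csv") as p:
        return load_similarity_matrix(p)


def mean_ratings_to_matrix(ratings: pd.DataFrame) -> SimilarityMatrix:
    """Average a long-form rating table into a symmetric matrix."""
    r = ratings.copy()
    r["a"] = r[["left", "right"]].min(axis=1)
    r["b"] = r[["left", "right"]].max(axis=1)
    means = r.groupby(["a", "b"])["rating"].mean()
    ids = tuple(sorted(set(r["a"]) | set(r["b"])))
    n = len(ids)
    pos = {s: i for i, s in enumerate(ids)}
    m = np.zeros((n, n))
    for (a, b), v in means.items():
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = v
    return SimilarityMatrix(ids=ids, values=m)


def similarity_to_dissimilarity(m: SimilarityMatrix, rule: str = "shift10") -> np.ndarray:
    """Monotone conversion of similarities to dissimilarities.

    ``shift10`` (default): delta = 10 - s, mapping the 1-9 rating scale onto
    9-1.  Alternatives: ``max_minus`` (max(s) + 1 - s) and ``reciprocal``
    (9 / s).  All are strictly decreasing in similarity; the choice affects
    only the dissimilarity *ranks*' spacing, and non-metric scaling uses the
    ranks alone.
    """
    s = m.values.copy()
    off = ~np.eye(len(m.ids), dtype=bool)
    if rule == "shift10":
        d = 10.0 - s
    elif rule == "max_minus":
        d = s[off].max() + 1.0 - s
    elif rule == "reciprocal":
        with np.errstate(divide="ignore"):
            d = 9.0 / s
    else:
        raise ValueError(f"unknown conversion rule {rule!r}")
    np.fill_diagonal(d, 0.0)
    if (d[off] <= 0).any() or not np.isfinite(d[off]).all():
        raise ValueError("conversion produced non-positive dissimilarities")
    return d


@dataclass
class MDSSolution:
    """A 2-D configuration with its Kruskal stress (in percent)."""

    ids: tuple[int, ...]
    configuration: np.ndarray  # (n, 2), centered
    stress: float  # stress-1 x 100
    metric: str
    n_iter: int
    converged: bool

    def as_space(self, chroma_weight: float = 1.0) -> StimulusSpace:
        """The configuration as a stimulus space (axes already in common units)."""
        coords = {i: (float(x), float(y))
                  for i, (x, y) in zip(self.ids, self.configuration)}
        return StimulusSpace(coords, chroma_weight=chroma_weight)


def classical_scaling(delta: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson's metric scaling; the deterministic starting configuration."""
    n = delta.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (delta ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dims]
    return V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))


def _config_distances(X: np.ndarray, metric: str) -> np.ndarray:
    return pdist(X, metric="cityblock" if metric == "cityblock" else "euclidean")


def nonmetric_mds(delta: np.ndarray, metric: str = "euclidean", dims: int = 2,
                  init: Optional[np.ndarray] = None, tol: float = 1e-10,
                  max_iter: int = 500, n_restarts: int = 0,
                  seed: Optional[int] = None,
                  ids: Optional[Sequence[int]] = None) -> MDSSolution:
    """Kruskal non-metric MDS of a symmetric dissimilarity matrix.

    ``metric`` selects how configuration distances are computed inside the
    stress loop (``euclidean`` or ``cityblock``).  Deterministic: starts
    from classical scaling and descends with L-BFGS; ``n_restarts`` adds
    seeded random starting configurations and keeps the lowest-stress
    solution.  A degenerate input (all off-diagonal dissimilarities equal)
    carries no rank information and is returned unoptimized with
    ``converged=False``.
    """
    delta = np.asarray(delta, dtype=float)
    n = delta.shape[0]
    if delta.shape != (n, n) or not np.allclose(delta, delta.T):
        raise ValueError("delta must be a square symmetric matrix")
    iu = np.triu_indices(n, 1)
    dvec = delta[iu]
    if (dvec <= 0).any():
        raise ValueError("off-diagonal dissimilarities must be positive")
    ids = tuple(ids) if ids is not None else tuple(range(1, n + 1))

    X0 = np.asarray(init, dtype=float) if init is not None else classical_scaling(delta, dims)
    if np.ptp(dvec) == 0.0:
        X = X0 - X0.mean(axis=0)
        return MDSSolution(ids, X, _stress(X, dvec, metric) * 100.0, metric, 0, False)

    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    ranks = np.arange(len(dvec), dtype=float)

    def fit_monotone(d: np.ndarray) -> np.ndarray:
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(ranks, d[order])
        return dhat

    def objective(xflat: np.ndarray):
        X = xflat.reshape(n, dims)
        d = _config_distances(X, metric)
        dhat = fit_monotone(d)
        sstar = np.sum((d - dhat) ** 2)
        tstar = np.sum(d ** 2)
        stress = np.sqrt(sstar / tstar)
        if stress == 0.0:
            return 0.0, np.zeros(n * dims)
        coef = stress * ((d - dhat) / sstar - d / tstar)
        G = np.zeros((n, dims))
        m = 0
        for i in range(n):
            for j in range(i + 1, n):
                diff = X[i] - X[j]
                if metric == "cityblock":
                    g = np.sign(diff)
                else:
                    g = diff / d[m] if d[m] > 0 else np.zeros(dims)
                G[i] += coef[m] * g
                G[j] -= coef[m] * g
                m += 1
        return stress, G.ravel()

    starts = [X0]
    if n_restarts:
        rng = np.random.default_rng(seed)
        scale = np.abs(X0).max() or 1.0
        starts += [rng.normal(scale=scale, size=(n, dims)) for _ in range(n_restarts)]
    best = None
    for start in starts:
        res = minimize(objective, start.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    X = best.x.reshape(n, dims)
    X = X - X.mean(axis=0)
    return MDSSolution(ids, X, _stress(X, dvec, metric, order, iso, ranks) * 100.0,
                       metric, int(best.nit), bool(best.success))


def _stress(X: np.ndarray, dvec: np.ndarray, metric: str,
            order=None, iso=None, ranks=None) -> float:
    d = _config_distances(X, metric)
    if order is None:
        order = np.argsort(dvec, kind="stable")
        iso = IsotonicRegression(increasing=True)
        ranks = np.arange(len(dvec), dtype=float)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(ranks, d[order])
    tstar = np.sum(d ** 2)
    return float(np.sqrt(np.sum((d - dhat) ** 2) / tstar)) if tstar > 0 else 0.0


@dataclass
class ProcrustesResult:
    """Least-squares similarity transform of a configuration onto a target.

    The transform (orthogonal rotation/reflection, uniform scale,
    translation) preserves ratios of inter-point Euclidean distances.
    """

    rotation: np.ndarray  # (2, 2) orthogonal
    scale: float
    translation: np.ndarray  # (2,)
    aligned: np.ndarray  # (n, 2)
    residuals: np.ndarray  # per-point Euclidean misfit to the target
    residual_ss: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(X, float) @ self.rotation.T + self.translation


def procrustes_fit(config: np.ndarray, target: np.ndarray) -> ProcrustesResult:
    """Align ``config`` to ``target`` (rows in stimulus-id correspondence)."""
    X = np.asarray(config, dtype=float)
    T = np.asarray(target, dtype=float)
    if X.shape != T.shape:
        raise ValueError("configuration and target must have matching shapes")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("rank-deficient configuration cannot be aligned")
    mx, mt = X.mean(axis=0), T.mean(axis=0)
    Xc, Tc = X - mx, T - mt
    U, s, Vt = np.linalg.svd(Tc.T @ Xc)
    R = U @ Vt
    scale = s.sum() / np.sum(Xc ** 2)
    translation = mt - scale * mx @ R.T
    aligned = scale * X @ R.T + translation
    residuals = np.sqrt(((aligned - T) ** 2).sum(axis=1))
    return ProcrustesResult(rotation=R, scale=float(scale), translation=translation,
                            aligned=aligned, residuals=residuals,
                            residual_ss=float((residuals ** 2).sum()))


def respace_prediction_table(solution: MDSSolution | StimulusSpace,
                             instances: Sequence[TriadInstance]) -> PredictionTable:
    """Strategy predictions computed in a scaling-derived space.

    The solution's (aligned) axes stand in for the chroma and brightness
    axes and are already in common psychological units, so no chroma
    weighting is applied.  Because recovered coordinates are generic floats,
    the identity model abstains on every arrangement in such a space.
    """
    space = solution.as_space() if isinstance(solution, MDSSolution) else solution
    return build_prediction_table(space, instances)
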