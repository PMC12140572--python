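"""End-to-end orchestration: simulate -> fit -> scale -> re-fit -> infer.

``run_pipeline`` executes the full analysis on synthetic data (or on trial
and rating files supplied in the config) and writes a report bundle:
prevalence tables, per-participant fits, MDS coordinates, Bayes-factor and
power results, and a manifest recording the seed and a hash of the
configuration so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .bayes_stats import (ContingencyTable, block_trend_ols, contingency_bf,
                          dienes_bf, effect_summary_from_groups, jzs_ttest_bf,
                          power_chisq, power_ttest)
from .io import read_trials, write_trials
from .mds import (mean_ratings_to_matrix, nonmetric_mds, procrustes_fit,
                  respace_prediction_table, similarity_to_dissimilarity)
from .response_models import Strategy, build_prediction_table
from .stimulus_space import (DESIGN_TRIADS, default_space, enumerate_instances,
                             load_space)
from .strategy_fit import (participant_proportions, score_blocks,
                           score_participant, summarize_prevalence,
                           ud_distribution)
from .synthetic_data import SimConfig, generate_ratings, simulate_experiment

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: Path
    coords_path: Optional[Path] = None
    trials_path: Optional[Path] = None
    ratings_path: Optional[Path] = None
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    mds_metrics: tuple[str, ...] = ("euclidean", "cityblock")
    similarity_rule: str = "shift10"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded: it cannot affect results)."""
        def enc(o):
            if isinstance(o, PipelineConfig):
                d = dataclasses.asdict(o)
                d.pop("out_dir", None)
                return {k: enc(v) for k, v in d.items()}
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, Strategy):
                return o.value
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    space = load_space(config.coords_path) if config.coords_path else default_space()
    sim = config.sim.with_(seed=config.seed)

    # --- trials: simulate or load ---------------------------------------
    if config.trials_path:
        trials = read_trials(config.trials_path)
        condition_of = {t.participant: t.condition_ms for t in trials}
    else:
        trials, condition_of = simulate_experiment(space, sim)
        write_trials(trials, out / "trials.csv")

    instances = enumerate_instances(list(DESIGN_TRIADS))
    table = build_prediction_table(space, instances)

    # --- participant-level fits; bias exclusion --------------------------
    by_pid: dict[str, list] = {}
    for t in trials:
        by_pid.setdefault(t.participant, []).append(t)
    fits = {pid: score_participant(ts, table) for pid, ts in sorted(by_pid.items())}
    bias_pids = [p for p, f in fits.items() if f.winner == "Bias"]
    kept = [t for t in trials if t.participant not in bias_pids]

    # --- by-block analysis ------------------------------------------------
    block_fits = score_blocks(kept, table)
    prevalence = summarize_prevalence(block_fits, condition_of)
    per_participant, trajectory = ud_distribution(block_fits, condition_of)

    # --- inference --------------------------------------------------------
    conds = sorted({t.condition_ms for t in trials})
    short, long_ = conds[0], conds[-1]
    tab = np.zeros((2, 2))
    for pid, f in fits.items():
        if f.winner in ("UD", "OS"):
            i = 0 if condition_of[pid] == short else 1
            tab[i, 0 if f.winner == "UD" else 1] += 1
    results: dict = {"seed": config.seed, "conditions_ms": conds}
    if (tab.sum(axis=1) > 0).all():
        results["contingency_bf10"] = contingency_bf(ContingencyTable(tab)).bf10
        results["contingency_table"] = tab.tolist()

    props = participant_proportions(block_fits).dropna()
    ud_short = [props.loc[p, "UD"] for p in props.index if condition_of[p] == short]
    ud_long = [props.loc[p, "UD"] for p in props.index if condition_of[p] == long_]
    if len(ud_short) >= 2 and len(ud_long) >= 2:
        results["jzs_bf10"] = jzs_ttest_bf(ud_short, ud_long).bf10
        eff = effect_summary_from_groups(ud_short, ud_long)
        results["ud_effect"] = {"diff": eff.effect, "se": eff.se,
                                "n": [eff.n1, eff.n2]}
        if eff.effect != 0:
            results["dienes_bf10"] = dienes_bf(eff, prior_mean=eff.effect).bf10
    results["power"] = {
        "chisq_w40_n46_df1": power_chisq(0.40, 46, 1),
        "ttest_d083_n25_25": power_ttest(0.83, 25, 25),
    }
    if not trajectory.empty and trajectory["condition_ms"].nunique() == 2:
        ols = block_trend_ols(trajectory)
        results["block_trend"] = {
            "df_resid": ols.attrs["df_resid"],
            "coef": ols["coef"].to_dict(), "t": ols["t"].to_dict(),
            "p": ols["p"].to_dict()}

    # --- similarity scaling ----------------------------------------------
    if config.ratings_path:
        import pandas as pd
        ratings = pd.read_csv(config.ratings_path)
    else:
        ratings = generate_ratings(space, sim)
        ratings.to_csv(out / "ratings.csv", index=False)
    sim_matrix = mean_ratings_to_matrix(ratings)
    delta = similarity_to_dissimilarity(sim_matrix, config.similarity_rule)
    mds_results = {}
    solutions = {}
    for metric in config.mds_metrics:
        sol = nonmetric_mds(delta, metric=metric, ids=sim_matrix.ids)
        solutions[metric] = sol
        mds_results[metric] = {"stress_pct": sol.stress, "converged": sol.converged,
                               "n_iter": sol.n_iter}
    results["mds"] = mds_results
    best = solutions.get("euclidean") or next(iter(solutions.values()))
    target = space.scaled_matrix(best.ids)
    proc = procrustes_fit(best.configuration, target)
    results["procrustes"] = {
        "residual_ss": proc.residual_ss,
        "residuals": {int(i): float(r) for i, r in zip(best.ids, proc.residuals)},
    }
    import pandas as pd
    pd.DataFrame({"stimulus": best.ids,
                  "dim1": proc.aligned[:, 0], "dim2": proc.aligned[:, 1]}
                 ).to_csv(out / "mds_coordinates.csv", index=False)

    # --- re-fit in the recovered space -----------------------------------
    mds_space = best.as_space()
    mds_space = type(mds_space)(
        {i: (x, y) for i, (x, y) in zip(best.ids, proc.aligned)}, chroma_weight=1.0)
    table2 = respace_prediction_table(mds_space, instances)
    block_fits2 = score_blocks(kept, table2)
    prevalence2 = summarize_prevalence(block_fits2, condition_of)
    results["prevalence"] = {
        "design_space": prevalence.proportions.round(6).to_dict(),
        "mds_space": prevalence2.proportions.round(6).to_dict(),
        "tie_rate_design": prevalence.tie_rate,
        "tie_rate_mds": prevalence2.tie_rate,
        "n_bias_excluded": len(bias_pids),
    }

    # --- report bundle ----------------------------------------------------
    manifest = {"package_version": __version__, "seed": config.seed,
                "config_hash": config.config_hash()}
    results["manifest"] = manifest
    fits_json = {
        pid: {"winner": f.winner, "detail": f.winner_detail, "tied": f.tied,
              "counts": {s.value: c for s, c in f.counts.items()}}
        for pid, f in fits.items()}
    (out / "fits.json").write_text(json.dumps(fits_json, indent=1, sort_keys=True,
                                              default=_jsonable))
    (out / "report.json").write_text(json.dumps(results, indent=1, sort_keys=True,
                                                default=_jsonable))
    per_participant.to_csv(out / "ud_per_participant.csv")
    trajectory.to_csv(out / "ud_trajectory.csv", index=False)
    return results
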