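"""Participant- and block-level strategy classification."""

import numpy as np
import pytest

import triadkit as tk
from triadkit.response_models import ABSTAIN, Strategy
from triadkit.strategy_fit import TIED, TrialRecord
from triadkit.synthetic_data import SimConfig, generate_design, generate_responses, substream


def make_session(space, table, strategy, lapse=0.0, seed=0, pid="p1", cond=100):
    """One synthetic participant executing a fixed strategy."""
    cfg = SimConfig(mixtures={cond: {strategy: 1.0}}, lapse=lapse, bias_prob=0.0)
    design = generate_design(pid, substream(seed, "design", pid))
    return generate_responses(design, pid, cond, cfg, substream(seed, "resp", pid), table)


def recount(trials, table, strategies):
    """Independent tally loop (oracle for the scoring implementation)."""
    counts = {}
    for s in strategies:
        n = 0
        for t in trials:
            p = table.predict(s, t.instance)
            if p is not ABSTAIN and p == t.response:
                n += 1
        counts[s] = n
    return counts


class TestScoreParticipant:
    def test_pure_os_scores_96(self, space, table):
        trials = make_session(space, table, Strategy.OS)
        fit = tk.score_participant(trials, table)
        assert fit.counts[Strategy.OS] == 96
        assert fit.winner == "OS" and not fit.tied

    def test_constant_key_is_bias(self, space, table):
        trials = make_session(space, table, Strategy.OS)
        pressed = [TrialRecord(t.participant, t.condition_ms, t.block, t.trial,
                               t.instance, 1) for t in trials]
        fit = tk.score_participant(pressed, table)
        assert fit.counts[Strategy.BIAS_LEFT] == 96
        assert fit.winner == "Bias" and fit.winner_detail == "BIAS_LEFT"

    @pytest.mark.parametrize("strategy,lapse", [
        (Strategy.OS, 0.5), (Strategy.UD_BRIGHTNESS, 0.3), (Strategy.ID, 0.2)])
    def test_counts_match_recount_oracle(self, space, table, strategy, lapse):
        trials = make_session(space, table, strategy, lapse=lapse, seed=3)
        fit = tk.score_participant(trials, table)
        assert fit.counts == recount(trials, table, list(Strategy))

    def test_mixed_participants_rejected(self, space, table):
        t1 = make_session(space, table, Strategy.OS, pid="a")
        t2 = make_session(space, table, Strategy.OS, pid="b")
        with pytest.raises(ValueError, match="one participant"):
            tk.score_participant(t1 + t2, table)

    def test_collapse_order_is_irrelevant(self, space, table):
        # argmax over raw counts then collapse == collapse then argmax
        for seed in range(8):
            trials = make_session(space, table, Strategy.UD_CHROMA, lapse=0.4, seed=seed)
            fit = tk.score_participant(trials, table)
            raw_best = max(fit.counts, key=lambda s: (fit.counts[s], s.value))
            if not fit.tied:
                assert raw_best.family == fit.winner

    def test_match_count_decreases_with_lapse(self, space, table):
        means = []
        for lapse in (0.0, 0.4, 0.9):
            wins = [tk.score_participant(
                make_session(space, table, Strategy.OS, lapse=lapse, seed=s),
                table).counts[Strategy.OS] for s in range(6)]
            means.append(np.mean(wins))
        assert means[0] > means[1] > means[2]


class TestScoreBlocks:
    def test_pure_brightness_ud_blocks(self, space, table):
        trials = make_session(space, table, Strategy.UD_BRIGHTNESS)
        fits = tk.score_blocks(trials, table)
        assert len(fits) == 12
        assert all(f.winner == "UD" for f in fits)

    def test_block_winners_match_recount_oracle(self, space, table):
        cfg = SimConfig(mixtures={100: {Strategy.OS: 0.5, Strategy.UD_BRIGHTNESS: 0.3,
                                        Strategy.UD_CHROMA: 0.1, Strategy.ID: 0.1}},
                        lapse=0.2, bias_prob=0.0)
        design = generate_design("p9", substream(5, "d"))
        trials = generate_responses(design, "p9", 100, cfg, substream(5, "r"), table)
        for f in tk.score_blocks(trials, table):
            block_trials = [t for t in trials if t.block == f.block]
            counts = recount(block_trials, table, list(f.counts))
            assert counts == f.counts
            fam = {"UD": max(counts[Strategy.UD_CHROMA], counts[Strategy.UD_BRIGHTNESS]),
                   "OS": counts[Strategy.OS], "ID": counts[Strategy.ID]}
            best = max(fam.values())
            winners = [k for k, v in fam.items() if v == best]
            assert f.winner == (winners[0] if len(winners) == 1 else TIED)

    def test_incomplete_block_rejected(self, space, table):
        trials = make_session(space, table, Strategy.OS)[:-1]
        with pytest.raises(ValueError, match="expected 8 trials"):
            tk.score_blocks(trials, table)


class TestPrevalence:
    def test_all_os_gives_proportion_one(self, space, table):
        trials = []
        cond = {}
        for i, c in enumerate([100, 100, 2000]):
            pid = f"p{i}"
            trials += make_session(space, table, Strategy.OS, pid=pid, cond=c, seed=i)
            cond[pid] = c
        summary = tk.summarize_prevalence(tk.score_blocks(trials, table), cond)
        assert np.allclose(summary.proportions["OS"], 1.0)
        assert np.allclose(summary.proportions[["UD", "ID"]], 0.0)
        assert summary.n_tied_removed == 0

    def test_proportions_sum_to_one(self, space, table):
        cfg = SimConfig(lapse=0.1, bias_prob=0.0)
        trials, cond = tk.simulate_experiment(space, cfg, seed=11)
        per = tk.strategy_fit.participant_proportions(tk.score_blocks(trials, table))
        per = per.dropna()
        assert np.allclose(per[["UD", "OS", "ID"]].sum(axis=1), 1.0)

    def test_recovers_generating_mixture(self, space, table):
        # UD per-block probability 0.12 vs 0.02, lapse 0.05, n = 29/17
        trials, cond = tk.simulate_experiment(space, SimConfig(bias_prob=0.0), seed=42)
        summary = tk.summarize_prevalence(tk.score_blocks(trials, table), cond)
        for cond_ms, p_true, n in ((100, 0.12, 29), (2000, 0.02, 17)):
            se = np.sqrt(p_true * (1 - p_true) / 12 / n)
            assert abs(summary.proportions.loc[cond_ms, "UD"] - p_true) < 3 * se + 0.01


class TestUDDistribution:
    def test_all_os_input_gives_zero_ud_everywhere(self, space, table):
        trials = make_session(space, table, Strategy.OS)
        per, traj = tk.ud_distribution(tk.score_blocks(trials, table), {"p1": 100})
        assert (per["ud_blocks"] == 0).all()
        assert (traj["ud_prop"] == 0).all()

    def test_histogram_matches_binomial_oracle(self, space, table):
        p_ud = 0.25
        cfg = SimConfig(
            n_participants={100: 60},
            mixtures={100: {Strategy.UD_BRIGHTNESS: p_ud, Strategy.OS: 1 - p_ud}},
            lapse=0.0, bias_prob=0.0)
        trials, cond = tk.simulate_experiment(space, cfg, seed=9)
        per, _ = tk.ud_distribution(tk.score_blocks(trials, table), cond)
        mean_ud = per["ud_blocks"].mean()
        se = np.sqrt(12 * p_ud * (1 - p_ud) / len(per))
        assert abs(mean_ud - 12 * p_ud) < 3 * se
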