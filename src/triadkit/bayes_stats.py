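"""Bayesian and frequentist inference for strategy-prevalence comparisons.

Implements the inferential toolbox this paradigm relies on:

* a Gunel-Dickey Bayes factor for a 2x2 contingency table of participants
  by condition and strategy class, under independent-multinomial sampling
  with row totals fixed by design and Dirichlet(a, ..., a) priors;
* the JZS (Jeffreys-Zellner-Siow) two-sample Bayes factor, integrating the
  noncentral-t likelihood of the observed t statistic against a zero-
  centered Cauchy prior on standardized effect size;
* a replication Bayes factor in the style of Dienes: the alternative's
  prior on the raw effect is a normal centered on a previously observed
  effect with standard deviation half that effect;
* power of the chi-square and two-sample t tests from the noncentral
  chi-square / noncentral t distributions;
* an ordinary least-squares trend model for by-block UD proportions
  (intercept, block, presentation time, and their interaction; with 12
  blocks x 2 conditions this leaves 20 residual degrees of freedom).

All Bayes factors are reported as BF10 (evidence for the alternative over
the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import betaln

import statsmodels.api as sm

__all__ = [
    "ContingencyTable",
    "BFResult",
    "EffectSummary",
    "contingency_bf",
    "jzs_ttest_bf",
    "jzs_bf_from_t",
    "dienes_bf",
    "power_chisq",
    "power_ttest",
    "block_trend_ols",
    "effect_summary_from_groups",
]

DEFAULT_CAUCHY_SCALE = float(np.sqrt(2.0) / 2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows are conditions (totals fixed by design), columns
    strategy classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        if (c.sum(axis=1) == 0).any():
            raise ValueError("each row must have a positive total")


@dataclass
class BFResult:
    bf10: float
    method: str
    prior: dict = field(default_factory=dict)
    error: Optional[float] = None  # numerical-error estimate, if available

    def __post_init__(self) -> None:
        if not self.bf10 > 0:
            raise ValueError("a Bayes factor must be positive")


@dataclass(frozen=True)
class EffectSummary:
    """An observed effect on its raw scale, with its standard error."""

    effect: float
    se: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("SE must be positive")
        if not (np.isfinite(self.effect) and np.isfinite(self.se)):
            raise ValueError("effect and SE must be finite")

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


def effect_summary_from_groups(a: Sequence[float], b: Sequence[float]) -> EffectSummary:
    """Difference of group means with its pooled-variance standard error."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    return EffectSummary(effect=float(a.mean() - b.mean()),
                         se=float(np.sqrt(sp2 * (1 / n1 + 1 / n2))), n1=n1, n2=n2)


def contingency_bf(table: ContingencyTable, prior_concentration: float = 1.0) -> BFResult:
    """Gunel-Dickey BF10 for association in a 2x2 table, rows fixed.

    Under the null both rows share one column-probability vector with a
    Dirichlet(a, a) prior; under the alternative each row has its own
    Dirichlet(a, a) vector.  Both marginal likelihoods are Beta functions,
    so the Bayes factor is evaluated in closed form (the multinomial
    coefficients cancel):

        BF10 = [prod_i B(y_i1 + a, y_i2 + a) / B(a, a)] / B(y_.1 + a, y_.2 + a)
               * B(a, a) ... collapsed into log space below.
    """
    a = float(prior_concentration)
    if a <= 0:
        raise ValueError("prior concentration must be positive")
    y = table.counts
    log_m1 = sum(betaln(y[i, 0] + a, y[i, 1] + a) - betaln(a, a) for i in range(2))
    log_m0 = betaln(y[:, 0].sum() + a, y[:, 1].sum() + a) - betaln(a, a)
    return BFResult(bf10=float(np.exp(log_m1 - log_m0)),
                    method="gunel_dickey",
                    prior={"concentration": a, "sampling": "independent_multinomial_rows"},
                    error=0.0)


def jzs_bf_from_t(t: float, n1: int, n2: int,
                  cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
                  directional: bool = False) -> BFResult:
    """JZS BF10 from a two-sample t statistic.

    BF10 = int f_nct(t; df, delta * sqrt(n_eff)) Cauchy(delta; 0, r) ddelta
           / f_t(t; df), with n_eff = n1 n2 / (n1 + n2).  ``directional``
    restricts (and renormalizes) the prior to delta > 0.
    """
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    prior = stats.cauchy(0.0, cauchy_scale)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * np.sqrt(neff)) * prior.pdf(delta)

    if directional:
        num, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
        num, err = 2.0 * num, 2.0 * err  # renormalized half-Cauchy
    else:
        num, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    den = stats.t.pdf(t, df)
    return BFResult(bf10=float(num / den), method="jzs",
                    prior={"cauchy_scale": cauchy_scale, "directional": directional},
                    error=float(err / den))


def jzs_ttest_bf(a: Sequence[float], b: Sequence[float],
                 cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
                 directional: bool = False) -> BFResult:
    """JZS BF10 comparing two groups of observations."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("observations must be finite")
    summ = effect_summary_from_groups(a, b)  # raises on n < 2 via df use below
    if summ.se == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = summ.effect / summ.se
    return jzs_bf_from_t(t, summ.n1, summ.n2, cauchy_scale, directional)


def dienes_bf(obs: EffectSummary, prior_mean: float,
              prior_sd: Optional[float] = None, tails: int = 2) -> BFResult:
    """Replication BF10 with a normal prior on the raw effect.

    The default prior follows the half-SD convention: centered on the
    previously observed effect with standard deviation half its size.
    Computed by numerical integration of

        BF10 = int N(obs; delta, SE) N(delta; mu, sd) ddelta / N(obs; 0, SE),

    and cross-checked against the conjugate closed form
    N(obs; mu, sqrt(SE^2 + sd^2)); the discrepancy is stored as ``error``.
    ``tails=1`` folds the prior onto the half-line sign(prior_mean).
    """
    if prior_sd is None:
        prior_sd = abs(prior_mean) / 2.0
    if not prior_sd > 0:
        raise ValueError("prior SD must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    lik = stats.norm(loc=obs.effect, scale=obs.se)
    prior = stats.norm(prior_mean, prior_sd)

    # conjugate closed form of the marginal (log space), used as cross-check
    log_marginal = stats.norm.logpdf(obs.effect, prior_mean, np.hypot(obs.se, prior_sd))
    if tails == 2:
        num, _ = integrate.quad(lambda d: lik.pdf(d) * prior.pdf(d),
                                -np.inf, np.inf, limit=200)
        log_closed = log_marginal
    else:
        sign = 1.0 if prior_mean >= 0 else -1.0
        mass = prior.sf(0.0) if sign > 0 else prior.cdf(0.0)
        lo, hi = (0.0, np.inf) if sign > 0 else (-np.inf, 0.0)
        num, _ = integrate.quad(lambda d: lik.pdf(d) * prior.pdf(d) / mass,
                                lo, hi, limit=200)
        # marginal x posterior mass on the prior's half-line, renormalized
        s_post = np.sqrt(obs.se ** 2 * prior_sd ** 2 / (obs.se ** 2 + prior_sd ** 2))
        m_post = (obs.effect * prior_sd ** 2 + prior_mean * obs.se ** 2) \
            / (obs.se ** 2 + prior_sd ** 2)
        half = stats.norm.sf(0.0, m_post, s_post) if sign > 0 \
            else stats.norm.cdf(0.0, m_post, s_post)
        log_closed = log_marginal + np.log(half) - np.log(mass)

    log_den = stats.norm.logpdf(obs.effect, 0.0, obs.se)
    log_num = np.log(num) if num > 0 else log_closed  # quad underflow: defer to closed form
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_num - log_den))
        bf_closed = float(np.exp(log_closed - log_den))
    error = abs(bf - bf_closed) if np.isfinite(bf) and np.isfinite(bf_closed) \
        else abs(float(log_num - log_closed))
    return BFResult(bf10=bf, method="dienes",
                    prior={"mean": prior_mean, "sd": prior_sd, "tails": tails},
                    error=error)


def power_chisq(w: float, n: int, df: int, alpha: float = 0.05) -> float:
    """Power of a chi-square test of effect size w at total sample size n."""
    if w < 0 or n <= 0 or df <= 0:
        raise ValueError("w must be >= 0 and n, df positive")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, n * w ** 2))


def power_ttest(d: float, n1: int, n2: Optional[int] = None, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t test for standardized effect d."""
    n2 = n1 if n2 is None else n2
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def block_trend_ols(trajectory: pd.DataFrame) -> pd.DataFrame:
    """OLS trend of per-block UD proportions on block and presentation time.

    ``trajectory`` has one row per (condition_ms, block) with a ``ud_prop``
    column (12 blocks x 2 conditions = 24 rows).  Presentation time is
    entered as an indicator for the long condition, so negative time
    coefficients mean less UD responding with more time.  Returns the
    coefficient table with t statistics on the residual degrees of freedom.
    """
    df = trajectory.copy()
    required = {"condition_ms", "block", "ud_prop"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory needs columns {sorted(required)}")
    conds = sorted(df["condition_ms"].unique())
    if len(conds) != 2:
        raise ValueError("exactly two presentation-time conditions expected")
    df["time_long"] = (df["condition_ms"] == conds[1]).astype(float)
    X = pd.DataFrame({
        "block": df["block"].astype(float),
        "time_long": df["time_long"],
        "block_x_time": df["block"].astype(float) * df["time_long"],
    })
    X = sm.add_constant(X)
    fit = sm.OLS(df["ud_prop"].astype(float), X).fit()
    out = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    })
    out.attrs["df_resid"] = int(fit.df_resid)
    return out
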