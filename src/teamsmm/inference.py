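"""Statistical machinery for the team-level pre/post design.

The primary analysis is a two-way mixed repeated-measures ANOVA on
team-level similarity scores: training group (between-teams, 2 levels) ×
time (within-teams, pre/post).  With two within levels the decomposition
reduces to two orthonormal per-team contrasts,

    b_i = (pre_i + post_i) / sqrt(2)      (between stratum)
    w_i = (post_i - pre_i) / sqrt(2)      (within stratum),

and the three 1-df effects are tested against their stratum's error mean
square on n_teams - 2 degrees of freedom.  For unequal group sizes the time
and interaction sums of squares use unweighted (Type III-style) cell means,
the convention of mainstream behavioural-statistics software; with two
groups this is the harmonic-mean-n form, and the interaction F is exactly
the pooled two-sample t² on team change scores.

Effect sizes are partial eta squared, eta_p² = SS_effect / (SS_effect +
SS_error) = F·df1 / (F·df1 + df2).  Baseline balance checks are Pearson
chi-square (no continuity correction) and summary-statistic two-sample t
tests; a priori sample size for the paired pre/post contrast comes from
noncentral-t power iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectResult",
    "MixedAnovaResult",
    "BalanceTestResult",
    "SampleSizeResult",
    "mixed_rm_anova",
    "eta_p_sq_from_f",
    "chi_square_independence",
    "t_two_sample",
    "paired_pre_post_sample_size",
    "logit_transform",
]


@dataclass(frozen=True)
class EffectResult:
    """One tested effect: sum of squares, F ratio, p value, partial eta²."""

    name: str
    ss: float
    df_effect: int
    df_error: int
    f: float
    p: float
    eta_p_sq: float


@dataclass(frozen=True)
class MixedAnovaResult:
    """Full mixed-design ANOVA table for one outcome.

    ``effects`` holds group, time and time × group (group rows absent in the
    single-group degenerate design).  ``zero_variance`` flags a degenerate
    within-stratum error (all change scores identical within groups), in
    which case nonzero effects report F = inf, p = 0.
    """

    effects: dict[str, EffectResult]
    ss_error_between: float
    ss_error_within: float
    n_teams: int
    group_sizes: dict[str, int]
    zero_variance: bool = False
    dv: str = "total"

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """ANOVA report table: effect, df pair, F, p, partial eta²."""
        rows = [
            {
                "effect": e.name,
                "df": f"{e.df_effect}, {e.df_error}",
                "F": e.f,
                "p": e.p,
                "eta_p_sq": e.eta_p_sq,
            }
            for e in self.effects.values()
        ]
        frame = pd.DataFrame(rows)
        if decimals is not None:
            for col in ("F", "p", "eta_p_sq"):
                frame[col] = frame[col].round(decimals)
        return frame


@dataclass(frozen=True)
class BalanceTestResult:
    statistic: float
    df: float
    p: float
    kind: Literal["chi_square", "t_two_sample"]
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SampleSizeResult:
    required_n: int
    achieved_power: float
    d: float
    alpha: float
    tails: int
    power_target: float


def eta_p_sq_from_f(f: float, df_effect: int, df_error: int) -> float:
    """Partial eta squared from an F ratio: F·df1 / (F·df1 + df2)."""
    if f < 0 or df_effect < 1 or df_error < 1:
        raise ValueError("need F >= 0 and both dfs >= 1")
    if math.isinf(f):
        return 1.0
    return f * df_effect / (f * df_effect + df_error)


def _f_test(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float, float]:
    """(F, p, eta_p²) for a 1-stratum effect; handles zero error variance."""
    ms_err = ss_err / df_err
    if ms_err == 0:
        if ss_eff == 0:
            return 0.0, 1.0, 0.0
        return math.inf, 0.0, 1.0
    f = (ss_eff / df_eff) / ms_err
    p = float(stats.f.sf(f, df_eff, df_err))
    return f, p, eta_p_sq_from_f(f, df_eff, df_err)


def mixed_rm_anova(
    scores: pd.DataFrame,
    dv: str = "total",
    team: str = "team_id",
    group: str = "group",
    time: str = "time",
    time_levels: tuple[str, str] = ("pre", "post"),
) -> MixedAnovaResult:
    """Two-way mixed RM-ANOVA on a long-format team-level score table.

    Parameters
    ----------
    scores :
        One row per team per time point with the outcome in column ``dv``.
    time_levels :
        The (first, second) within levels; the within contrast is
        second − first.

    Every team must have both time points (teams with incomplete data must
    be excluded by the caller, as the study design prescribes) and each
    group needs at least two teams.  With a single group the group and
    interaction effects are suppressed and F_time equals the squared paired
    t statistic on the change scores.
    """
    needed = {dv, team, group, time}
    missing = needed - set(scores.columns)
    if missing:
        raise ValueError(f"score table lacks column(s) {sorted(missing)}")
    sub = scores[[team, group, time, dv]].dropna(subset=[dv])

    wide = sub.pivot_table(index=[group, team], columns=time, values=dv, aggfunc="first")
    bad = [lv for lv in time_levels if lv not in wide.columns]
    if bad:
        raise ValueError(f"no observations at time point(s) {bad}")
    incomplete = wide.index[wide[list(time_levels)].isna().any(axis=1)]
    if len(incomplete):
        teams = [t for (_g, t) in incomplete]
        raise ValueError(
            f"team(s) {teams} lack a complete pre/post pair; exclude incomplete teams before analysis"
        )

    pre = wide[time_levels[0]].to_numpy(float)
    post = wide[time_levels[1]].to_numpy(float)
    glabels = wide.index.get_level_values(0)
    groups = list(dict.fromkeys(glabels))
    n = len(wide)
    b = (pre + post) / math.sqrt(2.0)
    w = (post - pre) / math.sqrt(2.0)

    if len(groups) == 1:
        # degenerate single-group design: paired pre/post comparison
        df_err = n - 1
        if df_err < 1:
            raise ValueError("need at least 2 teams")
        ss_time = n * float(np.mean(w)) ** 2
        ss_err_w = float(np.sum((w - np.mean(w)) ** 2))
        ss_err_b = float(np.sum((b - np.mean(b)) ** 2))
        f, p, eta = _f_test(ss_time, 1, ss_err_w, df_err)
        effects = {"time": EffectResult("time", ss_time, 1, df_err, f, p, eta)}
        return MixedAnovaResult(
            effects=effects,
            ss_error_between=ss_err_b,
            ss_error_within=ss_err_w,
            n_teams=n,
            group_sizes={groups[0]: n},
            zero_variance=(ss_err_w == 0),
            dv=dv,
        )

    if len(groups) != 2:
        raise ValueError(f"expected 1 or 2 groups, found {len(groups)}: {groups}")
    masks = [np.asarray(glabels == g) for g in groups]
    sizes = [int(m.sum()) for m in masks]
    if min(sizes) < 2:
        raise ValueError(f"each group needs >= 2 complete teams; sizes {dict(zip(groups, sizes))}")
    n1, n2 = sizes
    df_err = n - 2
    h = 1.0 / n1 + 1.0 / n2

    # between stratum: one-way ANOVA on the per-team sum contrast
    b_means = [float(b[m].mean()) for m in masks]
    grand_b = float(b.mean())
    ss_group = sum(ng * (bm - grand_b) ** 2 for ng, bm in zip(sizes, b_means))
    ss_err_b = sum(float(np.sum((b[m] - bm) ** 2)) for m, bm in zip(masks, b_means))

    # within stratum: unweighted (Type III-style) contrasts on change scores
    w_means = [float(w[m].mean()) for m in masks]
    ss_time = (w_means[0] + w_means[1]) ** 2 / h
    ss_inter = (w_means[0] - w_means[1]) ** 2 / h
    ss_err_w = sum(float(np.sum((w[m] - wm) ** 2)) for m, wm in zip(masks, w_means))

    effects: dict[str, EffectResult] = {}
    for name, ss, ss_err in (
        ("group", ss_group, ss_err_b),
        ("time", ss_time, ss_err_w),
        ("time_x_group", ss_inter, ss_err_w),
    ):
        f, p, eta = _f_test(ss, 1, ss_err, df_err)
        effects[name] = EffectResult(name, ss, 1, df_err, f, p, eta)

    return MixedAnovaResult(
        effects=effects,
        ss_error_between=ss_err_b,
        ss_error_within=ss_err_w,
        n_teams=n,
        group_sizes=dict(zip([str(g) for g in groups], sizes)),
        zero_variance=(ss_err_w == 0),
        dv=dv,
    )


def chi_square_independence(table) -> BalanceTestResult:
    """Pearson chi-square test of independence on an r×c contingency table.

    No Yates continuity correction is applied (matching standard reporting
    of baseline-balance tables).  df = (r-1)(c-1).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("need a 2-D table of nonnegative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must hold integer counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        # a zero margin is the only way a Pearson expected count can be zero
        raise ValueError("all-zero margin gives zero expected cell counts; use an exact test instead")
    res = stats.chi2_contingency(arr, correction=False)
    return BalanceTestResult(
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
        kind="chi_square",
    )


def t_two_sample(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: Literal["pooled", "welch"] = "pooled",
    tails: int = 2,
) -> BalanceTestResult:
    """Two-sample t test from summary statistics (means, SDs, group sizes).

    ``pooled`` assumes equal variances (classical Student test); ``welch``
    does not.  ``tails=1`` halves the two-sided p (direction of the observed
    difference).
    """
    if sd1 <= 0 or sd2 <= 0 or n1 < 2 or n2 < 2:
        raise ValueError("need positive SDs and group sizes >= 2")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    t = float(res.statistic)
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(res.pvalue)
    if tails == 1:
        p /= 2.0
    return BalanceTestResult(statistic=t, df=df, p=p, kind="t_two_sample", extra={"variant": variant, "tails": tails})


def _paired_power(n: int, d: float, alpha: float, tails: int) -> float:
    df = n - 1
    ncp = d * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / tails, df)
    power = float(stats.nct.sf(tcrit, df, ncp))
    if tails == 2:
        power += float(stats.nct.cdf(-tcrit, df, ncp))
    return power


def paired_pre_post_sample_size(
    d: float,
    alpha: float = 0.05,
    power_target: float = 0.80,
    tails: int = 2,
    n_max: int = 100_000,
) -> SampleSizeResult:
    """Smallest paired-design n whose noncentral-t power reaches the target.

    Power of the one-sample t test on pre/post differences with effect size
    d (ncp = d·sqrt(n), df = n − 1), iterated upward from n = 2.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < power_target < 1):
        raise ValueError("need 0 < alpha < power_target < 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        power = _paired_power(n, d, alpha, tails)
        if power >= power_target:
            return SampleSizeResult(
                required_n=n,
                achieved_power=power,
                d=d,
                alpha=alpha,
                tails=tails,
                power_target=power_target,
            )
    raise RuntimeError(f"no n <= {n_max} reaches power {power_target}")


def logit_transform(p, eps: float = 1e-6):
    """Optional logit transform for bounded-proportion outcomes (off by
    default in the pipeline; scores are analysed untransformed)."""
    arr = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    return np.log(arr / (1 - arr))
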