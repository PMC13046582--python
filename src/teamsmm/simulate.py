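"""Synthetic team-response generator and Monte-Carlo experiment harness.

The generative model is a *modal-response* ("team canon") model: each team
holds one canonical answer per item, fixed across time points, and members
respond independently given that canon.

* Single-choice items: a member picks the canonical option with adherence
  probability ``c`` and otherwise uniformly among the remaining m − 1
  options.  Two members then agree with probability

      E[agreement] = c² + (1 − c)² / (m − 1),

  which is invertible on c ∈ [1/m, 1], so convergence levels can be set by
  targeting an expected agreement directly.

* Multiple-choice items: the canon is an s-option subset; a member includes
  each canonical option with probability ``p_in`` and each non-canonical
  option with probability ``p_out``, independently.  The expected pairwise
  overlap (Jaccard/Dice/overlap coefficient, conditional on both selections
  being non-empty) has no simple closed form but is computed exactly by
  multinomial enumeration for instruments of ordinary size.

Training is emulated as a pre→post increase of the convergence parameters,
group-specific so interaction effects (or their absence, for type-I
studies) can be dialled in.  Default parameters are calibrated so that
team-level scores land near the levels observed in 29-team trauma-team
studies (task responsibility ≈ 0.61 pre, communication ≈ 0.81 pre).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .inference import mixed_rm_anova
from .questionnaire import (
    Domain,
    QuestionnaireSpec,
    ResponseMode,
    StudyDataset,
    TimePoint,
    default_questionnaire,
)
from .similarity import SCORE_COLUMNS, multi_item_scores, single_item_scores

__all__ = [
    "GroupParams",
    "SimulationConfig",
    "expected_agreement_single",
    "invert_agreement",
    "expected_overlap_multi",
    "calibrate_p_in",
    "default_config",
    "null_config",
    "simulate_study",
    "simulate_scores",
    "run_experiment",
]


def expected_agreement_single(c: float, m: int) -> float:
    """Expected pair agreement on a single-choice item under the canon model.

    Both members pick the canonical option (probability c each) or both
    miss it and coincide uniformly among the other m − 1 options.
    """
    if m < 2:
        raise ValueError("need m >= 2 options")
    if not 0.0 <= c <= 1.0:
        raise ValueError("adherence c must lie in [0, 1]")
    return c * c + (1.0 - c) ** 2 / (m - 1)


def invert_agreement(a: float, m: int) -> float:
    """Adherence c ∈ [1/m, 1] producing expected agreement ``a``.

    Root of the quadratic ``expected_agreement_single(c, m) = a`` on the
    monotone branch; closed form c = (1 + sqrt(m(m−1)a − (m−1))) / m.
    """
    if m < 2:
        raise ValueError("need m >= 2 options")
    lo = 1.0 / m
    if not (lo - 1e-12 <= a <= 1.0 + 1e-12):
        raise ValueError(f"target agreement {a} outside attainable range [{lo}, 1]")
    a = min(max(a, lo), 1.0)
    disc = m * (m - 1) * a - (m - 1)
    return (1.0 + math.sqrt(max(disc, 0.0))) / m


def _region_states(n: int, p1: float, p2: float):
    """Joint counts of per-option pair states (11, 10, 01, 00) over n
    options where member 1 includes each with prob p1 and member 2 with p2.
    Yields (prob, n11, n10, n01)."""
    q11, q10, q01, q00 = p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)
    for n11 in range(n + 1):
        for n10 in range(n - n11 + 1):
            for n01 in range(n - n11 - n10 + 1):
                n00 = n - n11 - n10 - n01
                coef = math.comb(n, n11) * math.comb(n - n11, n10) * math.comb(n - n11 - n10, n01)
                prob = coef * q11**n11 * q10**n10 * q01**n01 * q00**n00
                yield prob, n11, n10, n01


def expected_overlap_multi(
    p_in: float,
    p_out: float,
    s: int,
    m: int,
    metric: str = "jaccard",
) -> float:
    """Exact expected pairwise overlap on a multiple-choice item.

    Enumerates the multinomial distribution of joint per-option inclusion
    states inside and outside the canonical s-subset and averages the
    chosen overlap coefficient, conditional on both selections being
    non-empty (empty selections are missing data and score no pairs).
    """
    if not (0 <= s <= m) or m < 2:
        raise ValueError("need 0 <= s <= m and m >= 2")
    for p in (p_in, p_out):
        if not 0.0 <= p <= 1.0:
            raise ValueError("inclusion probabilities must lie in [0, 1]")
    num = 0.0
    p_both_nonempty = 0.0
    for prob_in, i11, i10, i01 in _region_states(s, p_in, p_in):
        if prob_in == 0.0:
            continue
        for prob_out, o11, o10, o01 in _region_states(m - s, p_out, p_out):
            prob = prob_in * prob_out
            if prob == 0.0:
                continue
            size_a = i11 + i10 + o11 + o10
            size_b = i11 + i01 + o11 + o01
            if size_a == 0 or size_b == 0:
                continue
            inter = i11 + o11
            if metric == "jaccard":
                val = inter / (size_a + size_b - inter)
            elif metric == "dice":
                val = 2 * inter / (size_a + size_b)
            elif metric in ("overlap", "overlap_coefficient"):
                val = inter / min(size_a, size_b)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            num += prob * val
            p_both_nonempty += prob
    if p_both_nonempty == 0.0:
        raise ValueError("both selections are empty almost surely; raise p_in/p_out")
    return num / p_both_nonempty


def calibrate_p_in(
    target: float,
    p_out: float,
    s: int,
    m: int,
    metric: str = "jaccard",
) -> float:
    """p_in whose exact expected overlap equals ``target`` (given p_out)."""

    def f(p):
        return expected_overlap_multi(p, p_out, s, m, metric) - target

    lo, hi = 1e-6, 1.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"target overlap {target} not attainable with p_out={p_out}, s={s}, m={m} "
            f"(range [{flo + target:.3f}, {fhi + target:.3f}])"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class GroupParams:
    """Convergence parameters of one training group.

    ``c_pre``/``c_post`` are single-choice adherence probabilities;
    ``p_in_*``/``p_out_*`` the multiple-choice inclusion probabilities for
    canonical and non-canonical options at each time point.
    """

    c_pre: float
    c_post: float
    p_in_pre: float
    p_out_pre: float
    p_in_post: float
    p_out_post: float

    def __post_init__(self):
        for name in ("c_pre", "c_post", "p_in_pre", "p_out_pre", "p_in_post", "p_out_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cluster-randomized study.

    Defaults reproduce the emulated design: two training arms of 15 and 14
    teams, team sizes uniform on 5-9, and the 54-item instrument.  ``seed``
    fully determines the generated dataset.
    """

    questionnaire: QuestionnaireSpec = field(default_factory=default_questionnaire)
    n_teams: Mapping[str, int] = field(default_factory=lambda: {"checklist": 15, "algorithm": 14})
    team_size_range: tuple[int, int] = (5, 9)
    params: Mapping[str, GroupParams] = None  # type: ignore[assignment]
    canon_size: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.params is None:
            object.__setattr__(self, "params", _default_group_params())
        if set(self.params) != set(self.n_teams):
            raise ValueError("params and n_teams must cover the same groups")
        lo, hi = self.team_size_range
        if not (2 <= lo <= hi):
            raise ValueError("team sizes must be >= 2 and ordered")
        if any(n < 1 for n in self.n_teams.values()):
            raise ValueError("each group needs >= 1 team")
        single_ms = [it.n_options for it in self.questionnaire if it.response_mode is ResponseMode.SINGLE]
        if single_ms:
            m_min = min(single_ms)
            for g, gp in self.params.items():
                for nm in ("c_pre", "c_post"):
                    if getattr(gp, nm) < 1.0 / m_min - 1e-12:
                        raise ValueError(
                            f"group {g!r}: {nm}={getattr(gp, nm)} below chance level 1/{m_min}"
                        )
        multi_ms = [it.n_options for it in self.questionnaire if it.response_mode is ResponseMode.MULTI]
        if multi_ms and not (0 < self.canon_size <= min(multi_ms)):
            raise ValueError("canon_size must be in [1, min option count of multi items]")


# Table-2-like calibration anchors for the default generator (team-level
# mean similarities, proportions): task responsibility ~0.61 pre rising to
# ~0.74/0.71, communication ~0.81 pre rising to ~0.83/0.82.
_DEFAULT_ANCHORS = {
    "checklist": {"task_pre": 0.6127, "task_post": 0.7371, "comm_pre": 0.8078, "comm_post": 0.8258},
    "algorithm": {"task_pre": 0.6226, "task_post": 0.7144, "comm_pre": 0.8042, "comm_post": 0.8238},
}
_DEFAULT_P_OUT = 0.03
_params_cache: dict = {}


def _default_group_params(
    m: int = 7,
    s: int = 3,
    n_task_single: int = 21,
    n_task_multi: int = 5,
) -> dict[str, GroupParams]:
    """Calibrate default per-group parameters against the anchor levels.

    The task-responsibility domain mixes 21 single- and 5 multiple-choice
    items, so the single-choice agreement target is backed out of the domain
    anchor after accounting for the multi items (which share the
    communication-level overlap parameters).
    """
    key = (m, s, n_task_single, n_task_multi)
    if key in _params_cache:
        return _params_cache[key]
    out = {}
    n_task = n_task_single + n_task_multi
    for grp, a in _DEFAULT_ANCHORS.items():
        kw = {}
        for when in ("pre", "post"):
            comm = a[f"comm_{when}"]
            p_in = calibrate_p_in(comm, _DEFAULT_P_OUT, s, m)
            a_single = (n_task * a[f"task_{when}"] - n_task_multi * comm) / n_task_single
            c = invert_agreement(a_single, m)
            kw[f"c_{when}"] = c
            kw[f"p_in_{when}"] = p_in
            kw[f"p_out_{when}"] = _DEFAULT_P_OUT
        out[grp] = GroupParams(**kw)
    _params_cache[key] = out
    return out


def default_config(seed: int | None = None) -> SimulationConfig:
    """The emulated-study configuration (15/14 teams, calibrated defaults)."""
    return SimulationConfig(seed=seed)


def null_config(seed: int | None = None) -> SimulationConfig:
    """Null-interaction variant: both groups share one parameter set, so any
    pre→post shift is identical across arms (time effect present,
    time × group effect exactly null)."""
    base = _default_group_params()
    shared = base["checklist"]
    return SimulationConfig(params={"checklist": shared, "algorithm": shared}, seed=seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


class _Structure:
    """Cached array-level layout of an instrument (single/multi blocks)."""

    def __init__(self, spec: QuestionnaireSpec):
        self.spec = spec
        self.single = [it for it in spec if it.response_mode is ResponseMode.SINGLE]
        self.multi = [it for it in spec if it.response_mode is ResponseMode.MULTI]
        self.m_single = np.array([it.n_options for it in self.single], dtype=np.int64)
        self.m_multi = np.array([it.n_options for it in self.multi], dtype=np.int64)
        self.max_m = int(self.m_multi.max()) if self.multi else 0
        self.single_task = np.array([it.domain is Domain.TASK for it in self.single], dtype=bool)
        self.multi_task = np.array([it.domain is Domain.TASK for it in self.multi], dtype=bool)


def _draw_team(rng: np.random.Generator, k: int, struct: _Structure, gp: GroupParams, s: int):
    """Draw one team's responses at both time points.

    Returns (codes_pre, codes_post) as (k, n_single) option-code arrays and
    (sel_pre, sel_post) as (k, n_multi, max_m) boolean selection arrays.
    The team canon is drawn once and shared by both time points.
    """
    ns, nm = len(struct.single), len(struct.multi)
    canon = (rng.random(ns) * struct.m_single).astype(np.int64) if ns else np.empty(0, np.int64)
    if nm:
        # canonical s-subset per multi item, uniform among that item's options
        r = rng.random((nm, struct.max_m))
        r[np.arange(struct.max_m)[None, :] >= struct.m_multi[:, None]] = np.inf
        canon_sets = np.argsort(r, axis=1, kind="stable") < s
    codes_out, sel_out = [], []
    for c, p_in, p_out in ((gp.c_pre, gp.p_in_pre, gp.p_out_pre), (gp.c_post, gp.p_in_post, gp.p_out_post)):
        if ns:
            adhere = rng.random((k, ns)) < c
            offset = 1 + (rng.random((k, ns)) * (struct.m_single - 1)).astype(np.int64)
            codes = np.where(adhere, canon[None, :], (canon[None, :] + offset) % struct.m_single)
        else:
            codes = np.empty((k, 0), np.int64)
        if nm:
            p = np.where(canon_sets, p_in, p_out)[None, :, :]
            sel = rng.random((k, nm, struct.max_m)) < p
            sel &= np.arange(struct.max_m)[None, None, :] < struct.m_multi[None, :, None]
        else:
            sel = np.zeros((k, 0, 0), bool)
        codes_out.append(codes)
        sel_out.append(sel)
    return codes_out[0], codes_out[1], sel_out[0], sel_out[1]


def _iter_teams(config: SimulationConfig, rng: np.random.Generator):
    """Yield (group, team_id, k, codes_pre, codes_post, sel_pre, sel_post)
    in a fixed deterministic order."""
    struct = _Structure(config.questionnaire)
    lo, hi = config.team_size_range
    for group in config.n_teams:
        gp = config.params[group]
        for t in range(config.n_teams[group]):
            team_id = f"{group}_t{t + 1:02d}"
            k = int(rng.integers(lo, hi + 1))
            yield (group, team_id, k, struct, *_draw_team(rng, k, struct, gp, config.canon_size))


def simulate_study(config: SimulationConfig) -> StudyDataset:
    """Generate a full synthetic :class:`StudyDataset` (seeded, reproducible)."""
    rng = np.random.default_rng(config.seed)
    responses = {}
    groups = {}
    for group, team_id, k, struct, c_pre, c_post, s_pre, s_post in _iter_teams(config, rng):
        groups[team_id] = group
        for time, codes, sel in ((TimePoint.PRE, c_pre, s_pre), (TimePoint.POST, c_post, s_post)):
            for i in range(k):
                member = f"m{i + 1}"
                for a, it in enumerate(struct.single):
                    responses[(team_id, member, time, it.item_id)] = frozenset(
                        [it.options[codes[i, a]]]
                    )
                for a, it in enumerate(struct.multi):
                    chosen = np.nonzero(sel[i, a])[0]
                    if chosen.size:  # empty selection = missing response
                        responses[(team_id, member, time, it.item_id)] = frozenset(
                            it.options[j] for j in chosen
                        )
    return StudyDataset(
        questionnaire=config.questionnaire, group_assignment=groups, responses=responses
    )


def simulate_scores(
    config: SimulationConfig,
    metric: str = "jaccard",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate and score a study without materializing the dataset object.

    Consumes exactly the same random draws as :func:`simulate_study`, so for
    a given seed this equals ``score_study(simulate_study(config))`` row for
    row.  Used by the Monte-Carlo experiment harness.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = {c: [] for c in SCORE_COLUMNS}
    recs = []
    for group, team_id, k, struct, c_pre, c_post, s_pre, s_post in _iter_teams(config, rng):
        for time, codes, sel in (("pre", c_pre, s_pre), ("post", c_post, s_post)):
            s_scores = single_item_scores(codes) if struct.single else np.empty(0)
            m_scores = multi_item_scores(sel, metric) if struct.multi else np.empty(0)
            task = np.concatenate([s_scores[struct.single_task], m_scores[struct.multi_task]])
            comm = np.concatenate([s_scores[~struct.single_task], m_scores[~struct.multi_task]])
            n_task = int(np.sum(~np.isnan(task)))
            n_comm = int(np.sum(~np.isnan(comm)))
            task_mean = float(np.nanmean(task)) if n_task else np.nan
            comm_mean = float(np.nanmean(comm)) if n_comm else np.nan
            if n_task and n_comm:
                total = (n_task * task_mean + n_comm * comm_mean) / (n_task + n_comm)
            else:
                total = np.nan
            recs.append((group, team_id, time, task_mean, comm_mean, total, k, n_task + n_comm))
    for rec in recs:
        for c, v in zip(SCORE_COLUMNS, rec):
            rows[c].append(v)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo experiments
# ---------------------------------------------------------------------------


def _binom_ci(k: int, n: int, level: float) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


def run_experiment(
    grid: Mapping[str, SimulationConfig] | Sequence[SimulationConfig],
    n_reps: int,
    analysis: Literal["type1", "power", "recovery"] = "power",
    dv: str = "total",
    alpha: float = 0.05,
    metric: str = "jaccard",
    seed: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Replicated simulation experiment over a grid of configurations.

    For ``type1``/``power`` each replicate simulates a study, scores it,
    runs the mixed RM-ANOVA on ``dv`` and records whether the time × group
    interaction (and the time main effect) rejects at ``alpha``; the output
    holds rejection rates with exact binomial confidence intervals.  The two
    modes run the same machinery — the label documents whether the grid cell
    is a null (equal shifts) or an alternative.

    For ``recovery`` each replicate inverts the mean pre-training
    single-choice item similarity back to an adherence estimate ĉ_pre and
    the output reports its mean, bias and RMSE against the generating value
    (groups pooled; meaningful when the grid cell gives both groups the same
    ``c_pre``, as the null/recovery designs do).

    One master seed drives the whole experiment; every (cell, replicate)
    stream is derived from it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(grid, Mapping):
        cells = list(grid.items())
    else:
        cells = [(f"cell{i}", cfg) for i, cfg in enumerate(grid)]
    master = np.random.SeedSequence(seed)
    cell_seeds = master.spawn(len(cells))
    out_rows = []
    for (label, cfg), cell_ss in zip(cells, cell_seeds):
        rng = np.random.default_rng(cell_ss)
        if analysis in ("type1", "power"):
            rej_int = rej_time = 0
            for _ in range(n_reps):
                scores = simulate_scores(cfg, metric=metric, rng=rng)
                res = mixed_rm_anova(scores, dv=dv)
                rej_int += res["time_x_group"].p < alpha
                rej_time += res["time"].p < alpha
            lo, hi = _binom_ci(rej_int, n_reps, ci_level)
            lo_t, hi_t = _binom_ci(rej_time, n_reps, ci_level)
            out_rows.append(
                {
                    "cell": label,
                    "analysis": analysis,
                    "dv": dv,
                    "n_reps": n_reps,
                    "alpha": alpha,
                    "reject_rate_interaction": rej_int / n_reps,
                    "ci_low_interaction": lo,
                    "ci_high_interaction": hi,
                    "reject_rate_time": rej_time / n_reps,
                    "ci_low_time": lo_t,
                    "ci_high_time": hi_t,
                }
            )
        elif analysis == "recovery":
            struct = _Structure(cfg.questionnaire)
            if not struct.single:
                raise ValueError("recovery analysis needs single-choice items")
            m_vals = set(struct.m_single.tolist())
            if len(m_vals) != 1:
                raise ValueError("recovery inversion assumes a common option count m")
            m = m_vals.pop()
            true_c = float(np.mean([gp.c_pre for gp in cfg.params.values()]))
            estimates = [_recover_c_pre(cfg, rng, m) for _ in range(n_reps)]
            est_arr = np.array(estimates)
            se = est_arr.std(ddof=1) / math.sqrt(n_reps) if n_reps > 1 else np.nan
            out_rows.append(
                {
                    "cell": label,
                    "analysis": "recovery",
                    "n_reps": n_reps,
                    "true_c_pre": true_c,
                    "mean_c_pre_hat": float(est_arr.mean()),
                    "bias": float(est_arr.mean() - true_c),
                    "rmse": float(np.sqrt(np.mean((est_arr - true_c) ** 2))),
                    "se_mean": float(se),
                }
            )
        else:
            raise ValueError(f"unknown analysis {analysis!r}")
    return pd.DataFrame(out_rows)


def _recover_c_pre(cfg: SimulationConfig, rng: np.random.Generator, m: int) -> float:
    """Moment estimator: mean pre single-choice item similarity, inverted."""
    vals = []
    for _group, _tid, _k, struct, c_pre, _c_post, _s_pre, _s_post in _iter_teams(cfg, rng):
        sc = single_item_scores(c_pre)
        vals.append(np.nanmean(sc))
    a_hat = float(np.mean(vals))
    a_hat = min(max(a_hat, 1.0 / m), 1.0)
    return invert_agreement(a_hat, m)


def shifted_config(base: SimulationConfig, extra_shift: float, group: str = "checklist") -> SimulationConfig:
    """Copy of ``base`` with one group's post-training single-choice
    adherence raised by ``extra_shift`` (clipped to 1): a simple dial for
    power curves over interaction effect sizes."""
    params = dict(base.params)
    gp = params[group]
    params[group] = replace(gp, c_post=min(gp.c_post + extra_shift, 1.0))
    return replace(base, params=params)
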