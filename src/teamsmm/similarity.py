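"""Within-team similarity scoring of questionnaire responses.

The team shared-mental-model score is a proportion-of-agreement statistic:
for every item, every unordered pair of team members is compared, the pair
scores are averaged over all C(k, 2) pairs, item scores are averaged to the
two domain scores, and the total is the item-count-weighted mean of the
domain scores (equivalently the plain mean over all scored items).

Single-choice items use exact agreement (1 if the two members picked the
same option, else 0), so the item score is the fraction of agreeing pairs.
Multiple-choice items use a set-overlap coefficient per pair — Jaccard
|a∩b|/|a∪b| by default, with Dice and the overlap coefficient selectable.
All scores live in [0, 1]; the reporting layer rescales to percentages.

Members missing an item are dropped from that item's pair set only; an item
with fewer than two responders in a team is unscorable and is skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .questionnaire import (
    Domain,
    ResponseMode,
    StudyDataset,
    TimePoint,
)

__all__ = [
    "METRICS",
    "TeamSimilarity",
    "pair_agreement_single",
    "pair_overlap_multi",
    "item_similarity",
    "score_team",
    "score_study",
    "score_table_percent",
    "weighted_total",
]

#: Supported multiple-choice overlap metrics (aliases map to canonical names).
METRICS = ("jaccard", "dice", "overlap")
_METRIC_ALIASES = {
    "jaccard": "jaccard",
    "dice": "dice",
    "overlap": "overlap",
    "overlap_coefficient": "overlap",
}

SCORE_COLUMNS = [
    "group",
    "team_id",
    "time",
    "task_responsibility",
    "communication",
    "total",
    "n_members",
    "n_items_scored",
]


def _canon_metric(metric: str) -> str:
    try:
        return _METRIC_ALIASES[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}") from None


def pair_agreement_single(a: Iterable[str] | str, b: Iterable[str] | str) -> int:
    """Exact-agreement pair score for a single-choice item: 1 iff identical.

    Accepts bare option labels or singleton selections.  Symmetric.
    """
    sa = frozenset([a]) if isinstance(a, str) else frozenset(a)
    sb = frozenset([b]) if isinstance(b, str) else frozenset(b)
    if len(sa) != 1 or len(sb) != 1:
        raise ValueError("single-choice pair agreement needs two singleton selections")
    return int(sa == sb)


def pair_overlap_multi(a: Iterable[str], b: Iterable[str], metric: str = "jaccard") -> float:
    """Set-overlap pair score for a multiple-choice item, in [0, 1].

    jaccard = |a∩b|/|a∪b|; dice = 2|a∩b|/(|a|+|b|); overlap = |a∩b|/min(|a|,|b|).
    Both selections must be non-empty (an empty selection is a missing
    response and its pairs are excluded upstream, not scored 0).
    """
    metric = _canon_metric(metric)
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValueError("pair overlap is undefined for empty selections; exclude the member first")
    inter = len(sa & sb)
    if metric == "jaccard":
        return inter / len(sa | sb)
    if metric == "dice":
        return 2 * inter / (len(sa) + len(sb))
    return inter / min(len(sa), len(sb))


def item_similarity(
    selections: Sequence[Iterable[str]],
    mode: ResponseMode | str = ResponseMode.SINGLE,
    metric: str = "jaccard",
) -> float | None:
    """Mean pair score over all C(k, 2) unordered pairs of k responses.

    ``selections`` holds only non-missing responses.  Returns None when
    k < 2 (score undefined).  For single-choice items this equals
    (# agreeing pairs) / C(k, 2).
    """
    mode = ResponseMode(mode)
    sels = [frozenset([s]) if isinstance(s, str) else frozenset(s) for s in selections]
    sels = [s for s in sels if s]
    if len(sels) < 2:
        return None
    if mode is ResponseMode.SINGLE:
        scores = [pair_agreement_single(a, b) for a, b in combinations(sels, 2)]
    else:
        scores = [pair_overlap_multi(a, b, metric) for a, b in combinations(sels, 2)]
    return float(sum(scores) / len(scores))


# ---------------------------------------------------------------------------
# Vectorized per-item kernels (shared with the simulator's fast path)
# ---------------------------------------------------------------------------


def single_item_scores(codes: np.ndarray) -> np.ndarray:
    """Agreement scores for a block of single-choice items.

    ``codes`` is (k members, n items) of integer option codes, -1 = missing.
    Returns (n,) scores with NaN where fewer than 2 members responded.
    """
    codes = np.asarray(codes)
    valid = codes >= 0
    both = valid[:, None, :] & valid[None, :, :]
    eq = (codes[:, None, :] == codes[None, :, :]) & both
    iu, ju = np.triu_indices(codes.shape[0], k=1)
    agree = eq[iu, ju].sum(axis=0).astype(float)
    k = valid.sum(axis=0)
    pairs = k * (k - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(pairs > 0, agree / np.where(pairs > 0, pairs, 1.0), np.nan)
    return out


def multi_item_scores(sel: np.ndarray, metric: str = "jaccard") -> np.ndarray:
    """Mean pairwise overlap for a block of multiple-choice items.

    ``sel`` is (k members, n items, m options) boolean; an all-False row for
    a member/item is a missing response.  Returns (n,) scores with NaN where
    fewer than 2 members responded.
    """
    metric = _canon_metric(metric)
    sel = np.asarray(sel, dtype=bool)
    k = sel.shape[0]
    sizes = sel.sum(axis=2)  # (k, n)
    nonempty = sizes > 0
    seli = sel.astype(np.int64)
    inter = np.einsum("iam,jam->ija", seli, seli)  # (k, k, n)
    iu, ju = np.triu_indices(k, k=1)
    inter_p = inter[iu, ju].astype(float)  # (pairs, n)
    si, sj = sizes[iu].astype(float), sizes[ju].astype(float)
    if metric == "jaccard":
        denom = si + sj - inter_p
    elif metric == "dice":
        denom = (si + sj) / 2.0
    else:
        denom = np.minimum(si, sj)
    pair_ok = nonempty[iu] & nonempty[ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_scores = np.where(pair_ok, inter_p / np.where(denom > 0, denom, 1.0), np.nan)
    n_ok = pair_ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(n_ok > 0, np.nansum(pair_scores, axis=0) / np.where(n_ok > 0, n_ok, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# Team- and study-level aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TeamSimilarity:
    """Similarity profile of one team at one time point.

    ``item_scores`` maps item_id to a score in [0, 1], or None when the item
    had fewer than two responders.  Domain scores are unweighted means of the
    defined item scores in each domain; ``total_score`` is the item-count-
    weighted mean of the domain scores (identically the mean over all defined
    item scores), or None if either domain had no scorable item.
    """

    team_id: str
    time_point: TimePoint
    item_scores: dict[str, float | None]
    domain_scores: dict[Domain, float | None]
    total_score: float | None
    n_members: int

    @property
    def n_items_scored(self) -> int:
        return sum(1 for v in self.item_scores.values() if v is not None)


def weighted_total(domain_means: dict[Domain | str, float], weights: dict[Domain | str, int]) -> float:
    """Item-count-weighted mean of domain-level scores.

    With the 54-item study instrument the weights are 26 (task
    responsibility) and 28 (communication); applied to domain means this
    reproduces the total-score column of a descriptives table.
    """
    keys = list(domain_means)
    w = np.array([weights[k] for k in keys], dtype=float)
    v = np.array([domain_means[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive count")
    return float((w * v).sum() / w.sum())


def _team_arrays(dataset: StudyDataset, team_id: str, time_point: TimePoint):
    """Materialize one team/time as (codes, multi_sel, item orderings)."""
    spec = dataset.questionnaire
    members = dataset.members(team_id)
    single_items = [it for it in spec if it.response_mode is ResponseMode.SINGLE]
    multi_items = [it for it in spec if it.response_mode is ResponseMode.MULTI]
    k = len(members)
    codes = np.full((k, len(single_items)), -1, dtype=np.int64)
    opt_index = {it.item_id: {o: j for j, o in enumerate(it.options)} for it in spec}
    for a, it in enumerate(single_items):
        idx = opt_index[it.item_id]
        for i, member in enumerate(members):
            sel = dataset.selection(team_id, member, time_point, it.item_id)
            if sel:
                codes[i, a] = idx[next(iter(sel))]
    max_m = max((it.n_options for it in multi_items), default=0)
    sel_arr = np.zeros((k, len(multi_items), max_m), dtype=bool)
    for a, it in enumerate(multi_items):
        idx = opt_index[it.item_id]
        for i, member in enumerate(members):
            sel = dataset.selection(team_id, member, time_point, it.item_id)
            if sel:
                for o in sel:
                    sel_arr[i, a, idx[o]] = True
    return members, single_items, multi_items, codes, sel_arr


def score_team(
    dataset: StudyDataset,
    team_id: str,
    time_point: TimePoint | str,
    metric: str = "jaccard",
) -> TeamSimilarity:
    """Score one team at one time point.

    Invariant to member ordering; members missing an item drop out of that
    item's pair set only.
    """
    time_point = TimePoint(time_point)
    members, single_items, multi_items, codes, sel_arr = _team_arrays(dataset, team_id, time_point)
    s_scores = single_item_scores(codes) if single_items else np.empty(0)
    m_scores = multi_item_scores(sel_arr, metric) if multi_items else np.empty(0)

    item_scores: dict[str, float | None] = {}
    for it, sc in zip(single_items, s_scores):
        item_scores[it.item_id] = None if math.isnan(sc) else float(sc)
    for it, sc in zip(multi_items, m_scores):
        item_scores[it.item_id] = None if math.isnan(sc) else float(sc)

    domain_scores: dict[Domain, float | None] = {}
    counts: dict[Domain, int] = {}
    for dom in (Domain.TASK, Domain.COMMUNICATION):
        vals = [
            item_scores[it.item_id]
            for it in dataset.questionnaire.items_in(dom)
            if item_scores.get(it.item_id) is not None
        ]
        counts[dom] = len(vals)
        domain_scores[dom] = float(np.mean(vals)) if vals else None

    if any(v is None for v in domain_scores.values()):
        total = None
    else:
        total = weighted_total(
            {d: s for d, s in domain_scores.items()},  # type: ignore[misc]
            {d: counts[d] for d in domain_scores},
        )
    return TeamSimilarity(
        team_id=team_id,
        time_point=time_point,
        item_scores=item_scores,
        domain_scores=domain_scores,
        total_score=total,
        n_members=len(members),
    )


def score_study(dataset: StudyDataset, metric: str = "jaccard") -> pd.DataFrame:
    """Score every (team, time point) in a study.

    Returns one row per team per time point with columns ``group, team_id,
    time, task_responsibility, communication, total, n_members,
    n_items_scored``; scores are proportions in [0, 1], NaN where undefined.
    Deterministic and invariant to member/row ordering.
    """
    rows = []
    for team in dataset.teams():
        for time in (TimePoint.PRE, TimePoint.POST):
            ts = score_team(dataset, team, time, metric)
            rows.append(
                {
                    "group": dataset.group_assignment[team],
                    "team_id": team,
                    "time": time.value,
                    "task_responsibility": np.nan
                    if ts.domain_scores[Domain.TASK] is None
                    else ts.domain_scores[Domain.TASK],
                    "communication": np.nan
                    if ts.domain_scores[Domain.COMMUNICATION] is None
                    else ts.domain_scores[Domain.COMMUNICATION],
                    "total": np.nan if ts.total_score is None else ts.total_score,
                    "n_members": ts.n_members,
                    "n_items_scored": ts.n_items_scored,
                }
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def score_table_percent(scores: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Report variant of a score table: proportions rescaled to percentages."""
    out = scores.copy()
    for col in ("task_responsibility", "communication", "total"):
        out[col] = (out[col] * 100).round(decimals)
    return out
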