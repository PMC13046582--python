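"""Similarity engine vs an independent brute-force pair-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest

from teamsmm.questionnaire import Domain, QuestionnaireSpec, ResponseMode, TimePoint
from teamsmm.similarity import (
    item_similarity,
    multi_item_scores,
    pair_agreement_single,
    pair_overlap_multi,
    score_study,
    score_team,
    single_item_scores,
    weighted_total,
)

from .conftest import build_dataset, make_item, random_dataset


# --- oracle: direct pair enumeration, written from the definitions --------


def oracle_pair(a, b, mode, metric):
    a, b = set(a), set(b)
    if mode == "single":
        return 1.0 if a == b else 0.0
    inter = len(a & b)
    if metric == "jaccard":
        return inter / len(a | b)
    if metric == "dice":
        return 2 * inter / (len(a) + len(b))
    return inter / min(len(a), len(b))


def oracle_item(selections, mode, metric):
    sels = [set(s) for s in selections if s]
    if len(sels) < 2:
        return None
    vals = [oracle_pair(a, b, mode, metric) for a, b in itertools.combinations(sels, 2)]
    return sum(vals) / len(vals)


class TestPairScores:
    def test_single_identity_and_mismatch(self):
        assert pair_agreement_single("teamleader", "teamleader") == 1
        assert pair_agreement_single("teamleader", "anesthetist") == 0

    def test_single_symmetric_over_all_option_pairs(self):
        opts = [f"o{i}" for i in range(5)]
        for a, b in itertools.product(opts, repeat=2):
            assert pair_agreement_single(a, b) == pair_agreement_single(b, a)
            assert pair_agreement_single(a, b) == (1 if a == b else 0)

    def test_single_rejects_non_singletons(self):
        with pytest.raises(ValueError):
            pair_agreement_single({"a", "b"}, {"a"})

    def test_jaccard_partial_overlap(self):
        assert pair_overlap_multi({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("metric", ["jaccard", "dice", "overlap"])
    def test_identical_and_disjoint_sets(self, metric):
        assert pair_overlap_multi({"A", "B"}, {"A", "B"}, metric) == 1.0
        assert pair_overlap_multi({"A"}, {"B"}, metric) == 0.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pair_overlap_multi(set(), {"A"})

    def test_overlap_alias_accepted(self):
        assert pair_overlap_multi({"A"}, {"A", "B"}, "overlap_coefficient") == 1.0


class TestItemSimilarity:
    def test_two_of_three_agree(self):
        assert item_similarity(["X", "X", "Y"]) == pytest.approx(1 / 3)

    def test_all_identical_is_one(self):
        assert item_similarity(["X"] * 6) == 1.0
        assert item_similarity([{"A", "B"}] * 4, mode="multi") == 1.0

    def test_all_distinct_is_zero(self):
        assert item_similarity(["W", "X", "Y", "Z"]) == 0.0

    def test_fewer_than_two_responses_undefined(self):
        assert item_similarity(["X"]) is None
        assert item_similarity([]) is None

    def test_modal_duplicate_never_decreases_score(self):
        # enumerate small response vectors; duplicating a modal responder
        # cannot lower the agreement proportion
        opts = ["a", "b", "c"]
        for k in (2, 3, 4):
            for combo in itertools.product(opts, repeat=k):
                modal = max(set(combo), key=combo.count)
                base = item_similarity(list(combo))
                more = item_similarity(list(combo) + [modal])
                assert more >= base - 1e-12


@pytest.mark.parametrize("metric", ["jaccard", "dice", "overlap"])
def test_engine_matches_oracle_random_instances(rng, metric):
    """Scalar and vectorized paths agree exactly with pair enumeration."""
    for _ in range(120):
        k = int(rng.integers(2, 10))
        m = int(rng.integers(2, 9))
        opts = [f"o{i}" for i in range(m)]
        if rng.random() < 0.5:
            sels = [{opts[rng.integers(m)]} for _ in range(k)]
            mode = "single"
            codes = np.array([[opts.index(next(iter(s))) for s in sels]]).T.reshape(k, 1)
            vec = single_item_scores(codes)[0]
        else:
            mode = "multi"
            sels = []
            arr = np.zeros((k, 1, m), dtype=bool)
            for i in range(k):
                mask = rng.random(m) < 0.5
                if not mask.any():
                    mask[rng.integers(m)] = True
                sels.append({o for o, keep in zip(opts, mask) if keep})
                arr[i, 0, :] = mask
            vec = multi_item_scores(arr, metric)[0]
        expected = oracle_item(sels, mode, metric)
        got = item_similarity(sels, mode, metric)
        assert got == pytest.approx(expected, abs=1e-12)
        assert vec == pytest.approx(expected, abs=1e-12)


class TestTeamAggregation:
    def test_weighted_total_matches_reported_cells(self):
        # 26/28-weighted domain means reproduce the total column of the
        # study's descriptives (percent scale)
        assert weighted_total(
            {"task": 61.27, "comm": 80.78}, {"task": 26, "comm": 28}
        ) == pytest.approx(71.38, abs=0.01)
        assert weighted_total(
            {"task": 73.71, "comm": 82.58}, {"task": 26, "comm": 28}
        ) == pytest.approx(78.31, abs=0.01)

    def test_all_identical_team_scores_one(self, tiny_spec):
        answers = {
            "t1": {
                m: {"pre": {"t_s": "o0", "t_m": {"o1", "o2"}, "c_m": {"o0"}}}
                for m in "ABCD"
            }
        }
        ds = build_dataset(tiny_spec, {"t1": "g1"}, answers)
        ts = score_team(ds, "t1", "pre")
        assert ts.domain_scores[Domain.TASK] == 1.0
        assert ts.domain_scores[Domain.COMMUNICATION] == 1.0
        assert ts.total_score == 1.0

    def test_domain_mean_is_unweighted_item_mean(self):
        spec = QuestionnaireSpec(
            items=(
                make_item("q1", Domain.TASK, ResponseMode.SINGLE, 4),
                make_item("q2", Domain.TASK, ResponseMode.SINGLE, 4),
            )
        )
        answers = {
            "t1": {
                "A": {"pre": {"q1": "o0", "q2": "o0"}},
                "B": {"pre": {"q1": "o0", "q2": "o1"}},
                "C": {"pre": {"q1": "o1", "q2": "o2"}},
            }
        }
        ds = build_dataset(spec, {"t1": "g1"}, answers)
        ts = score_team(ds, "t1", "pre")
        # q1: pair scores 1,0,0 -> 1/3; q2: all three distinct -> 0
        assert ts.item_scores["q1"] == pytest.approx(1 / 3)
        assert ts.item_scores["q2"] == pytest.approx(0.0)
        assert ts.domain_scores[Domain.TASK] == pytest.approx(1 / 6)

    def test_missing_domain_makes_total_undefined(self, tiny_spec):
        answers = {
            "t1": {m: {"pre": {"t_s": "o0"}} for m in "AB"}  # no communication item answered
        }
        ds = build_dataset(tiny_spec, {"t1": "g1"}, answers)
        ts = score_team(ds, "t1", "pre")
        assert ts.domain_scores[Domain.COMMUNICATION] is None
        assert ts.total_score is None

    def test_total_equals_mean_over_all_item_scores(self, rng, tiny_spec):
        for _ in range(10):
            ds = random_dataset(rng, tiny_spec, n_teams=2, missing_rate=0.2)
            for team in ds.teams():
                ts = score_team(ds, team, TimePoint.PRE)
                defined = [v for v in ts.item_scores.values() if v is not None]
                task_defined = any(
                    ts.item_scores.get(it.item_id) is not None
                    for it in tiny_spec.items_in(Domain.TASK)
                )
                comm_defined = any(
                    ts.item_scores.get(it.item_id) is not None
                    for it in tiny_spec.items_in(Domain.COMMUNICATION)
                )
                if ts.total_score is not None:
                    assert ts.total_score == pytest.approx(np.mean(defined), abs=1e-12)
                else:
                    assert not (task_defined and comm_defined)

    def test_scores_in_unit_interval(self, rng, tiny_spec):
        ds = random_dataset(rng, tiny_spec, n_teams=4, missing_rate=0.3)
        table = score_study(ds)
        for col in ("task_responsibility", "communication", "total"):
            vals = table[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()


class TestScoreStudy:
    def test_29_teams_give_58_rows(self, rng):
        from teamsmm.simulate import default_config, simulate_study

        ds = simulate_study(default_config(seed=3))
        table = score_study(ds)
        assert len(table) == 58
        assert table["time"].value_counts().to_dict() == {"pre": 29, "post": 29}

    def test_member_permutation_invariance(self, rng, tiny_spec):
        ds = random_dataset(rng, tiny_spec, n_teams=3, missing_rate=0.1)
        renamed = {
            (t, "member_" + m[::-1], tp, i): sel for (t, m, tp, i), sel in ds.responses.items()
        }
        ds2 = type(ds)(
            questionnaire=ds.questionnaire,
            group_assignment=dict(ds.group_assignment),
            responses=renamed,
        )
        a = score_study(ds).drop(columns="team_id")
        b = score_study(ds2).drop(columns="team_id")
        assert np.allclose(
            a[["task_responsibility", "communication", "total"]],
            b[["task_responsibility", "communication", "total"]],
            equal_nan=True,
        )

    def test_duplicated_team_scores_identically(self, rng, tiny_spec):
        ds = random_dataset(rng, tiny_spec, n_teams=1, groups=("g1",), missing_rate=0.0)
        team = ds.teams()[0]
        dup = {(f"{team}_copy", m, tp, i): sel for (t, m, tp, i), sel in ds.responses.items()}
        ds2 = type(ds)(
            questionnaire=ds.questionnaire,
            group_assignment={team: "g1", f"{team}_copy": "g1"},
            responses={**ds.responses, **dup},
        )
        table = score_study(ds2).set_index("team_id")
        cols = ["task_responsibility", "communication", "total"]
        for time in ("pre", "post"):
            sub = table[table["time"] == time]
            assert np.allclose(
                sub.loc[team, cols].astype(float),
                sub.loc[f"{team}_copy", cols].astype(float),
                equal_nan=True,
            )
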