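import numpy as np
import pytest

from teamsmm.questionnaire import (
    Domain,
    ItemSpec,
    QuestionnaireSpec,
    ResponseMode,
    StudyDataset,
    TimePoint,
)


def make_item(item_id="q1", domain=Domain.TASK, mode=ResponseMode.SINGLE, m=5):
    return ItemSpec(item_id, domain, mode, tuple(f"o{i}" for i in range(m)))


@pytest.fixture
def tiny_spec():
    """Two task items (one single, one multi) and one communication item."""
    return QuestionnaireSpec(
        items=(
            make_item("t_s", Domain.TASK, ResponseMode.SINGLE, 5),
            make_item("t_m", Domain.TASK, ResponseMode.MULTI, 4),
            make_item("c_m", Domain.COMMUNICATION, ResponseMode.MULTI, 4),
        )
    )


def build_dataset(spec, groups, answers):
    """Construct a StudyDataset from a nested dict.

    ``answers``: {team: {member: {time: {item: selection}}}} where selection
    is a string (single) or iterable of strings.
    """
    responses = {}
    for team, members in answers.items():
        for member, times in members.items():
            for time, items in times.items():
                for item, sel in items.items():
                    sel = frozenset([sel]) if isinstance(sel, str) else frozenset(sel)
                    if sel:
                        responses[(team, member, TimePoint(time), item)] = sel
    return StudyDataset(questionnaire=spec, group_assignment=dict(groups), responses=responses)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, spec, n_teams=3, k_range=(2, 5), groups=("g1", "g2"), missing_rate=0.1):
    """A random valid dataset over ``spec`` for property tests."""
    responses = {}
    assignment = {}
    for t in range(n_teams):
        team = f"team{t}"
        assignment[team] = groups[t % len(groups)]
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        for i in range(k):
            member = f"m{i}"
            for time in (TimePoint.PRE, TimePoint.POST):
                for j, item in enumerate(spec):
                    # first pre item always answered so every member counts
                    forced = j == 0 and time is TimePoint.PRE
                    if not forced and rng.random() < missing_rate:
                        continue
                    if item.response_mode is ResponseMode.SINGLE:
                        sel = frozenset([item.options[rng.integers(item.n_options)]])
                    else:
                        mask = rng.random(item.n_options) < 0.5
                        if not mask.any():
                            if forced:
                                mask[0] = True
                            else:
                                continue
                        sel = frozenset(o for o, keep in zip(item.options, mask) if keep)
                    responses[(team, member, time, item.item_id)] = sel
    return StudyDataset(questionnaire=spec, group_assignment=assignment, responses=responses)
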