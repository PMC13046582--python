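"""Score a small hand-built questionnaire study.

Three nurses/physicians in one trauma team answer one single-choice
task-responsibility item ("who leads the primary survey?") and one
multiple-choice communication item ("who do you report a completed task
to?").  The team similarity score per item is the mean pairwise agreement
over all member pairs.
"""

from teamsmm import (
    Domain,
    ItemSpec,
    QuestionnaireSpec,
    ResponseMode,
    StudyDataset,
    TimePoint,
    score_team,
)

spec = QuestionnaireSpec(
    items=(
        ItemSpec("lead_primary", Domain.TASK, ResponseMode.SINGLE,
                 ("teamleader", "anesthetist", "surgeon")),
        ItemSpec("report_to", Domain.COMMUNICATION, ResponseMode.MULTI,
                 ("teamleader", "anesthetist", "scribe", "nurse")),
    )
)

answers = {
    ("team1", "nurse_a"): {"lead_primary": {"teamleader"}, "report_to": {"teamleader", "scribe"}},
    ("team1", "nurse_b"): {"lead_primary": {"teamleader"}, "report_to": {"teamleader"}},
    ("team1", "doc_c"): {"lead_primary": {"anesthetist"}, "report_to": {"teamleader", "nurse"}},
}
responses = {
    (team, member, TimePoint.PRE, item): frozenset(sel)
    for (team, member), items in answers.items()
    for item, sel in items.items()
}
dataset = StudyDataset(
    questionnaire=spec, group_assignment={"team1": "checklist"}, responses=responses
)

result = score_team(dataset, "team1", "pre")
print("item scores:", {k: round(v, 3) for k, v in result.item_scores.items()})
print("domain scores:", {d.value: round(v, 3) for d, v in result.domain_scores.items()})
print(f"total: {result.total_score:.3f}")

# lead_primary: 1 agreeing pair of 3 -> 0.333.  report_to: Jaccard of the
# three pairs (1/2, 1/3, 1/2) -> 0.444.  The total averages the two items.
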