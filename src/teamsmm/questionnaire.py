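"""Questionnaire instrument and response-data model.

A shared-mental-model (SMM) instrument is a list of items, each belonging to
one of two content domains — who is responsible for which trauma-room task
(``task_responsibility``) and who reports what to whom (``communication``) —
and answered either single-choice (exactly one option) or multiple-choice
(any non-empty subset of options).  Responses live in long format: one row
per selected option, keyed by group, team, member, time point and item.

The default instrument mirrors the study design this package emulates:
26 task-responsibility items (21 single-choice, 5 multiple-choice) plus
28 multiple-choice communication items, 54 items in total, administered to
interprofessional teams of 5-9 members before and after a training day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Domain",
    "ResponseMode",
    "TimePoint",
    "ItemSpec",
    "QuestionnaireSpec",
    "MemberResponse",
    "StudyDataset",
    "ValidationReport",
    "ResponseValidationError",
    "default_questionnaire",
    "read_questionnaire",
    "write_questionnaire",
    "read_responses",
    "write_responses",
    "responses_from_frame",
    "wide_to_long",
    "validate_study",
]

RESPONSE_COLUMNS = ["group", "team_id", "member_id", "time", "item_id", "option"]

#: Minimum number of responders needed before an item can be scored for a team.
MIN_RESPONDERS = 2


class Domain(str, Enum):
    TASK = "task_responsibility"
    COMMUNICATION = "communication"


class ResponseMode(str, Enum):
    SINGLE = "single"
    MULTI = "multi"


class TimePoint(str, Enum):
    PRE = "pre"
    POST = "post"


class ResponseValidationError(ValueError):
    """Raised when a response file or dataset violates the instrument spec.

    Carries row-level diagnostics in :attr:`problems` (list of strings, each
    naming the offending row or key).
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        preview = "\n".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n... and {len(self.problems) - 20} more"
        super().__init__(f"{len(self.problems)} validation problem(s):\n{preview}{more}")


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item.

    Parameters
    ----------
    item_id :
        Unique identifier within the instrument.
    domain :
        Content domain the item belongs to.
    response_mode :
        ``single`` (exactly one option selectable) or ``multi`` (any
        non-empty subset).
    options :
        Ordered tuple of at least two opaque option identifiers.  Options are
        nominal labels; agreement scoring attaches no ordering semantics.
    """

    item_id: str
    domain: Domain
    response_mode: ResponseMode
    options: tuple[str, ...]

    def __post_init__(self):
        if len(self.options) < 2:
            raise ValueError(f"item {self.item_id!r}: needs >= 2 options, got {len(self.options)}")
        if len(set(self.options)) != len(self.options):
            raise ValueError(f"item {self.item_id!r}: duplicate options")
        object.__setattr__(self, "domain", Domain(self.domain))
        object.__setattr__(self, "response_mode", ResponseMode(self.response_mode))
        object.__setattr__(self, "options", tuple(self.options))

    @property
    def n_options(self) -> int:
        return len(self.options)


@dataclass(frozen=True)
class QuestionnaireSpec:
    """An instrument: an ordered collection of :class:`ItemSpec`."""

    items: tuple[ItemSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemSpec:
        try:
            return self._by_id[item_id]
        except AttributeError:
            object.__setattr__(self, "_by_id", {it.item_id: it for it in self.items})
            return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    def items_in(self, domain: Domain) -> tuple[ItemSpec, ...]:
        domain = Domain(domain)
        return tuple(it for it in self.items if it.domain == domain)

    @property
    def n_task(self) -> int:
        return len(self.items_in(Domain.TASK))

    @property
    def n_comm(self) -> int:
        return len(self.items_in(Domain.COMMUNICATION))

    @property
    def n_total(self) -> int:
        return len(self.items)

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": it.item_id,
                    "domain": it.domain.value,
                    "response_mode": it.response_mode.value,
                    "options": list(it.options),
                }
                for it in self.items
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuestionnaireSpec":
        return cls(
            items=tuple(
                ItemSpec(
                    item_id=str(rec["item_id"]),
                    domain=Domain(rec["domain"]),
                    response_mode=ResponseMode(rec["response_mode"]),
                    options=tuple(str(o) for o in rec["options"]),
                )
                for rec in d["items"]
            )
        )


def default_questionnaire(
    n_task_single: int = 21,
    n_task_multi: int = 5,
    n_comm: int = 28,
    n_options: int = 7,
) -> QuestionnaireSpec:
    """Build the default 54-item study instrument with placeholder options.

    The study instrument's item wording and per-item option counts are not
    published, so options are opaque placeholder labels ``opt1..optM`` and a
    single ``n_options`` applies to every item (default 7, about the number
    of distinct professional roles present in a 5-9 person trauma team).
    """
    opts = tuple(f"opt{i + 1}" for i in range(n_options))
    items: list[ItemSpec] = []
    for i in range(n_task_single):
        items.append(ItemSpec(f"task_s{i + 1:02d}", Domain.TASK, ResponseMode.SINGLE, opts))
    for i in range(n_task_multi):
        items.append(ItemSpec(f"task_m{i + 1:02d}", Domain.TASK, ResponseMode.MULTI, opts))
    for i in range(n_comm):
        items.append(ItemSpec(f"comm_m{i + 1:02d}", Domain.COMMUNICATION, ResponseMode.MULTI, opts))
    return QuestionnaireSpec(items=tuple(items))


def write_questionnaire(spec: QuestionnaireSpec, path: str | Path) -> None:
    """Serialize an instrument to JSON (``.json``) or YAML (anything else)."""
    path = Path(path)
    d = spec.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_questionnaire(path: str | Path) -> QuestionnaireSpec:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return QuestionnaireSpec.from_dict(d)


@dataclass(frozen=True)
class MemberResponse:
    """One member's answer to one item at one time point.

    ``selection`` is a frozenset of option identifiers — a singleton for
    single-choice items, possibly larger for multiple-choice.  An empty
    selection is treated as a missing response and is never stored in a
    :class:`StudyDataset` (absence of the key means the same thing).
    """

    team_id: str
    member_id: str
    time_point: TimePoint
    item_id: str
    selection: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "time_point", TimePoint(self.time_point))
        object.__setattr__(self, "selection", frozenset(self.selection))


ResponseKey = tuple[str, str, TimePoint, str]  # (team, member, time, item)


@dataclass
class StudyDataset:
    """Validated study data: instrument + group allocation + responses.

    ``responses`` maps ``(team_id, member_id, time_point, item_id)`` to the
    selected option set; missing responses are simply absent keys.
    """

    questionnaire: QuestionnaireSpec
    group_assignment: dict[str, str]
    responses: dict[ResponseKey, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        problems = self._check()
        if problems:
            raise ResponseValidationError(problems)

    def _check(self) -> list[str]:
        problems: list[str] = []
        for (team, member, time, item_id), sel in self.responses.items():
            if team not in self.group_assignment:
                problems.append(f"team {team!r}: not in group assignment")
                continue
            if item_id not in self.questionnaire:
                problems.append(f"({team},{member},{time},{item_id}): unknown item")
                continue
            spec = self.questionnaire[item_id]
            bad = sel - set(spec.options)
            if bad:
                problems.append(
                    f"({team},{member},{time.value},{item_id}): options {sorted(bad)} not in item spec"
                )
            if spec.response_mode is ResponseMode.SINGLE and len(sel) > 1:
                problems.append(
                    f"({team},{member},{time.value},{item_id}): {len(sel)} options selected on a single-choice item"
                )
            if not sel:
                problems.append(f"({team},{member},{time.value},{item_id}): empty selection stored; drop the key instead")
        for team in self.teams():
            if len(self.members(team)) < 2:
                problems.append(f"team {team!r}: fewer than 2 members with responses")
        return problems

    # -- views ---------------------------------------------------------------

    def teams(self) -> list[str]:
        return sorted({k[0] for k in self.responses})

    def members(self, team_id: str) -> list[str]:
        return sorted({k[1] for k in self.responses if k[0] == team_id})

    @property
    def team_sizes(self) -> dict[str, int]:
        return {t: len(self.members(t)) for t in self.teams()}

    def selection(self, team: str, member: str, time: TimePoint | str, item: str) -> frozenset[str] | None:
        """The stored option set, or None if the response is missing."""
        return self.responses.get((team, member, TimePoint(time), item))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per selected option, deterministic order."""
        rows = []
        for (team, member, time, item_id), sel in self.responses.items():
            for opt in sorted(sel):
                rows.append((self.group_assignment[team], team, member, time.value, item_id, opt))
        frame = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
        return frame.sort_values(RESPONSE_COLUMNS, kind="mergesort").reset_index(drop=True)


def responses_from_frame(frame: pd.DataFrame, spec: QuestionnaireSpec) -> StudyDataset:
    """Build a validated :class:`StudyDataset` from a long-format frame.

    Raises :class:`ResponseValidationError` with row-level diagnostics (row
    numbers refer to the frame's positional index, header excluded).
    """
    missing_cols = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ResponseValidationError([f"missing required column(s): {missing_cols}"])

    problems: list[str] = []
    groups: dict[str, str] = {}
    selections: dict[ResponseKey, set[str]] = {}
    for pos, row in enumerate(frame.itertuples(index=False)):
        team, member, item_id, opt = str(row.team_id), str(row.member_id), str(row.item_id), str(row.option)
        try:
            time = TimePoint(str(row.time))
        except ValueError:
            problems.append(f"row {pos}: unknown time point {row.time!r}")
            continue
        group = str(row.group)
        if groups.setdefault(team, group) != group:
            problems.append(f"row {pos}: team {team!r} assigned to both {groups[team]!r} and {group!r}")
            continue
        if item_id not in spec:
            problems.append(f"row {pos}: unknown item_id {item_id!r}")
            continue
        item = spec[item_id]
        if opt not in item.options:
            problems.append(f"row {pos}: option {opt!r} not among item {item_id!r} options")
            continue
        key = (team, member, time, item_id)
        sel = selections.setdefault(key, set())
        if item.response_mode is ResponseMode.SINGLE and sel and opt not in sel:
            problems.append(
                f"row {pos}: second option {opt!r} for single-choice item {item_id!r} "
                f"(member {member!r}, {time.value})"
            )
            continue
        sel.add(opt)
    if problems:
        raise ResponseValidationError(problems)
    responses = {k: frozenset(v) for k, v in selections.items() if v}
    return StudyDataset(questionnaire=spec, group_assignment=groups, responses=responses)


def read_responses(path: str | Path, spec: QuestionnaireSpec) -> StudyDataset:
    """Read a long-format CSV/TSV response file against an instrument spec.

    The file needs a header with columns ``group,team_id,member_id,time,
    item_id,option`` and one row per selected option.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    return responses_from_frame(frame, spec)


def write_responses(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset to long-format CSV/TSV; round-trips losslessly."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def wide_to_long(
    frame: pd.DataFrame,
    spec: QuestionnaireSpec,
    id_cols: Iterable[str] = ("group", "team_id", "member_id", "time"),
    sep: str = ";",
) -> pd.DataFrame:
    """Convenience converter: wide (one column per item) to long format.

    Multi-choice cells hold ``sep``-joined option labels; empty/NaN cells are
    missing responses.
    """
    id_cols = list(id_cols)
    item_cols = [c for c in frame.columns if c in spec]
    records = []
    for _, row in frame.iterrows():
        for item_id in item_cols:
            cell = row[item_id]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            for opt in str(cell).split(sep):
                opt = opt.strip()
                if opt:
                    records.append([*(row[c] for c in id_cols), item_id, opt])
    return pd.DataFrame(records, columns=[*id_cols, "item_id", "option"])


@dataclass(frozen=True)
class ValidationReport:
    """Scorability report: which (team, time, item) cells cannot be scored.

    ``unscorable`` maps ``(team_id, time_point, item_id)`` to the number of
    responders observed (< MIN_RESPONDERS).  Reporting only — nothing is
    mutated or excluded here; the scoring engine skips these cells itself.
    """

    unscorable: dict[tuple[str, TimePoint, str], int]
    responder_counts: dict[tuple[str, TimePoint, str], int]

    @property
    def ok(self) -> bool:
        return not self.unscorable

    def flagged_for(self, team_id: str) -> dict[tuple[TimePoint, str], int]:
        return {(t, i): k for (tm, t, i), k in self.unscorable.items() if tm == team_id}


def validate_study(dataset: StudyDataset) -> ValidationReport:
    """Flag (team, time, item) cells with fewer than two responders.

    Pairwise similarity needs at least two non-missing responses; cells below
    that minimum are flagged (with the observed responder count) but the
    dataset is left untouched.  Idempotent and side-effect free.
    """
    counts: dict[tuple[str, TimePoint, str], int] = {}
    for (team, _member, time, item_id) in dataset.responses:
        counts[(team, time, item_id)] = counts.get((team, time, item_id), 0) + 1
    unscorable: dict[tuple[str, TimePoint, str], int] = {}
    all_items = [it.item_id for it in dataset.questionnaire]
    for team in dataset.teams():
        for time in (TimePoint.PRE, TimePoint.POST):
            for item_id in all_items:
                k = counts.get((team, time, item_id), 0)
                if k < MIN_RESPONDERS:
                    unscorable[(team, time, item_id)] = k
    return ValidationReport(unscorable=unscorable, responder_counts=counts)
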