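"""Validation-unit machinery: independent events and modeled low-risk cases.

The unit of the validation analysis is the *independent event*, not the
pedigree.  A high-risk pedigree contributes one event per fulfilled criterion
(one pedigree can fulfill several).  A low-risk pedigree contributes one event
per recorded cancer history (type, age, degree of relation, side), one
*combination* event per family line carrying two or more histories, and a
single *no family history* event when nothing remains to record.

``model_low_risk`` reproduces the construction of modeled low-risk cases:
qualifying history that would fulfill a criterion is removed from a high-risk
pedigree (greedily, fewest removals first) until nothing fires, and all
remaining history is preserved verbatim.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from . import normalize as nz
from .criteria import DEFAULT_CONFIG, CriterionEvent, EngineConfig, evaluate
from .pedigree import (
    FamilyMember,
    Lineage,
    Pedigree,
    Relationship,
)

__all__ = [
    "EventKind",
    "SingleHistory",
    "IndependentEvent",
    "extract_high_risk_events",
    "extract_low_risk_events",
    "model_low_risk",
    "event_pedigree",
    "predict_event",
    "GroupingMode",
]

POLYP_HISTORY_TYPE = "colon_polyps"


class EventKind(str, enum.Enum):
    CRITERION = "criterion"
    SINGLE_HISTORY = "single_history"
    COMBINATION = "combination"
    NO_FAMILY_HISTORY = "no_family_history"


class GroupingMode(str, enum.Enum):
    """How same-side histories combine: one event per side (default), or one
    per pair."""

    PER_SIDE = "per_side"
    PER_PAIR = "per_pair"


@dataclass(frozen=True)
class SingleHistory:
    """One recorded cancer history: type, imputed age, degree, side."""

    cancer_type: str
    age: Optional[int]
    degree: int
    side: str  # maternal | paternal | both | self
    relationship: Relationship
    polyp_count: Optional[int] = None  # set for polyp histories only

    def to_dict(self) -> dict:
        return {
            "cancer_type": self.cancer_type,
            "age": self.age,
            "degree": self.degree,
            "side": self.side,
            "relationship": self.relationship.value,
        }


@dataclass(frozen=True)
class IndependentEvent:
    kind: EventKind
    criterion: Optional[CriterionEvent] = None
    histories: tuple[SingleHistory, ...] = ()
    side: Optional[str] = None
    source_pedigree_id: Optional[str] = None


def extract_high_risk_events(
    p: Pedigree, config: EngineConfig = DEFAULT_CONFIG
) -> list[IndependentEvent]:
    """One CRITERION event per fulfilled criterion; rejects low-risk input."""
    report = evaluate(p, config)
    if not report.meets_any:
        raise ValueError(
            "pedigree does not meet any criterion; use extract_low_risk_events"
        )
    return [
        IndependentEvent(
            kind=EventKind.CRITERION,
            criterion=ev,
            side=ev.side,
            source_pedigree_id=p.pedigree_id,
        )
        for ev in report.events
    ]


def _singles(p: Pedigree) -> list[SingleHistory]:
    out: list[SingleHistory] = []
    for person in p.everyone():
        for dx in person.diagnoses:
            try:
                age = nz.impute_age(dx.age)
            except nz.UnknownAgeError:
                age = None
            out.append(
                SingleHistory(
                    cancer_type=dx.cancer_type,
                    age=age,
                    degree=person.degree,
                    side=person.lineage.value,
                    relationship=person.relationship,
                )
            )
        if person.polyp_count:
            out.append(
                SingleHistory(
                    cancer_type=POLYP_HISTORY_TYPE,
                    age=None,
                    degree=person.degree,
                    side=person.lineage.value,
                    relationship=person.relationship,
                    polyp_count=person.polyp_count,
                )
            )
    return out


def extract_low_risk_events(
    p: Pedigree,
    config: EngineConfig = DEFAULT_CONFIG,
    grouping: GroupingMode = GroupingMode.PER_SIDE,
) -> list[IndependentEvent]:
    """Single histories, same-lineage combinations, or one no-family-history
    event; rejects high-risk input.

    Combinations group family-side histories (members of ``both`` lineage join
    either side); the proband's own history never joins a combination.  With
    ``grouping=PER_PAIR`` every same-side pair is its own event instead.
    """
    report = evaluate(p, config)
    if report.meets_any:
        raise ValueError(
            "pedigree meets criteria; use extract_high_risk_events"
        )
    pid = p.pedigree_id
    singles = _singles(p)
    events = [
        IndependentEvent(
            kind=EventKind.SINGLE_HISTORY,
            histories=(s,),
            side=s.side,
            source_pedigree_id=pid,
        )
        for s in singles
    ]
    if not singles:
        return [IndependentEvent(kind=EventKind.NO_FAMILY_HISTORY, source_pedigree_id=pid)]

    family = [s for s in singles if s.side != Lineage.SELF.value]
    seen: set[tuple] = set()
    for side in (Lineage.MATERNAL, Lineage.PATERNAL):
        group = [s for s in family if s.side in (side.value, Lineage.BOTH.value)]
        if len(group) < 2:
            continue
        key = tuple(sorted((s.relationship.value, s.cancer_type, s.age or -1) for s in group))
        if key in seen:
            continue  # an all-shared-lineage group is one combination, not two
        seen.add(key)
        if grouping is GroupingMode.PER_SIDE:
            events.append(
                IndependentEvent(
                    kind=EventKind.COMBINATION,
                    histories=tuple(group),
                    side=side.value,
                    source_pedigree_id=pid,
                )
            )
        else:
            from itertools import combinations

            for a, b in combinations(group, 2):
                events.append(
                    IndependentEvent(
                        kind=EventKind.COMBINATION,
                        histories=(a, b),
                        side=side.value,
                        source_pedigree_id=pid,
                    )
                )
    return events


# --------------------------------------------------------------------------
# per-event tool entry
# --------------------------------------------------------------------------


def event_pedigree(
    event: IndependentEvent, source: Optional[Pedigree] = None
) -> Pedigree:
    """Reconstruct the history that gets entered into the tool for one event.

    Low-risk events carry their histories verbatim.  A criterion event is
    restricted to its index person and contributing relatives from the source
    pedigree (which must be supplied), exercising the self-certifying
    property of criterion events.
    """
    from .pedigree import AgeRecord, CancerDiagnosis, Sex

    if event.kind is EventKind.NO_FAMILY_HISTORY:
        return Pedigree(proband=FamilyMember(relationship=Relationship.SELF, sex=Sex.FEMALE))
    if event.kind in (EventKind.SINGLE_HISTORY, EventKind.COMBINATION):
        # the intake always records family size (question six); per-event
        # entry keeps the source family's declared structure so the
        # limited-family clause reflects the real pedigree
        family_sizes = None
        if source is not None:
            family_sizes = source.family_sizes or {
                side: sum(
                    1
                    for m in source.members
                    if m.lineage.value in (side, Lineage.BOTH.value)
                    and m.relationship not in (Relationship.MOTHER, Relationship.FATHER)
                )
                for side in ("maternal", "paternal")
            }
        proband = FamilyMember(relationship=Relationship.SELF, sex=Sex.FEMALE)
        members: dict[Relationship, FamilyMember] = {}
        for h in event.histories:
            if h.relationship is Relationship.SELF:
                person = proband
            else:
                person = members.setdefault(
                    h.relationship, FamilyMember(relationship=h.relationship)
                )
            if h.cancer_type == POLYP_HISTORY_TYPE:
                person.polyp_count = h.polyp_count or 1
            else:
                age = AgeRecord.exact(h.age) if h.age is not None else AgeRecord.unknown()
                person.diagnoses.append(CancerDiagnosis(cancer_type=h.cancer_type, age=age))
        return Pedigree(
            proband=proband, members=list(members.values()), family_sizes=family_sizes
        )
    # criterion event: restrict the source pedigree to the contributing people
    if source is None:
        raise ValueError("criterion events need their source pedigree")
    crit = event.criterion
    assert crit is not None
    keep = set(crit.contributing) | {crit.index_person}
    proband = source.proband.model_copy(deep=True)
    if Relationship.SELF not in keep:
        proband.diagnoses = []
        proband.polyp_count = None
    members = [m.model_copy(deep=True) for m in source.members if m.relationship in keep]
    mutations = [
        mut for mut in source.mutations if mut.carrier in keep or mut.carrier is Relationship.SELF
    ]
    return Pedigree(proband=proband, members=members, mutations=list(mutations))


def predict_event(
    event: IndependentEvent,
    source: Optional[Pedigree] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> bool:
    """The tool's verdict when this event is entered on its own."""
    return evaluate(event_pedigree(event, source), config).meets_any


# --------------------------------------------------------------------------
# modeled low-risk construction
# --------------------------------------------------------------------------


def _candidate_removals(p: Pedigree):
    """Removable history items: (kind, person index, payload index, sort age).

    Person index -1 is the proband.  Mutations and polyp counts sort after
    diagnoses of equal criterion yield (no age to break ties by youth).
    """
    items = []
    people = [(-1, p.proband)] + list(enumerate(p.members))
    for pi, person in people:
        for di, dx in enumerate(person.diagnoses):
            try:
                age = nz.impute_age(dx.age)
            except nz.UnknownAgeError:
                age = 999
            items.append(("diagnosis", pi, di, age))
        if person.polyp_count:
            items.append(("polyps", pi, 0, 1000))
    for mi, _ in enumerate(p.mutations):
        items.append(("mutation", mi, 0, 1000))
    return items


def _without(p: Pedigree, item) -> Pedigree:
    kind, pi, di, _ = item
    data = p.model_copy(deep=True)
    if kind == "mutation":
        data.mutations.pop(pi)
        return data
    person = data.proband if pi == -1 else data.members[pi]
    if kind == "diagnosis":
        person.diagnoses.pop(di)
    else:
        person.polyp_count = None
    return data


def model_low_risk(p: Pedigree, config: EngineConfig = DEFAULT_CONFIG) -> Pedigree:
    """Remove a minimal set of qualifying history so no criterion fires.

    Greedy: at each step delete the item whose removal extinguishes the most
    fulfilled criterion events, breaking ties by youngest age at diagnosis and
    then by deterministic member order.  All remaining history is preserved
    verbatim.  Idempotent; a pedigree whose every item must go returns with an
    empty history (a valid no-family-history case).
    """
    current = p.model_copy(deep=True)
    while True:
        n_events = len(evaluate(current, config).events)
        if n_events == 0:
            return current
        best = None
        for item in _candidate_removals(current):
            remaining = len(evaluate(_without(current, item), config).events)
            drop = n_events - remaining
            key = (-drop, item[3], item[1], item[2], item[0])
            if best is None or key < best[0]:
                best = (key, item)
        assert best is not None
        if best[0][0] == 0:  # no single removal helps; clear everything left
            stripped = current.model_copy(deep=True)
            stripped.mutations = []
            for person in stripped.everyone():
                person.diagnoses = []
                person.polyp_count = None
            return stripped
        current = _without(current, best[1])
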