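"""Stepwise intake questionnaire.

Six primary prompts, asked in a fixed order, with follow-ups inserted only
after an affirmative answer:

1. ethnic background
2. personal cancer history (-> type and age per diagnosis)
3. family cancer history (-> who, type, age per relative)
4. colon polyps (-> who, how many)
5. known cancer-gene mutation in the family (-> which gene group)
6. family size per generation/side

The state machine is deliberately dumb: callers push answers, ``next_prompt``
says what to ask, and ``build_pedigree`` assembles the validated record once
everything is resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .normalize import normalize_cancer
from .pedigree import (
    AgeRecord,
    Ethnicity,
    FamilyMember,
    GeneGroup,
    MutationFinding,
    Pedigree,
    Relationship,
    Sex,
)

__all__ = ["Prompt", "IntakeState", "PROMPTS"]

DONE = "done"


@dataclass(frozen=True)
class Prompt:
    key: str
    text: str
    follow_up: Optional[str] = None
    #: conditional follow-ups appear only after an affirmative answer;
    #: the family-size detail is part of the primary answer itself
    conditional: bool = True


PROMPTS: list[Prompt] = [
    Prompt("ethnicity", "How would you describe your ethnic background?"),
    Prompt(
        "personal_cancer",
        "Have you ever been diagnosed with cancer?",
        "If so, what type and at what age?",
    ),
    Prompt(
        "family_cancer",
        "Is there a family history of cancer?",
        "If so, who, what type and at what age?",
    ),
    Prompt(
        "polyps",
        "Have you/family member had any colon polyps?",
        "If so, who/how many?",
    ),
    Prompt(
        "mutation",
        "Has anyone in your family tested positive for a cancer-related gene mutation?",
        "If so, from BRCA1/BRCA2, Lynch syndrome, APC/MUTYH?",
    ),
    Prompt(
        "family_size",
        "Help us understand the size of your family.",
        "Enter number of family members in each generation.",
        conditional=False,
    ),
]

_BY_KEY = {p.key: p for p in PROMPTS}


@dataclass
class IntakeState:
    """Ordered answers plus the queue of pending follow-ups."""

    answers: dict[str, object] = field(default_factory=dict)
    follow_ups: dict[str, object] = field(default_factory=dict)
    pending_follow_up: Optional[str] = None

    def next_prompt(self) -> tuple[str, str]:
        """(key, question text) of the next prompt, or ("done", "")."""
        if self.pending_follow_up is not None:
            prompt = _BY_KEY[self.pending_follow_up]
            assert prompt.follow_up is not None
            return f"{prompt.key}.follow_up", prompt.follow_up
        for prompt in PROMPTS:
            if prompt.key not in self.answers:
                return prompt.key, prompt.text
        return DONE, ""

    def answer(self, key: str, value) -> None:
        if key.endswith(".follow_up"):
            base = key[: -len(".follow_up")]
            if self.pending_follow_up != base:
                raise ValueError(f"no follow-up pending for {base!r}")
            self.follow_ups[base] = value
            self.pending_follow_up = None
            return
        prompt = _BY_KEY.get(key)
        if prompt is None:
            raise ValueError(f"unknown prompt key: {key!r}")
        expected, _ = self.next_prompt()
        if expected != key:
            raise ValueError(f"expected prompt {expected!r}, got {key!r}")
        self.answers[key] = value
        if prompt.follow_up is not None and prompt.conditional and _affirmative(value):
            self.pending_follow_up = key

    @property
    def done(self) -> bool:
        return self.next_prompt()[0] == DONE

    def build_pedigree(self) -> Pedigree:
        """Assemble the pedigree once all six prompts are resolved.

        Follow-up payload conventions: personal_cancer -> list of
        ``{"type", "age_kind", "age_value"}``; family_cancer -> list of the
        same plus ``"relationship"``; polyps -> list of
        ``{"relationship", "count"}``; mutation -> list of
        ``{"gene_group", "carrier"}``.
        """
        if not self.done:
            raise ValueError("intake is not complete")
        eths = self.answers.get("ethnicity") or []
        if isinstance(eths, (str, Ethnicity)):
            eths = [eths]
        proband = FamilyMember(
            relationship=Relationship.SELF,
            sex=Sex.FEMALE,
            ethnicities=frozenset(Ethnicity(e) for e in eths),
        )
        members: dict[str, FamilyMember] = {}

        def person_for(rel_value) -> FamilyMember:
            rel = Relationship(rel_value)
            if rel is Relationship.SELF:
                return proband
            if rel.value not in members:
                members[rel.value] = FamilyMember(relationship=rel)
            return members[rel.value]

        for item in self.follow_ups.get("personal_cancer", []) or []:
            proband.diagnoses.append(_diagnosis_from(item))
        for item in self.follow_ups.get("family_cancer", []) or []:
            person_for(item["relationship"]).diagnoses.append(_diagnosis_from(item))
        for item in self.follow_ups.get("polyps", []) or []:
            person_for(item["relationship"]).polyp_count = int(item["count"])
        mutations = [
            MutationFinding(
                gene_group=GeneGroup(item["gene_group"]),
                carrier=Relationship(item.get("carrier", "self")),
            )
            for item in self.follow_ups.get("mutation", []) or []
        ]
        family_sizes = self.answers.get("family_size")
        return Pedigree(
            proband=proband,
            members=list(members.values()),
            mutations=mutations,
            family_sizes=dict(family_sizes) if family_sizes else None,
        )


def _affirmative(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("y", "yes", "true", "1")
    return bool(value)


def _diagnosis_from(item: dict):
    kind = item.get("age_kind", "unknown")
    value = item.get("age_value")
    age = AgeRecord(kind=kind, value=int(value) if value is not None else None)
    return normalize_cancer(item["type"], age=age)
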