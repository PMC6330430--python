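"""File formats: pedigree JSON (canonical), events CSV, report JSON/text,
and an optional linkage-style PED export.

The pedigree JSON document is the schema-validated interchange format:

    {"proband": {...}, "members": [...], "mutations": [...],
     "family_sizes": {...}}

with ages as ``{"kind": "exact"|"early_decade"|..., "value": n}``.  Unknown
fields are rejected with their location.  The flat CSV view (one row per
member-diagnosis) is a convenience for spreadsheet work and is lossy for
qualifiers-free round trips only.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional, Union

from pydantic import ValidationError

from .criteria import RiskReport
from .events import EventKind, IndependentEvent
from .pedigree import (
    AgeRecord,
    CancerDiagnosis,
    FamilyMember,
    Pedigree,
    Relationship,
    Sex,
)

__all__ = [
    "PedigreeFormatError",
    "read_pedigree",
    "write_pedigree",
    "read_pedigree_csv",
    "write_report",
    "write_events_csv",
    "read_events_csv",
    "write_ped",
    "pedigree_json_schema",
]

PathLike = Union[str, Path]

EVENT_CSV_COLUMNS = [
    "pedigree_id",
    "event_kind",
    "criterion_id",
    "sub_criterion",
    "side",
    "degree",
    "relationship",
    "cancer_type",
    "age",
    "group_label",
]


class PedigreeFormatError(ValueError):
    """Schema violation naming the offending field and constraint."""


def pedigree_json_schema() -> dict:
    """JSON Schema for the pedigree interchange document."""
    return Pedigree.model_json_schema()


def read_pedigree(path: PathLike) -> Pedigree:
    """Load and schema-validate a pedigree JSON document."""
    raw = Path(path).read_text()
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise PedigreeFormatError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return Pedigree.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"]) or "<root>"
        raise PedigreeFormatError(f"{path}: at {loc}: {first['msg']}") from exc


def write_pedigree(p: Pedigree, path: PathLike) -> None:
    Path(path).write_text(p.model_dump_json(indent=2, exclude_none=True) + "\n")


def read_pedigree_csv(path: PathLike) -> Pedigree:
    """Flat person/diagnosis table: columns relationship, sex, cancer_type,
    age_kind, age_value, polyp_count.  One row per diagnosis; rows with an
    empty cancer_type declare an unaffected member."""
    people: dict[tuple[str, int], FamilyMember] = {}
    proband: Optional[FamilyMember] = None
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            rel = Relationship(row["relationship"].strip())
            key = (rel.value, int(row.get("person_index") or 0))
            if key not in people:
                sex = Sex(row["sex"].strip()) if row.get("sex", "").strip() else Sex.UNKNOWN
                member = FamilyMember(relationship=rel, sex=sex)
                people[key] = member
                if rel is Relationship.SELF:
                    proband = member
            person = people[key]
            if row.get("polyp_count", "").strip():
                person.polyp_count = int(row["polyp_count"])
            ctype = row.get("cancer_type", "").strip()
            if ctype:
                kind = row.get("age_kind", "").strip() or "unknown"
                value = row.get("age_value", "").strip()
                age = AgeRecord(kind=kind, value=int(value) if value else None)
                person.diagnoses.append(CancerDiagnosis(cancer_type=ctype, age=age))
    if proband is None:
        raise PedigreeFormatError(f"{path}: no row with relationship 'self'")
    members = [m for m in people.values() if m is not proband]
    return Pedigree(proband=proband, members=members)


def write_report(report: RiskReport, path: PathLike, as_text: bool = False) -> None:
    """Structured JSON report, or the human-readable text rendering."""
    if as_text:
        Path(path).write_text(render_report_text(report))
    else:
        Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def render_report_text(report: RiskReport) -> str:
    lines = []
    if report.meets_any:
        lines.append(f"Result: {report.recommendation_text}")
        lines.append("")
        lines.append("Fulfilled criteria:")
        for ev in report.events:
            detail = f" (mirrors {ev.sub_criterion})" if ev.sub_criterion else ""
            who = ", ".join(c.value for c in ev.contributing)
            lines.append(f"  {ev.criterion_id} [{ev.syndrome}]{detail}: {who}")
    else:
        lines.append("Result: criteria not met; routine screening guidance applies")
    return "\n".join(lines) + "\n"


def write_events_csv(
    events: Iterable[tuple[IndependentEvent, str]], path: PathLike
) -> None:
    """The analysis table of the validation study: one row per event, with
    its group label ('meets' or 'does-not-meet')."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=EVENT_CSV_COLUMNS)
        writer.writeheader()
        for event, group in events:
            base = {
                "pedigree_id": event.source_pedigree_id or "",
                "event_kind": event.kind.value,
                "group_label": group,
                "side": event.side or "",
                "criterion_id": "",
                "sub_criterion": "",
                "degree": "",
                "relationship": "",
                "cancer_type": "",
                "age": "",
            }
            if event.kind is EventKind.CRITERION:
                assert event.criterion is not None
                row = dict(base)
                row["criterion_id"] = event.criterion.criterion_id
                row["sub_criterion"] = event.criterion.sub_criterion or ""
                row["relationship"] = event.criterion.index_person.value
                writer.writerow(row)
            elif event.kind is EventKind.NO_FAMILY_HISTORY:
                writer.writerow(base)
            else:
                for h in event.histories:
                    row = dict(base)
                    row.update(
                        degree=h.degree,
                        relationship=h.relationship.value,
                        cancer_type=h.cancer_type,
                        age="" if h.age is None else h.age,
                    )
                    writer.writerow(row)


def read_events_csv(path: PathLike) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


_PED_SEX = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


def write_ped(p: Pedigree, path: PathLike, family_id: str = "FAM1") -> None:
    """Linkage-format export of family structure and sex only.

    Parent links are filled where the label algebra determines them (parents,
    grandparents, siblings); everyone else gets founder placeholders.  Persons
    are numbered in pedigree order with the proband first.
    """
    ids: dict[int, str] = {}
    people = p.everyone()
    for i, _ in enumerate(people):
        ids[i] = str(i + 1)
    label_to_idx = {m.relationship: i for i, m in enumerate(people)}

    def idx_of(label: Relationship) -> str:
        i = label_to_idx.get(label)
        return ids[i] if i is not None else "0"

    R = Relationship
    parent_map = {
        R.SELF: (R.FATHER, R.MOTHER),
        R.SISTER: (R.FATHER, R.MOTHER),
        R.BROTHER: (R.FATHER, R.MOTHER),
        R.MOTHER: (R.MATERNAL_GRANDFATHER, R.MATERNAL_GRANDMOTHER),
        R.FATHER: (R.PATERNAL_GRANDFATHER, R.PATERNAL_GRANDMOTHER),
        R.MATERNAL_AUNT: (R.MATERNAL_GRANDFATHER, R.MATERNAL_GRANDMOTHER),
        R.MATERNAL_UNCLE: (R.MATERNAL_GRANDFATHER, R.MATERNAL_GRANDMOTHER),
        R.PATERNAL_AUNT: (R.PATERNAL_GRANDFATHER, R.PATERNAL_GRANDMOTHER),
        R.PATERNAL_UNCLE: (R.PATERNAL_GRANDFATHER, R.PATERNAL_GRANDMOTHER),
    }
    lines = []
    for i, person in enumerate(people):
        father, mother = parent_map.get(person.relationship, (None, None))
        lines.append(
            "\t".join(
                [
                    family_id,
                    ids[i],
                    idx_of(father) if father else "0",
                    idx_of(mother) if mother else "0",
                    _PED_SEX[person.sex],
                    "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
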