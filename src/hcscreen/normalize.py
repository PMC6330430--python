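"""Deterministic normalization of raw family-history inputs.

Pedigrees as recorded in practice carry imprecise ages ("early 70s", "70s")
and free-text tumor labels.  This module maps both onto the closed
vocabulary the criteria engine works over, using fixed conventions:

* early decade -> decade start + 2 ("early 70s" -> 72)
* late decade  -> decade start + 8 ("late 70s" -> 78)
* whole decade -> decade median     ("70s" -> 75)
* tumor labels outside the vocabulary -> ``other_unspecified`` (never an error)
* prostate cancers without grading are treated as high-risk (Gleason > 7),
  since pedigrees rarely record aggressivity

Unknown ages satisfy only "at any age" clauses downstream; they are never
imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .pedigree import AgeKind, AgeRecord, CancerDiagnosis, Qualifier

__all__ = [
    "CancerVocabulary",
    "DecadeOffsets",
    "default_vocabulary",
    "impute_age",
    "normalize_cancer",
    "is_ovarian_equivalent",
    "is_ls_related",
    "is_colorectal_or_endometrial",
    "AMSTERDAM_CANCERS",
    "OVARIAN_EQUIVALENTS",
    "LS_RELATED",
    "OTHER_UNSPECIFIED",
    "UnknownAgeError",
]

OTHER_UNSPECIFIED = "other_unspecified"

#: ovarian carcinoma for criteria purposes includes tubal/peritoneal primaries
OVARIAN_EQUIVALENTS = frozenset({"ovarian", "fallopian_tube", "primary_peritoneal"})

#: Lynch-syndrome-related cancers (incl. the Muir-Torre skin lesions)
LS_RELATED = frozenset(
    {
        "colon",
        "uterine_endometrial",
        "stomach",
        "ovarian",
        "pancreatic",
        "ureter_renal_pelvis",
        "cns_brain",
        "small_intestine",
        "sebaceous",
        "keratoacanthoma",
    }
)

#: the narrower list used by the Amsterdam II family criteria
AMSTERDAM_CANCERS = frozenset(
    {"colon", "uterine_endometrial", "small_intestine", "ureter_renal_pelvis"}
)


class UnknownAgeError(ValueError):
    """An unknown age cannot be imputed; route it to "any age" clauses."""


@dataclass(frozen=True)
class DecadeOffsets:
    """Offsets added to the decade start when imputing imprecise ages."""

    early: int = 2
    late: int = 8
    whole: int = 5


@dataclass
class CancerVocabulary:
    """Closed tumor-type vocabulary with a synonym table.

    The mapping is total: any label it does not recognize normalizes to
    ``other_unspecified``.  Extra synonyms or canonical types may be layered on
    via :meth:`extend` without touching the shipped table.
    """

    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.synonyms = {self._key(k): v for k, v in self.synonyms.items()}

    @staticmethod
    def _key(label: str) -> str:
        return " ".join(label.strip().lower().replace("_", " ").split())

    @property
    def canonical_types(self) -> frozenset[str]:
        return frozenset(self.synonyms.values())

    def canonicalize(self, label: str) -> str:
        return self.synonyms.get(self._key(label), OTHER_UNSPECIFIED)

    def extend(self, mapping: dict[str, str]) -> "CancerVocabulary":
        merged = dict(self.synonyms)
        merged.update({self._key(k): v for k, v in mapping.items()})
        return CancerVocabulary(merged)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "CancerVocabulary":
        return cls({syn: canon for syn, canon in rows})


def _load_shipped_vocabulary() -> CancerVocabulary:
    rows: list[tuple[str, str]] = []
    with resources.files("hcscreen.data").joinpath("cancer_vocabulary.csv").open() as fh:
        for rec in csv.reader(fh):
            if not rec or rec[0].startswith("#"):
                continue
            rows.append((rec[0], rec[1]))
    return CancerVocabulary.from_rows(rows)


_DEFAULT_VOCABULARY: Optional[CancerVocabulary] = None


def default_vocabulary() -> CancerVocabulary:
    global _DEFAULT_VOCABULARY
    if _DEFAULT_VOCABULARY is None:
        _DEFAULT_VOCABULARY = _load_shipped_vocabulary()
    return _DEFAULT_VOCABULARY


def impute_age(age: AgeRecord, offsets: DecadeOffsets = DecadeOffsets()) -> int:
    """Integer age in years for a (possibly imprecise) age record.

    Exact ages pass through; decade records get the fixed offsets
    (early -> +2, late -> +8, whole decade -> median +5).
    """
    if age.kind is AgeKind.UNKNOWN:
        raise UnknownAgeError("unknown age: usable only in 'at any age' clauses")
    assert age.value is not None
    if age.kind is AgeKind.EXACT:
        return age.value
    offset = {
        AgeKind.EARLY_DECADE: offsets.early,
        AgeKind.LATE_DECADE: offsets.late,
        AgeKind.DECADE: offsets.whole,
    }[age.kind]
    return age.value + offset


def normalize_cancer(
    label: str,
    qualifiers: Optional[Iterable[Qualifier]] = None,
    age: Optional[AgeRecord] = None,
    vocabulary: Optional[CancerVocabulary] = None,
    primary_index: int = 1,
) -> CancerDiagnosis:
    """Build a canonical diagnosis from a free-text tumor label.

    Total function: unmapped labels become ``other_unspecified``.  Prostate
    entries with no grading information receive the high-risk (Gleason > 7)
    qualifier.
    """
    if not label or not label.strip():
        raise ValueError("empty cancer label")
    vocab = vocabulary or default_vocabulary()
    quals = set(qualifiers or ())
    text = label.strip().lower()
    # common pedigree shorthand: subtype appended to the label
    if "dcis" in text:
        quals.add(Qualifier.DCIS)
        text = text.replace("dcis", " ").replace("–", " ").replace("-", " ")
        if not text.strip():
            text = "breast"
    if "triple negative" in text or "triple-negative" in text:
        quals.add(Qualifier.TRIPLE_NEGATIVE)
        text = text.replace("triple negative", " ").replace("triple-negative", " ")
        if not text.strip():
            text = "breast"
    canonical = vocab.canonicalize(text)
    if canonical == OTHER_UNSPECIFIED and (Qualifier.DCIS in quals or Qualifier.TRIPLE_NEGATIVE in quals):
        canonical = "breast"
    if canonical == "prostate" and Qualifier.GLEASON_GT7 not in quals:
        quals.add(Qualifier.GLEASON_GT7)
    return CancerDiagnosis(
        cancer_type=canonical,
        age=age if age is not None else AgeRecord.unknown(),
        qualifiers=frozenset(quals),
        primary_index=primary_index,
    )


def is_ovarian_equivalent(cancer_type: str) -> bool:
    """Ovarian carcinoma in the criteria sense (incl. fallopian tube and
    primary peritoneal primaries)."""
    return cancer_type in OVARIAN_EQUIVALENTS


def is_ls_related(cancer_type: str) -> bool:
    """Lynch-syndrome-related cancer."""
    return cancer_type in LS_RELATED


def is_colorectal_or_endometrial(cancer_type: str) -> bool:
    return cancer_type in ("colon", "uterine_endometrial")
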