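"""Shared builders: terse pedigree construction and a seeded random-pedigree
generator used by the oracle-equivalence and monotonicity suites."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from hcscreen.pedigree import (
    AgeKind,
    AgeRecord,
    CancerDiagnosis,
    Ethnicity,
    FamilyMember,
    GeneGroup,
    MutationFinding,
    Pedigree,
    Qualifier,
    Relationship,
    Sex,
)

R = Relationship


def dx(cancer_type: str, age=None, *quals: Qualifier, kind: AgeKind = AgeKind.EXACT):
    """Terse diagnosis builder; age None means unknown."""
    if age is None:
        rec = AgeRecord.unknown()
    else:
        rec = AgeRecord(kind=kind, value=age)
    return CancerDiagnosis(cancer_type=cancer_type, age=rec, qualifiers=frozenset(quals))


def member(rel: Relationship, *diagnoses, sex: Sex = Sex.UNKNOWN, polyps=None):
    return FamilyMember(
        relationship=rel, sex=sex, diagnoses=list(diagnoses), polyp_count=polyps
    )


def pedigree(*members, proband_dx=(), ethnicities=(), mutations=(), sex=Sex.FEMALE,
             polyps=None, family_sizes=None):
    pro = FamilyMember(
        relationship=R.SELF,
        sex=sex,
        diagnoses=list(proband_dx),
        ethnicities=frozenset(ethnicities),
        polyp_count=polyps,
    )
    return Pedigree(
        proband=pro,
        members=list(members),
        mutations=list(mutations),
        family_sizes=family_sizes,
    )


# pools for random pedigrees: heavy on criteria-relevant types so rules
# actually exercise, light on bystander types
_DX_TYPES = [
    "breast",
    "breast",
    "ovarian",
    "fallopian_tube",
    "colon",
    "uterine_endometrial",
    "stomach",
    "cns_brain",
    "pancreatic",
    "lung",
    "melanoma",
    "skin_unspecified",
    "other_unspecified",
]

_ALL_LABELS = [r for r in Relationship if r is not Relationship.SELF]


def random_pedigree(rng: np.random.Generator, max_members: int = 8) -> Pedigree:
    """A random (not necessarily plausible) pedigree over the full label set,
    mixing exact, decade-imprecise, and unknown ages."""

    def random_age():
        u = rng.random()
        if u < 0.15:
            return AgeRecord.unknown()
        years = int(rng.integers(25, 86))
        if u < 0.30:
            kind = [AgeKind.EARLY_DECADE, AgeKind.LATE_DECADE, AgeKind.DECADE][
                int(rng.integers(3))
            ]
            return AgeRecord(kind=kind, value=(years // 10) * 10)
        return AgeRecord.exact(years)

    def random_dx(person_sex: Sex):
        ctype = _DX_TYPES[int(rng.integers(len(_DX_TYPES)))]
        quals = set()
        if ctype == "breast" and rng.random() < 0.15:
            quals.add(Qualifier.TRIPLE_NEGATIVE)
        if person_sex is Sex.MALE and rng.random() < 0.3:
            ctype = "prostate"
            quals.add(Qualifier.GLEASON_GT7)
        return CancerDiagnosis(
            cancer_type=ctype, age=random_age(), qualifiers=frozenset(quals)
        )

    pro_sex = Sex.FEMALE if rng.random() < 0.9 else Sex.MALE
    pro = FamilyMember(
        relationship=Relationship.SELF,
        sex=pro_sex,
        ethnicities=frozenset(
            {Ethnicity.ASHKENAZI_JEWISH} if rng.random() < 0.12 else {Ethnicity.CAUCASIAN}
        ),
        polyp_count=int(rng.integers(0, 16)) if rng.random() < 0.08 else None,
    )
    for _ in range(int(rng.integers(0, 3))):
        pro.diagnoses.append(random_dx(pro_sex))

    members = []
    for _ in range(int(rng.integers(0, max_members + 1))):
        rel = _ALL_LABELS[int(rng.integers(len(_ALL_LABELS)))]
        m = FamilyMember(relationship=rel)
        if m.sex is Sex.UNKNOWN:
            m.sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
        for _ in range(int(rng.integers(0, 3))):
            m.diagnoses.append(random_dx(m.sex))
        if rng.random() < 0.06:
            m.polyp_count = int(rng.integers(0, 16))
        members.append(m)

    mutations = []
    if rng.random() < 0.06:
        genes = list(GeneGroup)
        carriers = [Relationship.SELF] + [m.relationship for m in members]
        mutations.append(
            MutationFinding(
                gene_group=genes[int(rng.integers(len(genes)))],
                carrier=carriers[int(rng.integers(len(carriers)))],
            )
        )
    return Pedigree(proband=pro, members=members, mutations=mutations)


@pytest.fixture
def rng():
    return np.random.default_rng(20_2409)
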