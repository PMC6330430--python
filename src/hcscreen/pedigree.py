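"""Data model for three-generation family cancer histories.

A family history is captured as a :class:`Pedigree`: a proband plus a list of
relatives identified by controlled kinship labels (``mother``,
``maternal aunt``, ``paternal first cousin``, ...).  The engine never builds an
explicit genealogical graph; degree of relation, lineage (maternal vs paternal
bloodline) and generation offset are table-driven properties of the label, and
re-rooting the pedigree at a relative is a label-algebra operation.  This
mirrors how clinical intake tools record family history: degree + side, not
topology.

Kinship conventions
-------------------
* degree: standard consanguinity degree (parents/siblings/children = 1;
  grandparents, aunts/uncles, half-siblings, nieces/nephews, grandchildren = 2;
  great-grandparents, great-aunts/uncles, first cousins = 3).
* lineage: ``maternal``/``paternal`` for one-sided kin; full siblings,
  children, grandchildren, nieces/nephews share both parental bloodlines and
  carry lineage ``both`` (they may combine with relatives of either side).
* generation offset: proband = 0, parents = +1, grandparents = +2,
  children = -1.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Relationship",
    "Lineage",
    "Sex",
    "AgeKind",
    "Qualifier",
    "GeneGroup",
    "Ethnicity",
    "AgeRecord",
    "CancerDiagnosis",
    "MutationFinding",
    "FamilyMember",
    "Pedigree",
    "KinshipError",
    "degree_of",
    "lineage_of",
    "generation_of",
    "close_blood_relatives",
    "reroot",
    "reroot_with_origin",
    "relabel",
]


class KinshipError(ValueError):
    """Raised for labels outside the controlled vocabulary or invalid re-roots."""


class Relationship(str, enum.Enum):
    SELF = "self"
    MOTHER = "mother"
    FATHER = "father"
    SISTER = "sister"
    BROTHER = "brother"
    DAUGHTER = "daughter"
    SON = "son"
    MATERNAL_GRANDMOTHER = "maternal_grandmother"
    MATERNAL_GRANDFATHER = "maternal_grandfather"
    PATERNAL_GRANDMOTHER = "paternal_grandmother"
    PATERNAL_GRANDFATHER = "paternal_grandfather"
    MATERNAL_AUNT = "maternal_aunt"
    MATERNAL_UNCLE = "maternal_uncle"
    PATERNAL_AUNT = "paternal_aunt"
    PATERNAL_UNCLE = "paternal_uncle"
    NIECE = "niece"
    NEPHEW = "nephew"
    MATERNAL_HALF_SISTER = "maternal_half_sister"
    MATERNAL_HALF_BROTHER = "maternal_half_brother"
    PATERNAL_HALF_SISTER = "paternal_half_sister"
    PATERNAL_HALF_BROTHER = "paternal_half_brother"
    GRANDDAUGHTER = "granddaughter"
    GRANDSON = "grandson"
    MATERNAL_FIRST_COUSIN = "maternal_first_cousin"
    PATERNAL_FIRST_COUSIN = "paternal_first_cousin"
    MATERNAL_GREAT_GRANDMOTHER = "maternal_great_grandmother"
    MATERNAL_GREAT_GRANDFATHER = "maternal_great_grandfather"
    PATERNAL_GREAT_GRANDMOTHER = "paternal_great_grandmother"
    PATERNAL_GREAT_GRANDFATHER = "paternal_great_grandfather"
    MATERNAL_GREAT_AUNT = "maternal_great_aunt"
    MATERNAL_GREAT_UNCLE = "maternal_great_uncle"
    PATERNAL_GREAT_AUNT = "paternal_great_aunt"
    PATERNAL_GREAT_UNCLE = "paternal_great_uncle"


class Lineage(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BOTH = "both"
    SELF = "self"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class AgeKind(str, enum.Enum):
    EXACT = "exact"
    EARLY_DECADE = "early_decade"
    LATE_DECADE = "late_decade"
    DECADE = "decade"
    UNKNOWN = "unknown"


class Qualifier(str, enum.Enum):
    DCIS = "dcis"
    TRIPLE_NEGATIVE = "triple_negative"
    GLEASON_GT7 = "gleason_gt7"
    SYNCHRONOUS = "synchronous"
    METACHRONOUS = "metachronous"


class GeneGroup(str, enum.Enum):
    BRCA1_BRCA2 = "brca1_brca2"
    LYNCH = "lynch"
    APC_MUTYH = "apc_mutyh"


class Ethnicity(str, enum.Enum):
    AFRICAN_AMERICAN = "african_american"
    ASHKENAZI_JEWISH = "ashkenazi_jewish"
    ASIAN = "asian"
    CAUCASIAN = "caucasian"
    HISPANIC = "hispanic"
    NATIVE_AMERICAN = "native_american"
    UNKNOWN = "unknown"


R = Relationship
L = Lineage

# label -> (degree, lineage, generation offset)
_KINSHIP: dict[Relationship, tuple[int, Lineage, int]] = {
    R.SELF: (0, L.SELF, 0),
    R.MOTHER: (1, L.MATERNAL, 1),
    R.FATHER: (1, L.PATERNAL, 1),
    R.SISTER: (1, L.BOTH, 0),
    R.BROTHER: (1, L.BOTH, 0),
    R.DAUGHTER: (1, L.BOTH, -1),
    R.SON: (1, L.BOTH, -1),
    R.MATERNAL_GRANDMOTHER: (2, L.MATERNAL, 2),
    R.MATERNAL_GRANDFATHER: (2, L.MATERNAL, 2),
    R.PATERNAL_GRANDMOTHER: (2, L.PATERNAL, 2),
    R.PATERNAL_GRANDFATHER: (2, L.PATERNAL, 2),
    R.MATERNAL_AUNT: (2, L.MATERNAL, 1),
    R.MATERNAL_UNCLE: (2, L.MATERNAL, 1),
    R.PATERNAL_AUNT: (2, L.PATERNAL, 1),
    R.PATERNAL_UNCLE: (2, L.PATERNAL, 1),
    R.NIECE: (2, L.BOTH, -1),
    R.NEPHEW: (2, L.BOTH, -1),
    R.MATERNAL_HALF_SISTER: (2, L.MATERNAL, 0),
    R.MATERNAL_HALF_BROTHER: (2, L.MATERNAL, 0),
    R.PATERNAL_HALF_SISTER: (2, L.PATERNAL, 0),
    R.PATERNAL_HALF_BROTHER: (2, L.PATERNAL, 0),
    R.GRANDDAUGHTER: (2, L.BOTH, -2),
    R.GRANDSON: (2, L.BOTH, -2),
    R.MATERNAL_FIRST_COUSIN: (3, L.MATERNAL, 0),
    R.PATERNAL_FIRST_COUSIN: (3, L.PATERNAL, 0),
    R.MATERNAL_GREAT_GRANDMOTHER: (3, L.MATERNAL, 3),
    R.MATERNAL_GREAT_GRANDFATHER: (3, L.MATERNAL, 3),
    R.PATERNAL_GREAT_GRANDMOTHER: (3, L.PATERNAL, 3),
    R.PATERNAL_GREAT_GRANDFATHER: (3, L.PATERNAL, 3),
    R.MATERNAL_GREAT_AUNT: (3, L.MATERNAL, 2),
    R.MATERNAL_GREAT_UNCLE: (3, L.MATERNAL, 2),
    R.PATERNAL_GREAT_AUNT: (3, L.PATERNAL, 2),
    R.PATERNAL_GREAT_UNCLE: (3, L.PATERNAL, 2),
}

# sex implied by a sexed kinship term; unsexed labels are absent
_LABEL_SEX: dict[Relationship, Sex] = {
    R.MOTHER: Sex.FEMALE,
    R.FATHER: Sex.MALE,
    R.SISTER: Sex.FEMALE,
    R.BROTHER: Sex.MALE,
    R.DAUGHTER: Sex.FEMALE,
    R.SON: Sex.MALE,
    R.MATERNAL_GRANDMOTHER: Sex.FEMALE,
    R.MATERNAL_GRANDFATHER: Sex.MALE,
    R.PATERNAL_GRANDMOTHER: Sex.FEMALE,
    R.PATERNAL_GRANDFATHER: Sex.MALE,
    R.MATERNAL_AUNT: Sex.FEMALE,
    R.MATERNAL_UNCLE: Sex.MALE,
    R.PATERNAL_AUNT: Sex.FEMALE,
    R.PATERNAL_UNCLE: Sex.MALE,
    R.NIECE: Sex.FEMALE,
    R.NEPHEW: Sex.MALE,
    R.MATERNAL_HALF_SISTER: Sex.FEMALE,
    R.MATERNAL_HALF_BROTHER: Sex.MALE,
    R.PATERNAL_HALF_SISTER: Sex.FEMALE,
    R.PATERNAL_HALF_BROTHER: Sex.MALE,
    R.GRANDDAUGHTER: Sex.FEMALE,
    R.GRANDSON: Sex.MALE,
    R.MATERNAL_GREAT_GRANDMOTHER: Sex.FEMALE,
    R.MATERNAL_GREAT_GRANDFATHER: Sex.MALE,
    R.PATERNAL_GREAT_GRANDMOTHER: Sex.FEMALE,
    R.PATERNAL_GREAT_GRANDFATHER: Sex.MALE,
    R.MATERNAL_GREAT_AUNT: Sex.FEMALE,
    R.MATERNAL_GREAT_UNCLE: Sex.MALE,
    R.PATERNAL_GREAT_AUNT: Sex.FEMALE,
    R.PATERNAL_GREAT_UNCLE: Sex.MALE,
}


def _as_relationship(label) -> Relationship:
    if isinstance(label, Relationship):
        return label
    try:
        return Relationship(label)
    except ValueError:
        raise KinshipError(f"unknown relationship label: {label!r}") from None


def degree_of(relationship) -> int:
    """Consanguinity degree of a label relative to the proband (self = 0)."""
    return _KINSHIP[_as_relationship(relationship)][0]


def lineage_of(relationship) -> Lineage:
    """Bloodline of a label: maternal, paternal, both (shares both) or self."""
    return _KINSHIP[_as_relationship(relationship)][1]


def generation_of(relationship) -> int:
    """Generation offset of a label (proband 0, parents +1, children -1)."""
    return _KINSHIP[_as_relationship(relationship)][2]


def _side_compatible(lineage: Lineage, side: Lineage) -> bool:
    return lineage in (side, L.BOTH)


# --------------------------------------------------------------------------
# domain records
# --------------------------------------------------------------------------


class AgeRecord(BaseModel):
    """An age at diagnosis, possibly imprecise ('early 70s', '70s', ...)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: AgeKind = AgeKind.UNKNOWN
    value: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "AgeRecord":
        if self.kind is AgeKind.UNKNOWN:
            if self.value is not None:
                raise ValueError("unknown ages carry no value")
            return self
        if self.value is None:
            raise ValueError(f"age kind {self.kind.value} requires a value")
        if self.kind is AgeKind.EXACT:
            if not 0 <= self.value <= 120:
                raise ValueError("exact age must be in [0, 120]")
        elif self.value % 10 != 0 or not 0 <= self.value <= 120:
            raise ValueError("decade kinds take the decade start (multiple of 10)")
        return self

    @classmethod
    def exact(cls, years: int) -> "AgeRecord":
        return cls(kind=AgeKind.EXACT, value=years)

    @classmethod
    def unknown(cls) -> "AgeRecord":
        return cls(kind=AgeKind.UNKNOWN)


class CancerDiagnosis(BaseModel):
    """One primary tumor: canonical type, (possibly imprecise) age, qualifiers."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    cancer_type: str
    age: AgeRecord = Field(default_factory=AgeRecord.unknown)
    qualifiers: frozenset[Qualifier] = frozenset()
    primary_index: int = 1

    @model_validator(mode="after")
    def _check(self) -> "CancerDiagnosis":
        if self.primary_index < 1:
            raise ValueError("primary_index is 1-based")
        return self


class MutationFinding(BaseModel):
    """A known familial pathogenic variant, by gene group and tested person."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    gene_group: GeneGroup
    carrier: Relationship = Relationship.SELF


class FamilyMember(BaseModel):
    """A person in the pedigree, identified by their kinship label.

    ``ethnicities`` is populated on the proband only (intake asks about the
    respondent's background; blood relatives share ancestry by construction).
    """

    model_config = ConfigDict(extra="forbid")

    relationship: Relationship
    sex: Sex = Sex.UNKNOWN
    diagnoses: list[CancerDiagnosis] = Field(default_factory=list)
    polyp_count: Optional[int] = None
    deceased: Optional[bool] = None
    ethnicities: frozenset[Ethnicity] = frozenset()

    @model_validator(mode="after")
    def _check(self) -> "FamilyMember":
        implied = _LABEL_SEX.get(self.relationship)
        if implied is not None:
            if self.sex is Sex.UNKNOWN:
                self.sex = implied
            elif self.sex is not implied:
                raise ValueError(
                    f"label {self.relationship.value} implies sex {implied.value}, "
                    f"got {self.sex.value}"
                )
        if self.polyp_count is not None and self.polyp_count < 0:
            raise ValueError("polyp_count must be non-negative")
        return self

    @property
    def degree(self) -> int:
        return degree_of(self.relationship)

    @property
    def lineage(self) -> Lineage:
        return lineage_of(self.relationship)

    @property
    def generation(self) -> int:
        return generation_of(self.relationship)


class Pedigree(BaseModel):
    """Proband plus labeled relatives: the unit of criteria evaluation.

    ``family_sizes`` optionally records the declared number of relatives per
    side (keys like ``"maternal"``/``"paternal"``); when absent the family
    structure counts as unknown for limited-family-history clauses.
    """

    model_config = ConfigDict(extra="forbid")

    proband: FamilyMember
    members: list[FamilyMember] = Field(default_factory=list)
    mutations: list[MutationFinding] = Field(default_factory=list)
    family_sizes: Optional[dict[str, int]] = None
    pedigree_id: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Pedigree":
        if self.proband.relationship is not Relationship.SELF:
            raise ValueError("proband must carry relationship 'self'")
        for m in self.members:
            if m.relationship is Relationship.SELF:
                raise ValueError("at most one member may be 'self' (the proband)")
        return self

    def everyone(self) -> list[FamilyMember]:
        """Proband first, then relatives."""
        return [self.proband, *self.members]


def close_blood_relatives(pedigree: Pedigree, side) -> list[FamilyMember]:
    """Relatives of degree 1-3 on one side of the family.

    Members sharing both bloodlines (siblings, children, ...) appear on either
    side; the proband is never included.
    """
    side = Lineage(side)
    if side not in (L.MATERNAL, L.PATERNAL):
        raise KinshipError(f"side must be maternal or paternal, got {side.value}")
    return [m for m in pedigree.members if _side_compatible(m.lineage, side)]


# --------------------------------------------------------------------------
# re-rooting (label algebra)
# --------------------------------------------------------------------------


def _by_sex(sex: Sex, female: Relationship, male: Relationship) -> Relationship:
    """Pick the sexed variant of a label; unknown sex defaults to the female
    form (the study cohorts these histories come from are all-female; sex on
    the member record is authoritative for sex-dependent criteria)."""
    return male if sex is Sex.MALE else female


def _sided(side: Lineage, maternal: Relationship, paternal: Relationship) -> Relationship:
    return maternal if side is L.MATERNAL else paternal


def relabel(
    root: Relationship,
    member: Relationship,
    member_sex: Sex = Sex.UNKNOWN,
    proband_sex: Sex = Sex.FEMALE,
) -> Optional[Relationship]:
    """Kinship label of ``member`` as seen from ``root`` (both labels relative
    to the proband), or ``None`` when it is not derivable from labels alone.

    Ambiguities are dropped rather than guessed: e.g. a maternal
    great-grandparent is some grandparent of the proband's mother, but the
    labels do not say on which of *her* sides, so no controlled label applies.
    """
    root = _as_relationship(root)
    member = _as_relationship(member)
    if degree_of(root) not in (1, 2):
        raise KinshipError(f"re-root requires a first- or second-degree relative, got {root.value}")
    if member == root:
        return R.SELF

    deg_m, lin_m, _ = _KINSHIP[member]

    def child_of_root(sex: Sex) -> Relationship:
        return _by_sex(sex, R.DAUGHTER, R.SON)

    def grandchild_of_root(sex: Sex) -> Relationship:
        return _by_sex(sex, R.GRANDDAUGHTER, R.GRANDSON)

    # ---- parents as root --------------------------------------------------
    if root in (R.MOTHER, R.FATHER):
        side = L.MATERNAL if root is R.MOTHER else L.PATERNAL
        if member is R.SELF:
            return child_of_root(proband_sex)
        if member in (R.SISTER, R.BROTHER):
            return child_of_root(_LABEL_SEX[member])
        if member in (R.DAUGHTER, R.SON, R.NIECE, R.NEPHEW):
            return grandchild_of_root(_LABEL_SEX[member])
        if lin_m is not side:
            return None  # other bloodline, or spouse (the other parent)
        if generation_of(member) == 2 and deg_m == 2:  # that side's grandparents
            return _by_sex(_LABEL_SEX[member], R.MOTHER, R.FATHER)
        if member in (R.MATERNAL_AUNT, R.PATERNAL_AUNT):
            return R.SISTER
        if member in (R.MATERNAL_UNCLE, R.PATERNAL_UNCLE):
            return R.BROTHER
        if member in (R.MATERNAL_FIRST_COUSIN, R.PATERNAL_FIRST_COUSIN):
            return _by_sex(member_sex, R.NIECE, R.NEPHEW)
        if member in (R.MATERNAL_HALF_SISTER, R.PATERNAL_HALF_SISTER):
            return R.DAUGHTER
        if member in (R.MATERNAL_HALF_BROTHER, R.PATERNAL_HALF_BROTHER):
            return R.SON
        return None  # great-grandparents / great-aunts: root's side unknown

    # ---- full siblings as root --------------------------------------------
    if root in (R.SISTER, R.BROTHER):
        if member is R.SELF:
            return _by_sex(proband_sex, R.SISTER, R.BROTHER)
        if member in (R.DAUGHTER, R.SON):
            return _by_sex(_LABEL_SEX[member], R.NIECE, R.NEPHEW)
        if member in (R.NIECE, R.NEPHEW, R.GRANDDAUGHTER, R.GRANDSON):
            return None  # which sibling's child is not encoded
        # parents, grandparents, aunts/uncles, cousins, half-sibs, great-*:
        # identical relation for a full sibling
        return member

    # ---- children as root --------------------------------------------------
    if root in (R.DAUGHTER, R.SON):
        side = L.MATERNAL if proband_sex is not Sex.MALE else L.PATERNAL
        if member is R.SELF:
            return _by_sex(proband_sex, R.MOTHER, R.FATHER)
        if member in (R.DAUGHTER, R.SON):
            # another child of the proband; full siblingship assumed
            return _by_sex(_LABEL_SEX[member], R.SISTER, R.BROTHER)
        if member is R.MOTHER:
            return _sided(side, R.MATERNAL_GRANDMOTHER, R.PATERNAL_GRANDMOTHER)
        if member is R.FATHER:
            return _sided(side, R.MATERNAL_GRANDFATHER, R.PATERNAL_GRANDFATHER)
        if member is R.SISTER:
            return _sided(side, R.MATERNAL_AUNT, R.PATERNAL_AUNT)
        if member is R.BROTHER:
            return _sided(side, R.MATERNAL_UNCLE, R.PATERNAL_UNCLE)
        if deg_m == 2 and generation_of(member) == 2:  # proband's grandparents
            return _sided(
                side,
                _by_sex(_LABEL_SEX[member], R.MATERNAL_GREAT_GRANDMOTHER, R.MATERNAL_GREAT_GRANDFATHER),
                _by_sex(_LABEL_SEX[member], R.PATERNAL_GREAT_GRANDMOTHER, R.PATERNAL_GREAT_GRANDFATHER),
            )
        if member in (R.MATERNAL_AUNT, R.PATERNAL_AUNT):
            return _sided(side, R.MATERNAL_GREAT_AUNT, R.PATERNAL_GREAT_AUNT)
        if member in (R.MATERNAL_UNCLE, R.PATERNAL_UNCLE):
            return _sided(side, R.MATERNAL_GREAT_UNCLE, R.PATERNAL_GREAT_UNCLE)
        if member in (R.NIECE, R.NEPHEW):
            return _sided(side, R.MATERNAL_FIRST_COUSIN, R.PATERNAL_FIRST_COUSIN)
        return None  # half-kin, cousins, great-* of proband: degree > 3 or no label

    # ---- grandparents as root ----------------------------------------------
    if degree_of(root) == 2 and generation_of(root) == 2:
        side = lineage_of(root)
        if member is R.SELF:
            return grandchild_of_root(proband_sex)
        if member in (R.SISTER, R.BROTHER):
            return grandchild_of_root(_LABEL_SEX[member])
        if lin_m is not side:
            return None
        if member in (R.MOTHER, R.FATHER):
            return child_of_root(_LABEL_SEX[member])
        if member in (R.MATERNAL_AUNT, R.PATERNAL_AUNT):
            return R.DAUGHTER
        if member in (R.MATERNAL_UNCLE, R.PATERNAL_UNCLE):
            return R.SON
        if member in (R.MATERNAL_FIRST_COUSIN, R.PATERNAL_FIRST_COUSIN):
            return grandchild_of_root(member_sex)
        if member in (
            R.MATERNAL_HALF_SISTER,
            R.MATERNAL_HALF_BROTHER,
            R.PATERNAL_HALF_SISTER,
            R.PATERNAL_HALF_BROTHER,
        ):
            # half-sibling via the root's child (the proband's parent)
            return grandchild_of_root(_LABEL_SEX[member])
        return None  # spouse grandparent, great-*: not blood / ambiguous side

    # ---- aunts/uncles as root ----------------------------------------------
    if root in (R.MATERNAL_AUNT, R.MATERNAL_UNCLE, R.PATERNAL_AUNT, R.PATERNAL_UNCLE):
        side = lineage_of(root)
        if member is R.SELF:
            return _by_sex(proband_sex, R.NIECE, R.NEPHEW)
        if member in (R.SISTER, R.BROTHER):
            return _by_sex(_LABEL_SEX[member], R.NIECE, R.NEPHEW)
        if lin_m is not side:
            return None
        if member in (R.MOTHER, R.FATHER):
            return _by_sex(_LABEL_SEX[member], R.SISTER, R.BROTHER)
        if member in (R.MATERNAL_AUNT, R.PATERNAL_AUNT):
            return R.SISTER
        if member in (R.MATERNAL_UNCLE, R.PATERNAL_UNCLE):
            return R.BROTHER
        if deg_m == 2 and generation_of(member) == 2:  # that side's grandparents
            return _by_sex(_LABEL_SEX[member], R.MOTHER, R.FATHER)
        if member in (
            R.MATERNAL_HALF_SISTER,
            R.MATERNAL_HALF_BROTHER,
            R.PATERNAL_HALF_SISTER,
            R.PATERNAL_HALF_BROTHER,
        ):
            return _by_sex(_LABEL_SEX[member], R.NIECE, R.NEPHEW)
        return None  # cousins (own child vs niece?), great-*: ambiguous

    # ---- half-siblings as root ---------------------------------------------
    if root in (
        R.MATERNAL_HALF_SISTER,
        R.MATERNAL_HALF_BROTHER,
        R.PATERNAL_HALF_SISTER,
        R.PATERNAL_HALF_BROTHER,
    ):
        side = lineage_of(root)
        half = {
            (L.MATERNAL, Sex.FEMALE): R.MATERNAL_HALF_SISTER,
            (L.MATERNAL, Sex.MALE): R.MATERNAL_HALF_BROTHER,
            (L.PATERNAL, Sex.FEMALE): R.PATERNAL_HALF_SISTER,
            (L.PATERNAL, Sex.MALE): R.PATERNAL_HALF_BROTHER,
        }
        if member is R.SELF:
            return half[(side, Sex.MALE if proband_sex is Sex.MALE else Sex.FEMALE)]
        if member in (R.SISTER, R.BROTHER):
            return half[(side, _LABEL_SEX[member])]
        if lin_m is not side:
            return None
        if member in (R.MOTHER, R.FATHER):
            return member  # the shared parent
        if member in (
            R.MATERNAL_HALF_SISTER,
            R.MATERNAL_HALF_BROTHER,
            R.PATERNAL_HALF_SISTER,
            R.PATERNAL_HALF_BROTHER,
        ):
            return half[(side, _LABEL_SEX[member])]
        # same-side grandparents, aunts/uncles, cousins, great-* are shared
        # through the common parent: identical labels from the root's seat
        return member

    # ---- nieces/nephews and grandchildren as root --------------------------
    # The connecting person (which sibling, which child) is not encoded in the
    # labels, so no relation to anyone else is derivable.
    return None


def reroot(pedigree: Pedigree, new_root: FamilyMember) -> Pedigree:
    """Re-express the pedigree from the seat of a first- or second-degree
    relative.

    The new proband is ``new_root`` (keeping their diagnoses, polyp count and
    the family's ethnicity); every original member — including the original
    proband — whose relation to the root is derivable from the label algebra is
    re-labeled, and the rest are dropped.  Used to mirror personal-history
    criteria onto affected relatives.
    """
    return reroot_with_origin(pedigree, new_root)[0]


def reroot_with_origin(
    pedigree: Pedigree, new_root: FamilyMember
) -> tuple[Pedigree, dict[int, Relationship]]:
    """Like :func:`reroot`, also returning ``id(new member) -> original
    label`` so callers can trace re-labeled relatives back to their seats in
    the source pedigree (labels alone cannot: two relatives may share a
    re-rooted label)."""
    root_label = new_root.relationship
    if degree_of(root_label) not in (1, 2):
        raise KinshipError(
            f"cannot re-root at {root_label.value}: only first- or second-degree "
            "relatives may serve as index"
        )
    if all(m is not new_root for m in pedigree.members):
        raise KinshipError("new_root must be a member of the pedigree")

    proband_sex = pedigree.proband.sex
    new_proband = FamilyMember(
        relationship=R.SELF,
        sex=new_root.sex,
        diagnoses=list(new_root.diagnoses),
        polyp_count=new_root.polyp_count,
        deceased=new_root.deceased,
        ethnicities=pedigree.proband.ethnicities,
    )
    new_members: list[FamilyMember] = []
    origin: dict[int, Relationship] = {}
    originals: Iterable[FamilyMember] = [pedigree.proband] + [
        m for m in pedigree.members if m is not new_root
    ]
    for m in originals:
        new_label = relabel(root_label, m.relationship, m.sex, proband_sex)
        if new_label is None or new_label is R.SELF:
            continue
        sex = m.sex if m.sex is not Sex.UNKNOWN else Sex.UNKNOWN
        nm = FamilyMember(
            relationship=new_label,
            sex=_LABEL_SEX.get(new_label, sex),
            diagnoses=list(m.diagnoses),
            polyp_count=m.polyp_count,
            deceased=m.deceased,
        )
        origin[id(nm)] = m.relationship
        new_members.append(nm)
    new_mutations: list[MutationFinding] = []
    for mut in pedigree.mutations:
        if mut.carrier == root_label:
            new_mutations.append(MutationFinding(gene_group=mut.gene_group, carrier=R.SELF))
            continue
        new_label = relabel(root_label, mut.carrier, Sex.UNKNOWN, proband_sex)
        if new_label is not None:
            new_mutations.append(MutationFinding(gene_group=mut.gene_group, carrier=new_label))
    rerooted = Pedigree(
        proband=new_proband,
        members=new_members,
        mutations=new_mutations,
        family_sizes=None,
        pedigree_id=pedigree.pedigree_id,
    )
    return rerooted, origin
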