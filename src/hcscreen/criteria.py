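"""Guideline criteria engine.

Matches a normalized pedigree one-to-one against the enumerated genetic-testing
criteria for BRCA-related hereditary breast and ovarian cancer (B1-B19), Lynch
syndrome (L1-L6, including Amsterdam II), and polyposis syndromes (P1-P3).
Every fulfilled criterion is reported (not first-match), each as a
self-certifying :class:`CriterionEvent` naming the contributing relatives.

Counting conventions
--------------------
* "close blood relative" = degree 1-3 on one side of the family; relatives
  sharing both bloodlines (siblings, children) may count on either side;
  clauses never combine relatives across sides.
* The index person is never counted among their own supporting relatives;
  distinct people, not distinct tumors, are counted (except the
  second-breast-primary clause, which is within-person by design).
* Family-history mirroring (B18): any first- or second-degree relative may
  serve as index for the personal-history clauses B2-B17, evaluated on the
  re-rooted pedigree.
* Age bounds: the BRCA bounds 45/50/60 are inclusive ("diagnosed at or under
  45"); Lynch and Amsterdam II use strict "before age 50".  Both are
  configurable.
* Unknown ages satisfy only "at any age" clauses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from . import normalize as nz
from .pedigree import (
    Ethnicity,
    FamilyMember,
    GeneGroup,
    Lineage,
    Pedigree,
    Qualifier,
    Relationship,
    Sex,
    degree_of,
    generation_of,
    relabel,
    reroot_with_origin,
)

__all__ = [
    "EngineConfig",
    "Criterion",
    "CriterionEvent",
    "RiskReport",
    "NormalizationError",
    "RECOMMENDATION_TEXT",
    "evaluate",
    "evaluate_brca",
    "evaluate_lynch",
    "evaluate_polyposis",
    "meets_amsterdam_ii",
    "criterion_registry",
]

RECOMMENDATION_TEXT = "genetic screening should be considered at this time"

R = Relationship
L = Lineage


class NormalizationError(ValueError):
    """Input carries un-normalized content; run the normalize module first."""


@dataclass(frozen=True)
class EngineConfig:
    """Tunable engine parameters.

    ``brca_ages_inclusive`` applies the BRCA breast-age bounds as <= (the
    guideline reading "diagnosed at or under"); the Lynch/Amsterdam bound stays
    strict regardless.  ``polyp_threshold`` is the cumulative adenoma count for
    the polyposis rules.  ``limited_family_threshold`` is the per-side relative
    count (beyond parents) below which a family history counts as limited.
    """

    brca_age_young: int = 45
    brca_age_mid: int = 50
    brca_age_tnbc: int = 60
    brca_ages_inclusive: bool = True
    lynch_age: int = 50
    polyp_threshold: int = 10
    limited_family_threshold: int = 2


DEFAULT_CONFIG = EngineConfig()


@dataclass(frozen=True)
class CriterionEvent:
    """One fulfilled criterion: the unit of the validation analysis.

    ``contributing`` holds kinship labels (serialized); ``members`` carries
    the actual member objects where the evaluator tracked them, so duplicate
    labels (two affected maternal aunts, say) stay distinguishable.
    """

    criterion_id: str
    syndrome: str  # BRCA | LYNCH | POLYPOSIS
    contributing: tuple[Relationship, ...]
    index_person: Relationship = Relationship.SELF
    side: Optional[str] = None
    sub_criterion: Optional[str] = None
    members: tuple = field(default=(), repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "criterion_id": self.criterion_id,
            "syndrome": self.syndrome,
            "contributing": [c.value for c in self.contributing],
            "index_person": self.index_person.value,
            "side": self.side,
            "sub_criterion": self.sub_criterion,
        }


@dataclass(frozen=True)
class Criterion:
    """Registry entry: stable id, syndrome, printed rule text, parameters."""

    id: str
    syndrome: str
    description: str
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RiskReport:
    meets_any: bool
    events: tuple[CriterionEvent, ...]

    @property
    def per_syndrome(self) -> dict[str, tuple[CriterionEvent, ...]]:
        out: dict[str, tuple[CriterionEvent, ...]] = {}
        for ev in self.events:
            out.setdefault(ev.syndrome, ())
            out[ev.syndrome] = out[ev.syndrome] + (ev,)
        return out

    @property
    def recommendation_text(self) -> str:
        return RECOMMENDATION_TEXT if self.meets_any else ""

    def to_dict(self) -> dict:
        return {
            "meets_any": self.meets_any,
            "recommendation_text": self.recommendation_text,
            "events": [ev.to_dict() for ev in self.events],
        }


# --------------------------------------------------------------------------
# registry metadata (descriptions shipped as versioned data)
# --------------------------------------------------------------------------

_REGISTRY: Optional[dict[str, Criterion]] = None


def criterion_registry() -> dict[str, Criterion]:
    """The versioned rule registry (id -> metadata)."""
    global _REGISTRY
    if _REGISTRY is None:
        text = resources.files("hcscreen.data").joinpath("criteria_v2_2017.yaml").read_text()
        doc = yaml.safe_load(text)
        _REGISTRY = {
            row["id"]: Criterion(
                id=row["id"],
                syndrome=row["syndrome"],
                description=row["description"],
                parameters=row.get("parameters", {}),
            )
            for row in doc["criteria"]
        }
    return _REGISTRY


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _imputed(dx) -> Optional[int]:
    try:
        return nz.impute_age(dx.age)
    except nz.UnknownAgeError:
        return None


def _le(age: Optional[int], bound: int, inclusive: bool) -> bool:
    if age is None:
        return False
    return age <= bound if inclusive else age < bound


def _breast(dx) -> bool:
    return dx.cancer_type == "breast"


def _member_has(member: FamilyMember, pred) -> bool:
    return any(pred(dx) for dx in member.diagnoses)


def _side_ok(member: FamilyMember, side: Lineage) -> bool:
    return member.lineage in (side, L.BOTH)


def _sided_group(members, pred, min_count: int):
    """First side (maternal, then paternal) holding >= min_count distinct
    relatives satisfying ``pred``; returns (side, chosen members) or None."""
    for side in (L.MATERNAL, L.PATERNAL):
        chosen = [m for m in members if _side_ok(m, side) and _member_has(m, pred)]
        if len(chosen) >= min_count:
            return side, chosen[:min_count]
    return None


def _limited_family_history(p: Pedigree, cfg: EngineConfig) -> bool:
    """Unknown or limited family structure: fewer than the threshold number of
    reported relatives beyond the parents on each side, and no declared family
    size reaching the threshold."""
    for side, key in ((L.MATERNAL, "maternal"), (L.PATERNAL, "paternal")):
        reported = sum(
            1
            for m in p.members
            if _side_ok(m, side) and m.relationship not in (R.MOTHER, R.FATHER)
        )
        declared = (p.family_sizes or {}).get(key, 0)
        if max(reported, declared) >= cfg.limited_family_threshold:
            return False
    return True


def _check_normalized(p: Pedigree) -> None:
    vocab = nz.default_vocabulary().canonical_types
    for person in p.everyone():
        for dx in person.diagnoses:
            if dx.cancer_type not in vocab:
                raise NormalizationError(
                    f"cancer type {dx.cancer_type!r} is not canonical; "
                    "run normalize.normalize_cancer first"
                )


# --------------------------------------------------------------------------
# BRCA-related criteria
# --------------------------------------------------------------------------


def _family_pattern_b16(p: Pedigree, cfg: EngineConfig):
    """Supporting family pattern shared by the prostate/pancreatic clauses:
    one relative with ovarian carcinoma at any age, or one with breast <= 50,
    or two same-side relatives with breast/pancreatic/prostate at any age."""
    inc = cfg.brca_ages_inclusive
    for m in p.members:
        if _member_has(m, lambda d: nz.is_ovarian_equivalent(d.cancer_type)):
            return [m], None
    for m in p.members:
        if _member_has(m, lambda d: _breast(d) and _le(_imputed(d), cfg.brca_age_mid, inc)):
            return [m], None
    pair = _sided_group(
        p.members,
        lambda d: d.cancer_type in ("breast", "pancreatic", "prostate"),
        2,
    )
    if pair:
        side, chosen = pair
        return chosen, side.value
    return None


def _personal_brca_events(
    p: Pedigree, cfg: EngineConfig, mirrored: bool = False
) -> list[CriterionEvent]:
    """B2-B17 with the pedigree's proband as index person.

    The limited-family-history clause (B7) is anchored to the respondent: the
    tool records family structure for the proband only, so B7 is skipped in
    mirrored (re-rooted) evaluation.
    """
    inc = cfg.brca_ages_inclusive
    pro = p.proband
    events: list[CriterionEvent] = []

    breast_dx = [d for d in pro.diagnoses if _breast(d)]
    has_breast = bool(breast_dx)
    breast_young = any(_le(_imputed(d), cfg.brca_age_young, inc) for d in breast_dx)
    breast_mid = any(_le(_imputed(d), cfg.brca_age_mid, inc) for d in breast_dx)

    def ev(cid: str, support=(), side=None) -> CriterionEvent:
        return CriterionEvent(
            criterion_id=cid,
            syndrome="BRCA",
            contributing=(R.SELF,) + tuple(m.relationship for m in support),
            side=side,
            members=tuple(support),
        )

    if breast_young:
        events.append(ev("B2"))
    if breast_mid and len(breast_dx) >= 2:
        events.append(ev("B3"))
    if breast_mid:
        for cid, type_pred in (
            ("B4", _breast),
            ("B5", lambda d: d.cancer_type == "pancreatic"),
            ("B6", lambda d: d.cancer_type == "prostate"),
        ):
            hit = next((m for m in p.members if _member_has(m, type_pred)), None)
            if hit is not None:
                events.append(ev(cid, [hit]))
        if not mirrored and _limited_family_history(p, cfg):
            events.append(ev("B7"))
    if any(
        Qualifier.TRIPLE_NEGATIVE in d.qualifiers and _le(_imputed(d), cfg.brca_age_tnbc, inc)
        for d in breast_dx
    ):
        events.append(ev("B8"))
    if has_breast:
        pair = _sided_group(
            p.members, lambda d: d.cancer_type in ("breast", "pancreatic", "prostate"), 2
        )
        if pair:
            side, chosen = pair
            events.append(ev("B9", chosen, side.value))
        hit = next(
            (
                m
                for m in p.members
                if _member_has(m, lambda d: _breast(d) and _le(_imputed(d), cfg.brca_age_mid, inc))
            ),
            None,
        )
        if hit is not None:
            events.append(ev("B10", [hit]))
        hit = next(
            (m for m in p.members if _member_has(m, lambda d: nz.is_ovarian_equivalent(d.cancer_type))),
            None,
        )
        if hit is not None:
            events.append(ev("B11", [hit]))
        hit = next(
            (m for m in p.members if m.sex is Sex.MALE and _member_has(m, _breast)),
            None,
        )
        if hit is not None:
            events.append(ev("B12", [hit]))
        if Ethnicity.ASHKENAZI_JEWISH in pro.ethnicities:
            events.append(ev("B13"))
    if any(nz.is_ovarian_equivalent(d.cancer_type) for d in pro.diagnoses):
        events.append(ev("B14"))
    if pro.sex is Sex.MALE and has_breast:
        events.append(ev("B15"))
    for cid, personal in (
        ("B16", lambda d: d.cancer_type == "prostate" and Qualifier.GLEASON_GT7 in d.qualifiers),
        ("B17", lambda d: d.cancer_type == "pancreatic"),
    ):
        if any(personal(d) for d in pro.diagnoses):
            pattern = _family_pattern_b16(p, cfg)
            if pattern:
                support, side = pattern
                events.append(ev(cid, support, side))
    return events


def _b19_events(p: Pedigree, cfg: EngineConfig) -> list[CriterionEvent]:
    """Third-degree relative with breast/ovarian plus >= 2 of *their* close
    blood relatives with breast (>= 1 at/under 50) and/or ovarian carcinoma."""
    inc = cfg.brca_ages_inclusive

    def b_or_ov(d) -> bool:
        return _breast(d) or nz.is_ovarian_equivalent(d.cancer_type)

    def anchors(person) -> bool:
        # the clause's "at least one" relative: breast at/under 50, or ovarian
        return _member_has(
            person,
            lambda d: (_breast(d) and _le(_imputed(d), cfg.brca_age_mid, inc))
            or nz.is_ovarian_equivalent(d.cancer_type),
        )

    events = []
    for t in p.members:
        if t.degree != 3 or not _member_has(t, b_or_ov):
            continue
        t_side = t.lineage
        supporters = [
            x
            for x in p.everyone()
            if x is not t
            and (x.relationship is R.SELF or _side_ok(x, t_side))
            and _member_has(x, b_or_ov)
        ]
        if len(supporters) < 2 or not any(anchors(x) for x in supporters):
            continue
        anchor = next(x for x in supporters if anchors(x))
        other = next(x for x in supporters if x is not anchor)
        events.append(
            CriterionEvent(
                criterion_id="B19",
                syndrome="BRCA",
                contributing=(t.relationship, anchor.relationship, other.relationship),
                index_person=t.relationship,
                side=t_side.value,
            )
        )
    return events


def evaluate_brca(
    p: Pedigree, config: EngineConfig = DEFAULT_CONFIG
) -> list[CriterionEvent]:
    """All fulfilled BRCA-related criteria (B1-B19)."""
    _check_normalized(p)
    events: list[CriterionEvent] = []
    for mut in p.mutations:
        if mut.gene_group is GeneGroup.BRCA1_BRCA2:
            events.append(
                CriterionEvent("B1", "BRCA", (mut.carrier,), index_person=mut.carrier)
            )
            break
    events.extend(_personal_brca_events(p, config))
    # family-history mirroring: any FDR/SDR as index for B2-B17
    for member in p.members:
        if member.degree not in (1, 2):
            continue
        if not member.diagnoses:
            continue  # B2-B17 all require a personal history at the index
        rp, origin = reroot_with_origin(p, member)
        for sub in _personal_brca_events(rp, config, mirrored=True):
            contributing = [member.relationship]
            for mo in sub.members:
                orig = origin.get(id(mo))
                if orig is not None:
                    contributing.append(orig)
            events.append(
                CriterionEvent(
                    criterion_id="B18",
                    syndrome="BRCA",
                    contributing=tuple(contributing),
                    index_person=member.relationship,
                    side=sub.side,
                    sub_criterion=sub.criterion_id,
                )
            )
    events.extend(_b19_events(p, config))
    return events


# --------------------------------------------------------------------------
# Lynch syndrome criteria
# --------------------------------------------------------------------------


def evaluate_lynch(
    p: Pedigree, config: EngineConfig = DEFAULT_CONFIG
) -> list[CriterionEvent]:
    """All fulfilled Lynch-syndrome criteria (L1-L6)."""
    _check_normalized(p)
    cfg = config
    events: list[CriterionEvent] = []

    def ev(cid, contributing, side=None, index=R.SELF):
        return CriterionEvent(cid, "LYNCH", tuple(contributing), index_person=index, side=side)

    for mut in p.mutations:
        if mut.gene_group is GeneGroup.LYNCH:
            events.append(ev("L1", [mut.carrier], index=mut.carrier))
            break

    crc_endo = nz.is_colorectal_or_endometrial
    fdrs = [m for m in p.members if m.degree == 1]

    hit = next(
        (
            m
            for m in fdrs
            if _member_has(
                m, lambda d: crc_endo(d.cancer_type) and _le(_imputed(d), cfg.lynch_age, False)
            )
        ),
        None,
    )
    if hit is not None:
        events.append(ev("L2", [hit.relationship], index=hit.relationship))

    for m in fdrs:
        ls_dx = [d for d in m.diagnoses if nz.is_ls_related(d.cancer_type)]
        if len(ls_dx) >= 2 and any(crc_endo(d.cancer_type) for d in ls_dx):
            flagged = any(
                d.qualifiers & {Qualifier.SYNCHRONOUS, Qualifier.METACHRONOUS} for d in ls_dx
            )
            # two LS-related primaries qualify at any interval; explicit
            # synchronous/metachronous flags are accepted but not required
            del flagged
            events.append(ev("L3", [m.relationship], index=m.relationship))
            break

    ls_pred = lambda d: nz.is_ls_related(d.cancer_type)  # noqa: E731
    fdr_sdr = [m for m in p.members if m.degree in (1, 2)]
    for side in (L.MATERNAL, L.PATERNAL):
        group = [m for m in fdr_sdr if _side_ok(m, side) and _member_has(m, ls_pred)]
        young = [
            m
            for m in group
            if _member_has(
                m, lambda d: ls_pred(d) and _le(_imputed(d), cfg.lynch_age, False)
            )
        ]
        if len(group) >= 2 and young:
            others = [m for m in group if m is not young[0]]
            events.append(
                ev("L4", [young[0].relationship, others[0].relationship], side=side.value)
            )
            break
    for side in (L.MATERNAL, L.PATERNAL):
        group = [m for m in fdr_sdr if _side_ok(m, side) and _member_has(m, ls_pred)]
        if len(group) >= 3:
            events.append(ev("L5", [m.relationship for m in group[:3]], side=side.value))
            break

    amsterdam = meets_amsterdam_ii(p, config)
    if amsterdam[0]:
        events.append(ev("L6", amsterdam[1]))
    return events


def _pairwise_degree(a: Relationship, b: Relationship) -> Optional[int]:
    """Consanguinity degree between two labeled positions, where derivable."""
    if a == b:
        return 0
    if a is R.SELF:
        return degree_of(b)
    if b is R.SELF:
        return degree_of(a)
    if degree_of(a) in (1, 2):
        lbl = relabel(a, b)
        if lbl is not None:
            return degree_of(lbl)
    if degree_of(b) in (1, 2):
        lbl = relabel(b, a)
        if lbl is not None:
            return degree_of(lbl)
    return None


def meets_amsterdam_ii(
    p: Pedigree, config: EngineConfig = DEFAULT_CONFIG
) -> tuple[bool, tuple[Relationship, ...]]:
    """Amsterdam II family criteria.

    >= 3 relatives (the proband may be one) with Amsterdam-list cancers
    (colorectal, endometrial, small intestine, ureter/renal pelvis), one a
    first-degree relative of the other two, >= 2 successive generations
    affected, >= 1 diagnosis before age 50; all on one family line.
    """
    amst = lambda d: d.cancer_type in nz.AMSTERDAM_CANCERS  # noqa: E731
    affected = [x for x in p.everyone() if _member_has(x, amst)]
    if len(affected) < 3:
        return False, ()
    from itertools import combinations

    for trio in combinations(affected, 3):
        labels = [x.relationship for x in trio]
        # one person is an FDR of the other two
        if not any(
            all(
                _pairwise_degree(labels[i], labels[j]) == 1
                for j in range(3)
                if j != i
            )
            for i in range(3)
        ):
            continue
        # single family line: all lineages compatible with one side
        if not any(
            all(x.relationship is R.SELF or _side_ok(x, side) for x in trio)
            for side in (L.MATERNAL, L.PATERNAL)
        ):
            continue
        gens = {generation_of(x.relationship) for x in trio}
        if not any(g + 1 in gens for g in gens):
            continue  # need two successive generations affected
        if not any(
            _member_has(x, lambda d: amst(d) and _le(_imputed(d), config.lynch_age, False))
            for x in trio
        ):
            continue
        return True, tuple(labels)
    return False, ()


# --------------------------------------------------------------------------
# polyposis criteria
# --------------------------------------------------------------------------


def evaluate_polyposis(
    p: Pedigree, config: EngineConfig = DEFAULT_CONFIG
) -> list[CriterionEvent]:
    """Polyposis rules (P1-P3): known APC/MUTYH mutation, or a cumulative
    adenoma burden at/over the threshold in the proband or a first-degree
    relative."""
    _check_normalized(p)
    events: list[CriterionEvent] = []
    for mut in p.mutations:
        if mut.gene_group is GeneGroup.APC_MUTYH:
            events.append(
                CriterionEvent("P1", "POLYPOSIS", (mut.carrier,), index_person=mut.carrier)
            )
            break
    if (p.proband.polyp_count or 0) >= config.polyp_threshold:
        events.append(CriterionEvent("P2", "POLYPOSIS", (R.SELF,)))
    hit = next(
        (
            m
            for m in p.members
            if m.degree == 1 and (m.polyp_count or 0) >= config.polyp_threshold
        ),
        None,
    )
    if hit is not None:
        events.append(
            CriterionEvent("P3", "POLYPOSIS", (hit.relationship,), index_person=hit.relationship)
        )
    return events


# --------------------------------------------------------------------------
# top level
# --------------------------------------------------------------------------


def evaluate(p: Pedigree, config: EngineConfig = DEFAULT_CONFIG) -> RiskReport:
    """Evaluate a pedigree against every registered criterion.

    Pure and deterministic; reports all fulfilled criteria, not the first
    match.
    """
    events = (
        evaluate_brca(p, config)
        + evaluate_lynch(p, config)
        + evaluate_polyposis(p, config)
    )
    return RiskReport(meets_any=bool(events), events=tuple(events))
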