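"""Brute-force clause-enumeration oracle.

Re-derives the fulfilled-criterion set by literal enumeration: every counting
clause is evaluated by enumerating relative subsets with itertools and
checking side compatibility explicitly, and every mirrored clause by
re-rooting at each candidate index and re-running the literal personal
clauses.  The kinship label algebra (degree/lineage tables, re-rooting) is
shared with the package — it is the published semantics of the labels — but
all clause logic here is independent of the engine's.
"""

from __future__ import annotations

from itertools import combinations

from hcscreen.criteria import EngineConfig, DEFAULT_CONFIG
from hcscreen.normalize import (
    AMSTERDAM_CANCERS,
    LS_RELATED,
    OVARIAN_EQUIVALENTS,
    UnknownAgeError,
    impute_age,
)
from hcscreen.pedigree import (
    Ethnicity,
    GeneGroup,
    Lineage,
    Pedigree,
    Qualifier,
    Relationship,
    Sex,
    degree_of,
    generation_of,
    relabel,
    reroot,
)

R = Relationship


def _age(d):
    try:
        return impute_age(d.age)
    except UnknownAgeError:
        return None


def _has(person, pred) -> bool:
    return any(pred(d) for d in person.diagnoses)


def _subset_on_one_side(members) -> bool:
    for side in (Lineage.MATERNAL, Lineage.PATERNAL):
        if all(m.lineage in (side, Lineage.BOTH) for m in members):
            return True
    return False


def _exists_sided_subset(members, pred, k) -> bool:
    qualifying = [m for m in members if _has(m, pred)]
    return any(
        _subset_on_one_side(combo) for combo in combinations(qualifying, k)
    )


def _personal_clauses(p: Pedigree, cfg: EngineConfig, mirrored: bool = False) -> set[str]:
    """Literal evaluation of the personal-history clauses B2-B17 with the
    pedigree's proband as index.  The limited-family clause is
    proband-anchored and never mirrored."""
    pro = p.proband
    rel = p.members
    hi = cfg.brca_ages_inclusive

    def le(a, bound):
        return a is not None and (a <= bound if hi else a < bound)

    breast = [d for d in pro.diagnoses if d.cancer_type == "breast"]
    out: set[str] = set()
    if any(le(_age(d), cfg.brca_age_young) for d in breast):
        out.add("B2")
    if any(le(_age(d), cfg.brca_age_mid) for d in breast) and len(breast) >= 2:
        out.add("B3")
    if any(le(_age(d), cfg.brca_age_mid) for d in breast):
        if any(_has(m, lambda d: d.cancer_type == "breast") for m in rel):
            out.add("B4")
        if any(_has(m, lambda d: d.cancer_type == "pancreatic") for m in rel):
            out.add("B5")
        if any(_has(m, lambda d: d.cancer_type == "prostate") for m in rel):
            out.add("B6")
        if not mirrored and _limited(p, cfg):
            out.add("B7")
    if any(
        Qualifier.TRIPLE_NEGATIVE in d.qualifiers and le(_age(d), cfg.brca_age_tnbc)
        for d in breast
    ):
        out.add("B8")
    if breast:
        if _exists_sided_subset(
            rel, lambda d: d.cancer_type in ("breast", "pancreatic", "prostate"), 2
        ):
            out.add("B9")
        if any(
            _has(m, lambda d: d.cancer_type == "breast" and le(_age(d), cfg.brca_age_mid))
            for m in rel
        ):
            out.add("B10")
        if any(_has(m, lambda d: d.cancer_type in OVARIAN_EQUIVALENTS) for m in rel):
            out.add("B11")
        if any(
            m.sex is Sex.MALE and _has(m, lambda d: d.cancer_type == "breast") for m in rel
        ):
            out.add("B12")
        if Ethnicity.ASHKENAZI_JEWISH in pro.ethnicities:
            out.add("B13")
    if _has(pro, lambda d: d.cancer_type in OVARIAN_EQUIVALENTS):
        out.add("B14")
    if pro.sex is Sex.MALE and breast:
        out.add("B15")
    pattern = (
        any(_has(m, lambda d: d.cancer_type in OVARIAN_EQUIVALENTS) for m in rel)
        or any(
            _has(m, lambda d: d.cancer_type == "breast" and le(_age(d), cfg.brca_age_mid))
            for m in rel
        )
        or _exists_sided_subset(
            rel, lambda d: d.cancer_type in ("breast", "pancreatic", "prostate"), 2
        )
    )
    if (
        _has(
            pro,
            lambda d: d.cancer_type == "prostate" and Qualifier.GLEASON_GT7 in d.qualifiers,
        )
        and pattern
    ):
        out.add("B16")
    if _has(pro, lambda d: d.cancer_type == "pancreatic") and pattern:
        out.add("B17")
    return out


def _limited(p: Pedigree, cfg: EngineConfig) -> bool:
    for side, key in ((Lineage.MATERNAL, "maternal"), (Lineage.PATERNAL, "paternal")):
        n = sum(
            1
            for m in p.members
            if m.lineage in (side, Lineage.BOTH)
            and m.relationship not in (R.MOTHER, R.FATHER)
        )
        declared = (p.family_sizes or {}).get(key, 0)
        if max(n, declared) >= cfg.limited_family_threshold:
            return False
    return True


def _pair_degree(a: Relationship, b: Relationship):
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


def oracle_criteria(p: Pedigree, cfg: EngineConfig = DEFAULT_CONFIG) -> set[str]:
    """The full fulfilled-criterion id set by literal enumeration."""
    out: set[str] = set()

    # known-mutation rules
    for mut in p.mutations:
        out.add(
            {GeneGroup.BRCA1_BRCA2: "B1", GeneGroup.LYNCH: "L1", GeneGroup.APC_MUTYH: "P1"}[
                mut.gene_group
            ]
        )

    out |= _personal_clauses(p, cfg)

    # mirrored personal clauses at every first/second-degree relative
    for m in p.members:
        if degree_of(m.relationship) in (1, 2) and m.diagnoses:
            if _personal_clauses(reroot(p, m), cfg, mirrored=True):
                out.add("B18")

    # third-degree relative with breast/ovarian plus two supporting relatives
    for t in p.members:
        if degree_of(t.relationship) != 3:
            continue
        if not _has(t, lambda d: d.cancer_type == "breast" or d.cancer_type in OVARIAN_EQUIVALENTS):
            continue
        others = [
            x
            for x in [p.proband] + p.members
            if x is not t
            and (
                x.relationship is R.SELF
                or x.lineage in (t.lineage, Lineage.BOTH)
            )
            and _has(
                x, lambda d: d.cancer_type == "breast" or d.cancer_type in OVARIAN_EQUIVALENTS
            )
        ]
        anchor = lambda x: _has(  # noqa: E731
            x,
            lambda d: (
                d.cancer_type == "breast"
                and _age(d) is not None
                and (
                    _age(d) <= cfg.brca_age_mid
                    if cfg.brca_ages_inclusive
                    else _age(d) < cfg.brca_age_mid
                )
            )
            or d.cancer_type in OVARIAN_EQUIVALENTS,
        )
        if len(others) >= 2 and any(anchor(x) for x in others):
            out.add("B19")

    # Lynch family-history clauses
    fdr = [m for m in p.members if degree_of(m.relationship) == 1]
    fdr_sdr = [m for m in p.members if degree_of(m.relationship) in (1, 2)]
    crc_endo = lambda d: d.cancer_type in ("colon", "uterine_endometrial")  # noqa: E731
    ls = lambda d: d.cancer_type in LS_RELATED  # noqa: E731
    if any(
        _has(m, lambda d: crc_endo(d) and _age(d) is not None and _age(d) < cfg.lynch_age)
        for m in fdr
    ):
        out.add("L2")
    for m in fdr:
        ls_dx = [d for d in m.diagnoses if ls(d)]
        if len(ls_dx) >= 2 and any(crc_endo(d) for d in ls_dx):
            out.add("L3")
    ls_members = [m for m in fdr_sdr if _has(m, ls)]
    for combo in combinations(ls_members, 2):
        if _subset_on_one_side(combo) and any(
            _has(m, lambda d: ls(d) and _age(d) is not None and _age(d) < cfg.lynch_age)
            for m in combo
        ):
            out.add("L4")
            break
    for combo in combinations(ls_members, 3):
        if _subset_on_one_side(combo):
            out.add("L5")
            break

    # Amsterdam II
    amst = lambda d: d.cancer_type in AMSTERDAM_CANCERS  # noqa: E731
    affected = [x for x in [p.proband] + p.members if _has(x, amst)]
    for trio in combinations(affected, 3):
        if not any(
            all(
                _pair_degree(trio[i].relationship, trio[j].relationship) == 1
                for j in range(3)
                if j != i
            )
            for i in range(3)
        ):
            continue
        if not any(
            all(
                x.relationship is R.SELF or x.lineage in (side, Lineage.BOTH)
                for x in trio
            )
            for side in (Lineage.MATERNAL, Lineage.PATERNAL)
        ):
            continue
        gens = {generation_of(x.relationship) for x in trio}
        if not any(g + 1 in gens for g in gens):
            continue
        if not any(
            _has(x, lambda d: amst(d) and _age(d) is not None and _age(d) < cfg.lynch_age)
            for x in trio
        ):
            continue
        out.add("L6")
        break

    # polyposis counts
    if (p.proband.polyp_count or 0) >= cfg.polyp_threshold:
        out.add("P2")
    if any(
        degree_of(m.relationship) == 1 and (m.polyp_count or 0) >= cfg.polyp_threshold
        for m in p.members
    ):
        out.add("P3")
    return out
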