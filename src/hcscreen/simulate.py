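"""Seeded synthetic pedigree and cohort generator.

Emulates the study design end to end with no external data: three-generation
family structures, background (sporadic) cancer histories with realistic
age-at-diagnosis distributions, imprecise-age masking, and named high-risk
*motifs* — the qualifying configurations that make a history meet criteria
(early breast cancer, a same-side breast cluster, ovarian carcinoma, male
breast cancer, breast cancer on an Ashkenazi background, a young colorectal/
endometrial first-degree relative, a Lynch-related cancer cluster, a known
familial mutation).

High-risk pedigrees are background + one sampled motif, verified against the
engine; low-risk pedigrees are background passed through ``model_low_risk`` so
nothing fires.  Gold labels therefore come from the same criteria semantics
the engine implements: the simulator validates pipeline plumbing, while
criteria correctness is established separately by the brute-force oracle and
hand-checked worked examples.

Everything is driven by a mandatory seed; identical (seed, config) pairs give
identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .criteria import DEFAULT_CONFIG, EngineConfig, evaluate
from .events import (
    IndependentEvent,
    extract_high_risk_events,
    extract_low_risk_events,
    model_low_risk,
    predict_event,
)
from .pedigree import (
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

__all__ = [
    "SimConfig",
    "Cohort",
    "CohortEntry",
    "default_config",
    "generate_pedigree",
    "generate_cohort",
    "perturb_pedigree",
    "InfeasibleConfigError",
]

R = Relationship


class InfeasibleConfigError(RuntimeError):
    """The retry budget was exhausted without producing a valid pedigree."""


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``baseline_incidence`` is the per-relative probability of each sporadic
    tumor type; ``age_dist`` gives per-type (mean, sd, lower, upper) truncated
    normals for age at diagnosis in years.  ``age_mask_frac`` is the fraction
    of relatives' ages recorded imprecisely (as early/late/whole decades), as
    real pedigrees do.  ``motif_weights`` set the mix of qualifying high-risk
    configurations; ``proband_motif_frac`` is the chance the motif lands on
    the proband where it can (matching the minority of probands with a
    personal history).
    """

    baseline_incidence: dict[str, float] = field(
        default_factory=lambda: {
            "breast": 0.034,
            "lung": 0.026,
            "colon": 0.022,
            "prostate": 0.045,  # male relatives only
            "melanoma": 0.015,
            "skin_unspecified": 0.019,
            "leukemia": 0.009,
            "cervical": 0.008,  # female relatives only
            "cns_brain": 0.006,
            "stomach": 0.006,
            "pancreatic": 0.009,
            "renal": 0.005,
            "bladder": 0.005,
            "thyroid": 0.008,
            "uterine_endometrial": 0.005,
            "non_hodgkin_lymphoma": 0.005,
            "other_unspecified": 0.011,
        }
    )
    age_dist: dict[str, tuple[float, float, int, int]] = field(
        default_factory=lambda: {
            "breast": (64.0, 8.0, 51, 90),
            "lung": (68.0, 8.0, 50, 90),
            "colon": (68.0, 9.0, 50, 92),
            "prostate": (71.0, 7.0, 55, 92),
            "melanoma": (58.0, 12.0, 35, 90),
            "skin_unspecified": (62.0, 12.0, 35, 92),
            "leukemia": (55.0, 15.0, 20, 88),
            "cervical": (45.0, 10.0, 25, 70),
            "cns_brain": (60.0, 12.0, 35, 85),
            "stomach": (66.0, 10.0, 50, 90),
            "pancreatic": (68.0, 8.0, 51, 88),
            "renal": (63.0, 10.0, 45, 88),
            "bladder": (68.0, 9.0, 50, 90),
            "thyroid": (48.0, 12.0, 25, 80),
            "uterine_endometrial": (64.0, 8.0, 51, 85),
            "non_hodgkin_lymphoma": (60.0, 13.0, 30, 88),
            "other_unspecified": (64.0, 11.0, 40, 90),
        }
    )
    ethnicity_freqs: dict[Ethnicity, float] = field(
        default_factory=lambda: {
            Ethnicity.CAUCASIAN: 0.745,
            Ethnicity.ASHKENAZI_JEWISH: 0.075,
            Ethnicity.AFRICAN_AMERICAN: 0.053,
            Ethnicity.ASIAN: 0.041,
            Ethnicity.HISPANIC: 0.047,
            Ethnicity.NATIVE_AMERICAN: 0.022,
            Ethnicity.UNKNOWN: 0.017,
        }
    )
    motif_weights: dict[str, float] = field(
        default_factory=lambda: {
            "early_breast": 0.28,
            "breast_cluster": 0.17,
            "ovarian": 0.27,
            "male_breast": 0.01,
            "ashkenazi_breast": 0.05,
            "lynch_fdr_young": 0.05,
            "lynch_cluster": 0.13,
            "known_mutation": 0.04,
        }
    )
    polyp_incidence: float = 0.0
    age_mask_frac: float = 0.25
    proband_motif_frac: float = 0.28
    proband_age_range: tuple[int, int] = (25, 70)
    mean_siblings: float = 1.3
    mean_aunts_uncles: float = 1.6
    mean_cousins: float = 0.7
    max_retries: int = 40

    def validate(self) -> None:
        for name, p in list(self.baseline_incidence.items()) + [
            ("polyp_incidence", self.polyp_incidence),
            ("age_mask_frac", self.age_mask_frac),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range for {name}: {p}")
        if not self.motif_weights or min(self.motif_weights.values()) < 0:
            raise ValueError("motif weights must be non-negative and non-empty")


def default_config() -> SimConfig:
    return SimConfig()


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

_FEMALE_ONLY = {"breast", "cervical", "ovarian", "uterine_endometrial"}
_MALE_ONLY = {"prostate"}


def _trunc_normal_age(rng: np.random.Generator, dist) -> int:
    mean, sd, lo, hi = dist
    for _ in range(100):
        a = int(round(rng.normal(mean, sd)))
        if lo <= a <= hi:
            return a
    return int(np.clip(round(mean), lo, hi))


def _mask_age(rng: np.random.Generator, years: int, frac: float) -> AgeRecord:
    if rng.random() >= frac:
        return AgeRecord.exact(years)
    decade = (years // 10) * 10
    kind = _pick(rng, (AgeKind.EARLY_DECADE, AgeKind.LATE_DECADE, AgeKind.DECADE))
    return AgeRecord(kind=kind, value=decade)


def _family_structure(rng: np.random.Generator, cfg: SimConfig) -> list[FamilyMember]:
    members: list[FamilyMember] = [
        FamilyMember(relationship=R.MOTHER),
        FamilyMember(relationship=R.FATHER),
        FamilyMember(relationship=R.MATERNAL_GRANDMOTHER),
        FamilyMember(relationship=R.MATERNAL_GRANDFATHER),
        FamilyMember(relationship=R.PATERNAL_GRANDMOTHER),
        FamilyMember(relationship=R.PATERNAL_GRANDFATHER),
    ]
    for _ in range(rng.poisson(cfg.mean_siblings)):
        members.append(
            FamilyMember(relationship=R.SISTER if rng.random() < 0.5 else R.BROTHER)
        )
    for side_aunt, side_uncle in (
        (R.MATERNAL_AUNT, R.MATERNAL_UNCLE),
        (R.PATERNAL_AUNT, R.PATERNAL_UNCLE),
    ):
        for _ in range(rng.poisson(cfg.mean_aunts_uncles)):
            members.append(
                FamilyMember(relationship=side_aunt if rng.random() < 0.5 else side_uncle)
            )
    for cousin in (R.MATERNAL_FIRST_COUSIN, R.PATERNAL_FIRST_COUSIN):
        for _ in range(rng.poisson(cfg.mean_cousins)):
            members.append(
                FamilyMember(
                    relationship=cousin,
                    sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                )
            )
    return members


def _sample_background(
    rng: np.random.Generator, cfg: SimConfig, person: FamilyMember
) -> None:
    for cancer_type, p in cfg.baseline_incidence.items():
        if cancer_type in _FEMALE_ONLY and person.sex is Sex.MALE:
            continue
        if cancer_type in _MALE_ONLY and person.sex is not Sex.MALE:
            continue
        if rng.random() < p:
            years = _trunc_normal_age(rng, cfg.age_dist[cancer_type])
            person.diagnoses.append(
                CancerDiagnosis(
                    cancer_type=cancer_type, age=_mask_age(rng, years, cfg.age_mask_frac)
                )
            )
    if cfg.polyp_incidence and rng.random() < cfg.polyp_incidence:
        person.polyp_count = int(rng.integers(1, 30))


def _base_pedigree(rng: np.random.Generator, cfg: SimConfig) -> Pedigree:
    eth_names = list(cfg.ethnicity_freqs)
    probs = np.array([cfg.ethnicity_freqs[e] for e in eth_names], dtype=float)
    probs = probs / probs.sum()
    ethnicity = eth_names[int(rng.choice(len(eth_names), p=probs))]
    proband = FamilyMember(
        relationship=R.SELF, sex=Sex.FEMALE, ethnicities=frozenset({ethnicity})
    )
    members = _family_structure(rng, cfg)
    for person in [proband] + members:
        _sample_background(rng, cfg, person)
    sides = {"maternal": 0, "paternal": 0}
    for m in members:
        if m.lineage.value in sides:
            sides[m.lineage.value] += 1
    return Pedigree(proband=proband, members=members, family_sizes=sides)


# --------------------------------------------------------------------------
# high-risk motifs
# --------------------------------------------------------------------------


def _add_dx(person: FamilyMember, cancer_type: str, years: int, *quals: Qualifier) -> None:
    person.diagnoses.append(
        CancerDiagnosis(
            cancer_type=cancer_type,
            age=AgeRecord.exact(years),
            qualifiers=frozenset(quals),
            primary_index=1 + sum(d.cancer_type == cancer_type for d in person.diagnoses),
        )
    )


def _pick(rng: np.random.Generator, options):
    """Uniform pick preserving element types (numpy choice would coerce
    str-enums to plain strings)."""
    return options[int(rng.integers(len(options)))]


def _ensure(p: Pedigree, label: Relationship) -> FamilyMember:
    for m in p.members:
        if m.relationship is label:
            return m
    m = FamilyMember(relationship=label)
    p.members.append(m)
    return m


_FEMALE_FDR_SDR = (
    R.MOTHER,
    R.SISTER,
    R.MATERNAL_GRANDMOTHER,
    R.PATERNAL_GRANDMOTHER,
    R.MATERNAL_AUNT,
    R.PATERNAL_AUNT,
)


def _apply_motif(rng: np.random.Generator, cfg: SimConfig, p: Pedigree, motif: str) -> None:
    on_proband = rng.random() < cfg.proband_motif_frac
    if motif == "early_breast":
        target = p.proband if on_proband else _ensure(p, _pick(rng, _FEMALE_FDR_SDR))
        _add_dx(target, "breast", int(rng.integers(32, 46)))
    elif motif == "breast_cluster":
        # a same-side breast cluster: grandmother plus two of her daughters
        if rng.random() < 0.5:
            gm, aunt = R.MATERNAL_GRANDMOTHER, R.MATERNAL_AUNT
        else:
            gm, aunt = R.PATERNAL_GRANDMOTHER, R.PATERNAL_AUNT
        _add_dx(_ensure(p, gm), "breast", int(rng.integers(50, 72)))
        _add_dx(_ensure(p, aunt), "breast", int(rng.integers(48, 70)))
        second_aunt = FamilyMember(relationship=aunt)
        _add_dx(second_aunt, "breast", int(rng.integers(48, 70)))
        p.members.append(second_aunt)
        if on_proband:
            _add_dx(p.proband, "breast", int(rng.integers(40, 60)))
    elif motif == "ovarian":
        target = p.proband if on_proband else _ensure(p, _pick(rng, _FEMALE_FDR_SDR))
        _add_dx(target, "ovarian", int(rng.integers(45, 72)))
    elif motif == "male_breast":
        target = _ensure(
            p, _pick(rng, (R.FATHER, R.BROTHER, R.MATERNAL_UNCLE, R.PATERNAL_UNCLE))
        )
        _add_dx(target, "breast", int(rng.integers(55, 78)))
    elif motif == "ashkenazi_breast":
        p.proband.ethnicities = p.proband.ethnicities | {Ethnicity.ASHKENAZI_JEWISH}
        target = p.proband if on_proband else _ensure(p, _pick(rng, _FEMALE_FDR_SDR))
        _add_dx(target, "breast", int(rng.integers(46, 72)))
    elif motif == "lynch_fdr_young":
        target = _ensure(p, _pick(rng, (R.MOTHER, R.FATHER, R.SISTER, R.BROTHER)))
        ctype = (
            "uterine_endometrial"
            if target.sex is Sex.FEMALE and rng.random() < 0.4
            else "colon"
        )
        _add_dx(target, ctype, int(rng.integers(38, 50)))
    elif motif == "lynch_cluster":
        if rng.random() < 0.5:
            labels = (R.MOTHER, R.MATERNAL_GRANDFATHER, R.MATERNAL_UNCLE)
        else:
            labels = (R.FATHER, R.PATERNAL_GRANDFATHER, R.PATERNAL_UNCLE)
        types = ["colon", "stomach", "colon"]
        for label, ctype in zip(labels, types):
            _add_dx(_ensure(p, label), ctype, int(rng.integers(52, 75)))
    elif motif == "known_mutation":
        gene = _pick(rng, (GeneGroup.BRCA1_BRCA2, GeneGroup.LYNCH))
        carrier = _pick(rng, (R.SELF, R.MOTHER, R.MATERNAL_AUNT, R.SISTER, R.PATERNAL_AUNT))
        p.mutations.append(MutationFinding(gene_group=gene, carrier=carrier))
    else:
        raise ValueError(f"unknown motif: {motif}")


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def generate_pedigree(
    config: SimConfig,
    role: str,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    engine_config: EngineConfig = DEFAULT_CONFIG,
) -> Pedigree:
    """One synthetic pedigree with a guaranteed risk label.

    ``role`` is ``"high_risk"`` (background + sampled motif, re-sampled until
    the engine confirms it fires) or ``"low_risk"`` (background passed through
    ``model_low_risk`` so nothing fires).
    """
    config.validate()
    if rng is None:
        if seed is None:
            raise ValueError("provide an rng or a seed: generation must be seeded")
        rng = np.random.default_rng(seed)
    if role not in ("high_risk", "low_risk"):
        raise ValueError(f"role must be high_risk or low_risk, got {role!r}")
    motifs = list(config.motif_weights)
    weights = np.array([config.motif_weights[m] for m in motifs], dtype=float)
    weights = weights / weights.sum()
    for _ in range(config.max_retries):
        p = _base_pedigree(rng, config)
        if role == "low_risk":
            p = model_low_risk(p, engine_config)
            if not evaluate(p, engine_config).meets_any:
                return p
            continue
        motif = motifs[int(rng.choice(len(motifs), p=weights))]
        _apply_motif(rng, config, p, motif)
        if evaluate(p, engine_config).meets_any:
            return p
    raise InfeasibleConfigError(f"retry budget exhausted for role {role!r}")


@dataclass(frozen=True)
class CohortEntry:
    pedigree_id: str
    pedigree: Pedigree
    gold_high: bool


@dataclass
class Cohort:
    """A labeled synthetic cohort plus its provenance (config, seed)."""

    entries: list[CohortEntry]
    config: SimConfig
    seed: int
    engine_config: EngineConfig = DEFAULT_CONFIG

    @property
    def pedigrees(self) -> list[Pedigree]:
        return [e.pedigree for e in self.entries]

    def events(self) -> list[tuple[IndependentEvent, bool]]:
        """All independent events with their gold (review) labels."""
        out: list[tuple[IndependentEvent, bool]] = []
        for e in self.entries:
            if e.gold_high:
                out.extend(
                    (ev, True) for ev in extract_high_risk_events(e.pedigree, self.engine_config)
                )
            else:
                out.extend(
                    (ev, False) for ev in extract_low_risk_events(e.pedigree, self.engine_config)
                )
        return out

    def predicted_labels(self) -> tuple[list[bool], list[bool]]:
        """(gold, predicted) per event, entering each event into the engine
        on its own — the concordance experiment."""
        gold: list[bool] = []
        pred: list[bool] = []
        by_id = {e.pedigree_id: e.pedigree for e in self.entries}
        for ev, label in self.events():
            gold.append(label)
            source = by_id.get(ev.source_pedigree_id or "")
            pred.append(predict_event(ev, source, self.engine_config))
        return gold, pred


def generate_cohort(
    config: SimConfig,
    n_high: int,
    n_low: int,
    seed: int,
    engine_config: EngineConfig = DEFAULT_CONFIG,
) -> Cohort:
    """A cohort of ``n_high`` high-risk and ``n_low`` low-risk pedigrees."""
    rng = np.random.default_rng(seed)
    entries: list[CohortEntry] = []
    for i in range(n_high):
        p = generate_pedigree(config, "high_risk", rng=rng, engine_config=engine_config)
        p.pedigree_id = f"H{i:04d}"
        entries.append(CohortEntry(p.pedigree_id, p, True))
    for i in range(n_low):
        p = generate_pedigree(config, "low_risk", rng=rng, engine_config=engine_config)
        p.pedigree_id = f"L{i:04d}"
        entries.append(CohortEntry(p.pedigree_id, p, False))
    return Cohort(entries=entries, config=config, seed=seed, engine_config=engine_config)


# --------------------------------------------------------------------------
# perturbation (the only sanctioned way to inject discordance)
# --------------------------------------------------------------------------


def perturb_pedigree(
    p: Pedigree,
    rng: np.random.Generator,
    age_jitter: int = 0,
    relabel_prob: float = 0.0,
) -> Pedigree:
    """Corrupt a pedigree the way transcription errors would: jitter exact
    ages by up to ``age_jitter`` years and relabel tumor types to
    ``other_unspecified`` with probability ``relabel_prob``.  Used to produce
    non-degenerate confusion matrices; the unperturbed pipeline is exactly
    concordant by construction."""
    q = p.model_copy(deep=True)
    for person in q.everyone():
        new_dx = []
        for dx in person.diagnoses:
            age = dx.age
            if age_jitter and age.kind is AgeKind.EXACT:
                shifted = int(np.clip(age.value + rng.integers(-age_jitter, age_jitter + 1), 0, 120))
                age = AgeRecord.exact(shifted)
            ctype = dx.cancer_type
            if relabel_prob and rng.random() < relabel_prob:
                ctype = "other_unspecified"
            new_dx.append(
                CancerDiagnosis(
                    cancer_type=ctype,
                    age=age,
                    qualifiers=dx.qualifiers,
                    primary_index=dx.primary_index,
                )
            )
        person.diagnoses = new_dx
    return q
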