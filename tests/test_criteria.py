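"""Criteria engine: worked histories, per-syndrome rules, Amsterdam II, and
the structural properties (monotonicity, mirror consistency, oracle
equivalence, self-certification)."""

import numpy as np
import pytest

from conftest import dx, member, pedigree, random_pedigree
from oracle import oracle_criteria
from hcscreen.criteria import (
    EngineConfig,
    NormalizationError,
    RECOMMENDATION_TEXT,
    criterion_registry,
    evaluate,
    evaluate_brca,
    evaluate_lynch,
    evaluate_polyposis,
    meets_amsterdam_ii,
)
from hcscreen.pedigree import (
    CancerDiagnosis,
    AgeRecord,
    Ethnicity,
    GeneGroup,
    MutationFinding,
    Qualifier,
    Relationship,
    Sex,
    degree_of,
    reroot,
)

R = Relationship


def ids(events):
    return {e.criterion_id for e in events}


class TestWorkedHistories:
    def test_empty_history_meets_nothing(self):
        assert not evaluate(pedigree()).meets_any

    def test_fdr_brain_45_is_low_risk(self):
        """Brain cancer in one first-degree relative at 45: Lynch-related
        type, but no clause fires on a single non-colorectal relative."""
        p = pedigree(member(R.FATHER, dx("cns_brain", 45)))
        assert not evaluate(p).meets_any

    def test_sdr_brain_43_is_low_risk(self):
        p = pedigree(member(R.MATERNAL_UNCLE, dx("cns_brain", 43)))
        assert not evaluate(p).meets_any

    def test_early_breast_fires(self):
        p = pedigree(proband_dx=[dx("breast", 44)])
        report = evaluate(p)
        assert report.meets_any
        assert "B2" in ids(report.events)
        assert report.recommendation_text == RECOMMENDATION_TEXT

    def test_report_pure_and_deterministic(self):
        p = pedigree(member(R.MOTHER, dx("ovarian", 62)))
        before = p.model_dump_json()
        r1, r2 = evaluate(p), evaluate(p)
        assert r1 == r2
        assert p.model_dump_json() == before

    def test_unnormalized_type_rejected(self):
        p = pedigree(proband_dx=[
            CancerDiagnosis(cancer_type="Breast!!", age=AgeRecord.exact(40))
        ])
        with pytest.raises(NormalizationError, match="normalize"):
            evaluate(p)


class TestBrcaCriteria:
    def test_ashkenazi_breast_any_age(self):
        p = pedigree(
            proband_dx=[dx("breast", 65)], ethnicities={Ethnicity.ASHKENAZI_JEWISH}
        )
        assert "B13" in ids(evaluate_brca(p))

    def test_mother_ovarian_mirrors_personal_ovarian(self):
        p = pedigree(member(R.MOTHER, dx("ovarian", 62)))
        events = evaluate_brca(p)
        b18 = [e for e in events if e.criterion_id == "B18"]
        assert b18 and b18[0].sub_criterion == "B14"
        assert b18[0].index_person is R.MOTHER

    def test_two_breast_primaries_fire_both_age_rules(self):
        p = pedigree(proband_dx=[dx("breast", 41), dx("breast", 48)])
        got = ids(evaluate_brca(p))
        assert {"B2", "B3"} <= got

    def test_melanoma_only_fires_nothing(self):
        p = pedigree(proband_dx=[dx("melanoma", 40)])
        assert evaluate_brca(p) == []

    def test_known_brca_mutation_on_any_blood_relative(self):
        p = pedigree(
            member(R.MATERNAL_FIRST_COUSIN, sex=Sex.FEMALE),
            mutations=[MutationFinding(gene_group=GeneGroup.BRCA1_BRCA2,
                                       carrier=R.MATERNAL_FIRST_COUSIN)],
        )
        assert "B1" in ids(evaluate_brca(p))

    def test_triple_negative_under_60(self):
        p = pedigree(proband_dx=[dx("breast", 55, Qualifier.TRIPLE_NEGATIVE)])
        assert "B8" in ids(evaluate_brca(p))
        p2 = pedigree(proband_dx=[dx("breast", 61, Qualifier.TRIPLE_NEGATIVE)])
        assert "B8" not in ids(evaluate_brca(p2))

    def test_b9_requires_same_side(self):
        base = [dx("breast", 62)]
        cross = pedigree(
            member(R.MATERNAL_AUNT, dx("breast", 66)),
            member(R.PATERNAL_AUNT, dx("pancreatic", 60)),
            proband_dx=base,
        )
        assert "B9" not in ids(evaluate_brca(cross))
        same = pedigree(
            member(R.MATERNAL_AUNT, dx("breast", 66)),
            member(R.MATERNAL_UNCLE, dx("pancreatic", 60)),
            proband_dx=base,
        )
        assert "B9" in ids(evaluate_brca(same))

    def test_siblings_combine_with_either_side(self):
        """A sister's cancer supports a cluster on both family lines."""
        p = pedigree(
            member(R.SISTER, dx("breast", 58)),
            member(R.PATERNAL_AUNT, dx("breast", 63)),
            proband_dx=[dx("breast", 70)],
        )
        assert "B9" in ids(evaluate_brca(p))

    def test_male_breast_in_family(self):
        p = pedigree(member(R.MATERNAL_UNCLE, dx("breast", 64)))
        events = evaluate_brca(p)
        assert any(e.criterion_id == "B18" and e.sub_criterion == "B15" for e in events)

    def test_age_bounds_inclusive_by_default_and_configurable(self):
        p = pedigree(proband_dx=[dx("breast", 45)])
        assert "B2" in ids(evaluate_brca(p))
        strict = EngineConfig(brca_ages_inclusive=False)
        assert "B2" not in ids(evaluate_brca(p, strict))

    def test_unknown_age_only_any_age_clauses(self):
        p = pedigree(proband_dx=[dx("breast")], ethnicities={Ethnicity.ASHKENAZI_JEWISH})
        got = ids(evaluate_brca(p))
        assert "B13" in got  # any-age clause
        assert "B2" not in got and "B3" not in got  # age-bounded clauses

    def test_b19_third_degree_cluster(self):
        p = pedigree(
            member(R.MATERNAL_FIRST_COUSIN, dx("breast", 49), sex=Sex.FEMALE),
            member(R.MATERNAL_AUNT, dx("breast", 48)),
            member(R.MATERNAL_GRANDMOTHER, dx("ovarian", 60)),
        )
        assert "B19" in ids(evaluate_brca(p))


class TestLynchCriteria:
    def test_fdr_colon_under_50(self):
        p = pedigree(member(R.MOTHER, dx("colon", 48)))
        assert "L2" in ids(evaluate_lynch(p))

    def test_fdr_colon_at_50_is_strict(self):
        p = pedigree(member(R.MOTHER, dx("colon", 50)))
        assert "L2" not in ids(evaluate_lynch(p))

    def test_three_ls_relatives_regardless_of_age(self):
        p = pedigree(
            member(R.MATERNAL_GRANDMOTHER, dx("stomach", 55)),
            member(R.MATERNAL_UNCLE, dx("colon", 62)),
            member(R.MOTHER, dx("uterine_endometrial", 60)),
        )
        assert "L5" in ids(evaluate_lynch(p))

    def test_single_sdr_colon_fires_nothing(self):
        p = pedigree(member(R.MATERNAL_AUNT, dx("colon", 45)))
        assert evaluate_lynch(p) == []

    def test_l3_two_ls_primaries_in_one_fdr(self):
        p = pedigree(member(R.FATHER, dx("colon", 55), dx("stomach", 60)))
        assert "L3" in ids(evaluate_lynch(p))

    def test_l4_pair_with_one_young(self):
        p = pedigree(
            member(R.MOTHER, dx("uterine_endometrial", 47)),
            member(R.MATERNAL_GRANDFATHER, dx("colon", 70)),
        )
        assert "L4" in ids(evaluate_lynch(p))


class TestAmsterdamII:
    def test_classic_three_generation_family(self):
        p = pedigree(
            member(R.MOTHER, dx("colon", 49)),
            member(R.MATERNAL_GRANDFATHER, dx("colon", 60)),
            proband_dx=[dx("uterine_endometrial", 55)],
        )
        met, contributing = meets_amsterdam_ii(p)
        assert met
        assert set(contributing) == {R.SELF, R.MOTHER, R.MATERNAL_GRANDFATHER}

    def test_one_generation_fails_successive_clause(self):
        p = pedigree(
            member(R.MATERNAL_AUNT, dx("colon", 45)),
            member(R.MATERNAL_UNCLE, dx("colon", 55)),
            member(R.MOTHER, dx("colon", 60)),
        )
        assert not meets_amsterdam_ii(p)[0]

    def test_empty_pedigree(self):
        assert meets_amsterdam_ii(pedigree()) == (False, ())

    def test_requires_diagnosis_before_50(self):
        p = pedigree(
            member(R.MOTHER, dx("colon", 52)),
            member(R.MATERNAL_GRANDFATHER, dx("colon", 60)),
            proband_dx=[dx("uterine_endometrial", 55)],
        )
        assert not meets_amsterdam_ii(p)[0]


class TestPolyposis:
    def test_known_apc_mutyh_mutation(self):
        p = pedigree(
            mutations=[MutationFinding(gene_group=GeneGroup.APC_MUTYH, carrier=R.SELF)]
        )
        assert "P1" in ids(evaluate_polyposis(p))

    def test_no_polyps_no_event(self):
        assert evaluate_polyposis(pedigree(polyps=0)) == []

    def test_threshold_comparison(self):
        assert "P2" in ids(evaluate_polyposis(pedigree(polyps=15)))
        assert "P2" not in ids(evaluate_polyposis(pedigree(polyps=9)))
        assert "P2" in ids(
            evaluate_polyposis(pedigree(polyps=9), EngineConfig(polyp_threshold=5))
        )

    def test_fdr_polyp_burden(self):
        p = pedigree(member(R.BROTHER, polyps=12))
        assert "P3" in ids(evaluate_polyposis(p))
        p2 = pedigree(member(R.MATERNAL_AUNT, polyps=12))
        assert "P3" not in ids(evaluate_polyposis(p2))


class TestRegistry:
    def test_ids_unique_and_complete(self):
        reg = criterion_registry()
        assert len(reg) == 28
        assert {c.syndrome for c in reg.values()} == {"BRCA", "LYNCH", "POLYPOSIS"}
        assert set(reg) >= {f"B{i}" for i in range(1, 20)}


PERSONAL_IDS = {f"B{i}" for i in range(2, 18)}


class TestProperties:
    def test_monotone_in_history_content(self):
        """Adding a diagnosis, mutation, or the high-frequency ethnicity can
        switch a history from low to high risk but never the reverse."""
        rng = np.random.default_rng(42)
        flips = 0
        for _ in range(1000):
            p = random_pedigree(rng, max_members=6)
            before = evaluate(p).meets_any
            q = p.model_copy(deep=True)
            u = rng.random()
            if u < 0.5:
                target = [q.proband, *q.members][int(rng.integers(len(q.members) + 1))]
                target.diagnoses.append(
                    dx(
                        ["breast", "ovarian", "colon", "lung"][int(rng.integers(4))],
                        int(rng.integers(25, 80)),
                    )
                )
            elif u < 0.75:
                q.mutations.append(
                    MutationFinding(gene_group=GeneGroup.BRCA1_BRCA2, carrier=R.SELF)
                )
            else:
                q.proband.ethnicities = q.proband.ethnicities | {
                    Ethnicity.ASHKENAZI_JEWISH
                }
            after = evaluate(q).meets_any
            assert not (before and not after), "addition flipped high->low"
            flips += int(after and not before)
        assert flips > 50  # the additions genuinely exercise the rules

    def test_oracle_equivalence_small(self):
        rng = np.random.default_rng(7)
        for _ in range(250):
            p = random_pedigree(rng)
            assert {e.criterion_id for e in evaluate(p).events} == oracle_criteria(p)

    def test_mirror_consistency(self):
        """B18 fires iff some FDR/SDR index fulfills a personal clause on the
        re-rooted pedigree."""
        rng = np.random.default_rng(13)
        fired = 0
        for _ in range(300):
            p = random_pedigree(rng, max_members=6)
            engine_b18 = "B18" in {e.criterion_id for e in evaluate_brca(p)}
            mirrored = False
            for m in p.members:
                if degree_of(m.relationship) in (1, 2):
                    rp = reroot(p, m)
                    direct = {
                        e.criterion_id
                        for e in evaluate_brca(rp)
                        if e.index_person is R.SELF and e.criterion_id in PERSONAL_IDS
                    }
                    if direct:
                        mirrored = True
                        break
            assert engine_b18 == mirrored
            fired += int(engine_b18)
        assert fired > 30

    def test_events_self_certifying(self):
        """Re-evaluating only the contributing members plus the index person
        still satisfies each reported criterion."""
        from hcscreen.events import event_pedigree, extract_high_risk_events

        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(200):
            p = random_pedigree(rng, max_members=6)
            report = evaluate(p)
            if not report.meets_any:
                continue
            for ev in extract_high_risk_events(p):
                restricted = event_pedigree(ev, p)
                assert evaluate(restricted).meets_any, ev
                checked += 1
        assert checked > 100
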