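"""Independent-event extraction and modeled low-risk construction."""

import numpy as np
import pytest

from conftest import dx, member, pedigree, random_pedigree
from hcscreen.criteria import evaluate
from hcscreen.events import (
    EventKind,
    GroupingMode,
    event_pedigree,
    extract_high_risk_events,
    extract_low_risk_events,
    model_low_risk,
    predict_event,
)
from hcscreen.pedigree import Relationship

R = Relationship


class TestHighRiskExtraction:
    def test_one_event_per_fulfilled_criterion(self):
        p = pedigree(
            member(R.MOTHER, dx("ovarian", 62)),
            proband_dx=[dx("breast", 44)],
        )
        events = extract_high_risk_events(p)
        crits = sorted(e.criterion.criterion_id for e in events)
        # breast<=45 (B2), limited family (B7), relative ovarian (B11),
        # mirrored personal ovarian at the mother (B18)
        assert crits == ["B11", "B18", "B2", "B7"]
        assert all(e.kind is EventKind.CRITERION for e in events)

    def test_single_criterion_single_event(self):
        p = pedigree(proband_dx=[dx("ovarian", 58)])
        events = extract_high_risk_events(p)
        assert len(events) == 1
        assert events[0].criterion.criterion_id == "B14"

    def test_low_risk_input_rejected(self):
        with pytest.raises(ValueError, match="low_risk"):
            extract_high_risk_events(pedigree())

    def test_nonempty_iff_meets_any(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = random_pedigree(rng, max_members=5)
            if evaluate(p).meets_any:
                assert extract_high_risk_events(p)
            else:
                with pytest.raises(ValueError):
                    extract_high_risk_events(p)


class TestLowRiskExtraction:
    def test_same_side_pair_yields_combination(self):
        p = pedigree(
            member(R.MATERNAL_UNCLE, dx("lung", 60)),
            member(R.MATERNAL_GRANDFATHER, dx("colon", 65)),
        )
        events = extract_low_risk_events(p)
        kinds = [e.kind for e in events]
        assert kinds.count(EventKind.SINGLE_HISTORY) == 2
        assert kinds.count(EventKind.COMBINATION) == 1
        combo = next(e for e in events if e.kind is EventKind.COMBINATION)
        assert len(combo.histories) == 2 and combo.side == "maternal"

    def test_empty_history_is_one_event(self):
        events = extract_low_risk_events(pedigree())
        assert len(events) == 1
        assert events[0].kind is EventKind.NO_FAMILY_HISTORY

    def test_single_history_no_combination(self):
        p = pedigree(member(R.FATHER, dx("bladder", 70)))
        events = extract_low_risk_events(p)
        assert len(events) == 1
        h = events[0].histories[0]
        assert (h.cancer_type, h.age, h.degree, h.side) == ("bladder", 70, 1, "paternal")

    def test_cross_side_histories_never_combine(self):
        p = pedigree(
            member(R.MATERNAL_UNCLE, dx("lung", 60)),
            member(R.PATERNAL_UNCLE, dx("colon", 65)),
        )
        events = extract_low_risk_events(p)
        assert all(e.kind is not EventKind.COMBINATION for e in events)

    def test_per_pair_grouping_mode(self):
        p = pedigree(
            member(R.MATERNAL_UNCLE, dx("lung", 60)),
            member(R.MATERNAL_GRANDFATHER, dx("colon", 65)),
            member(R.MATERNAL_AUNT, dx("thyroid", 50)),
        )
        per_side = extract_low_risk_events(p, grouping=GroupingMode.PER_SIDE)
        per_pair = extract_low_risk_events(p, grouping=GroupingMode.PER_PAIR)
        assert sum(e.kind is EventKind.COMBINATION for e in per_side) == 1
        assert sum(e.kind is EventKind.COMBINATION for e in per_pair) == 3

    def test_high_risk_input_rejected(self):
        with pytest.raises(ValueError, match="high_risk"):
            extract_low_risk_events(pedigree(proband_dx=[dx("breast", 40)]))

    def test_no_payload_evaluates_high_alone(self):
        """Each low-risk event entered on its own stays low risk (the
        ground-truth construction of the specificity arm)."""
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(200):
            p = random_pedigree(rng, max_members=6)
            if evaluate(p).meets_any:
                p = model_low_risk(p)
            for ev in extract_low_risk_events(p):
                assert predict_event(ev, p) is False
                checked += 1
        assert checked > 200


class TestModelLowRisk:
    def test_removes_only_the_qualifying_event(self):
        p = pedigree(
            member(R.MOTHER, dx("ovarian", 52)),
            member(R.MATERNAL_GRANDFATHER, dx("lung", 60)),
        )
        modeled = model_low_risk(p)
        assert not evaluate(modeled).meets_any
        remaining = [
            (m.relationship, d.cancer_type)
            for m in modeled.members
            for d in m.diagnoses
        ]
        assert remaining == [(R.MATERNAL_GRANDFATHER, "lung")]

    def test_sole_qualifying_history_leaves_empty_pedigree(self):
        p = pedigree(proband_dx=[dx("breast", 44)])
        modeled = model_low_risk(p)
        assert modeled.proband.diagnoses == []
        events = extract_low_risk_events(modeled)
        assert events[0].kind is EventKind.NO_FAMILY_HISTORY

    def test_postcondition_and_idempotence(self):
        rng = np.random.default_rng(5)
        for _ in range(120):
            p = random_pedigree(rng, max_members=6)
            modeled = model_low_risk(p)
            assert not evaluate(modeled).meets_any
            assert model_low_risk(modeled) == modeled

    def test_preserves_non_qualifying_history_verbatim(self):
        p = pedigree(
            member(R.MOTHER, dx("colon", 48)),  # fires the young-colorectal rule
            member(R.PATERNAL_AUNT, dx("melanoma", 61)),
        )
        modeled = model_low_risk(p)
        kept = [d for m in modeled.members for d in m.diagnoses]
        assert [d.cancer_type for d in kept] == ["melanoma"]
        assert kept[0].age.value == 61


class TestEventEntry:
    def test_criterion_event_needs_source(self):
        p = pedigree(proband_dx=[dx("ovarian", 58)])
        ev = extract_high_risk_events(p)[0]
        with pytest.raises(ValueError, match="source"):
            event_pedigree(ev)

    def test_single_history_round_trip(self):
        p = pedigree(member(R.MATERNAL_AUNT, dx("lung", 63)))
        ev = extract_low_risk_events(p)[0]
        rebuilt = event_pedigree(ev)
        assert rebuilt.members[0].relationship is R.MATERNAL_AUNT
        assert rebuilt.members[0].diagnoses[0].age.value == 63
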