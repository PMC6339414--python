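"""Instrument rule engine: Katz ADL, Barthel index, SF-36 sections."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ccfo.extraction import Finding
from ccfo.scoring import score_barthel, score_katz, score_sf36, validate_rules

F = Finding

INDEPENDENT_KATZ = [
    F("112441", "able"), F("112442", "able"), F("112444", "able"), F("112445", "able"),
    F("1122", "able"), F("112721"), F("112722"),
]
DEPENDENT_KATZ = [
    F("112441", "unable"), F("112442", "unable"), F("112444", "unable"),
    F("112445", "unable"), F("1122", "unable"), F("112711"), F("112712"),
]
DEPENDENT_BARTHEL = [
    F("112711"), F("112712"),
    F("112441", "unable"), F("112442", "unable"), F("112443", "unable"),
    F("112444", "unable"), F("112445", "unable"),
    F("1122", "absent"), F("1121221"), F("1124713", "unable"),
]


class TestRuleTable:
    def test_rules_reference_known_concepts(self, rules, ont):
        assert validate_rules(rules, ont) == []


class TestKatz:
    def test_fully_independent_scores_six(self, ont):
        r = score_katz(INDEPENDENT_KATZ, ont)
        assert r.total == 6
        assert r.coverage == 1.0

    def test_fully_dependent_scores_zero(self, ont):
        assert score_katz(DEPENDENT_KATZ, ont).total == 0

    def test_continence_only_scores_one(self, ont):
        r = score_katz([F("112721"), F("112722")], ont)
        assert r.total == 1
        assert r.coverage == pytest.approx(1 / 6)

    def test_absent_qualified_incontinence_counts_as_continent(self, ont):
        r = score_katz([F("112711", "absent"), F("112712", "absent")], ont)
        assert r.total == 1

    def test_one_continence_kind_is_not_enough(self, ont):
        assert score_katz([F("112721")], ont).total == 0

    def test_oracle_equivalence_by_exhaustive_enumeration(self, ont):
        """score_katz matches a literal hand-coded reading of the printed
        counting rules over all 3^5 qualifier ladders x continence states."""
        concepts = ["112441", "112442", "112444", "112445", "1122"]
        levels = ["able", "with-difficulty", "unable"]
        cont_states = ["both-continent", "both-incontinent", "none"]

        def oracle(assign, cont):
            total = sum(1 for q in assign if q == "able")
            if cont == "both-continent":
                total += 1
            return total

        for assign in itertools.product(levels, repeat=5):
            for cont in cont_states:
                findings = [F(c, q) for c, q in zip(concepts, assign)]
                if cont == "both-continent":
                    findings += [F("112721"), F("112722")]
                elif cont == "both-incontinent":
                    findings += [F("112711"), F("112712")]
                assert score_katz(findings, ont).total == oracle(assign, cont)


class TestBarthel:
    def test_fully_dependent_scores_zero_with_full_coverage(self, ont):
        r = score_barthel(DEPENDENT_BARTHEL, ont)
        assert r.total == 0
        assert r.coverage == 1.0

    def test_wheelchair_bound_mobility_contribution_is_one(self, ont):
        r = score_barthel([F("1121223")], ont)
        assert r.item_points["mobility"] == 1
        assert r.total == 1

    def test_unqualified_personal_care_children_score_ten(self, ont):
        fs = [F(c) for c in ("112441", "112442", "112443", "112444", "112445")]
        assert score_barthel(fs, ont).total == 10

    @pytest.mark.parametrize(
        "finding,points",
        [
            (F("112121", "able"), 3),
            (F("112472"), 3),
            (F("112121", "with-difficulty"), 2),
            (F("112473"), 2),
            (F("1121223"), 1),
            (F("1121221"), 0),
            (F("112121", "unable"), 0),
        ],
    )
    def test_mobility_ladder(self, ont, finding, points):
        assert score_barthel([finding], ont).item_points["mobility"] == points

    def test_bed_ridden_beats_able_mobilize(self, ont):
        # conflicting evidence: the most dependent rung wins
        r = score_barthel([F("112121", "able"), F("1121221")], ont)
        assert r.item_points["mobility"] == 0

    def test_scale_metadata_reports_published_and_rule_sum_bounds(self, ont):
        r = score_barthel([], ont)
        assert (r.scale_min, r.scale_max) == (0, 20)
        assert r.rule_sum_max == 19


class TestSF36:
    def test_best_case_general_health_is_100(self, ont):
        fs = [F("1323", "high-frequency"),
              F("1323", "high-frequency", course="sudden-onset")]
        assert score_sf36(fs, ont).total["general-health"] == 100

    def test_worst_case_general_health_is_0(self, ont):
        assert score_sf36([F("1324", "high-frequency")], ont).total["general-health"] == 0

    def test_mid_frequency_pain_covers_only_question_21(self, ont):
        r = score_sf36([F("1111", "mid-frequency")], ont)
        assert r.total["pain"] == 50
        assert r.item_points["pain/q21"] == 50
        assert r.item_points["pain/q22"] is None

    def test_pain_with_daily_routine_conjunction(self, ont):
        r = score_sf36([F("1111", "mid-frequency"), F("11245", "able")], ont)
        assert r.item_points["pain/q22"] == 75
        assert r.total["pain"] == pytest.approx((50 + 75) / 2)

    def test_multi_question_blocks_weight_the_section_average(self, ont):
        # walking (3 questions, 200/300) + kneeling (1 question, 100/100)
        r = score_sf36([F("112471", "with-difficulty"), F("11211", "able")], ont)
        assert r.total["physical-functioning"] == pytest.approx((200 + 100) / 4)

    def test_role_emotional_needs_a_psychological_finding(self, ont):
        alone = score_sf36([F("1154", "absent")], ont)
        assert alone.total["role-emotional"] is None
        with_psych = score_sf36([F("1154", "absent"), F("113334", "absent")], ont)
        assert with_psych.total["role-emotional"] == 100

    def test_section_without_evidence_has_no_score(self, ont):
        r = score_sf36([], ont)
        assert all(v is None for v in r.total.values())
        assert r.coverage == 0.0

    def test_section_values_stay_in_bounds(self, ont):
        fs = [F("113331", "high-frequency"), F("113332", "mid-frequency"),
              F("21", "absent"), F("22")]
        r = score_sf36(fs, ont)
        for v in r.total.values():
            if v is not None:
                assert 0 <= v <= 100


# -- cross-instrument properties -------------------------------------------

_ABILITY = ["unable", "with-difficulty", "able"]
_FREQ_DEFICIT = ["high-frequency", "mid-frequency", "absent"]
_ABILITY_CONCEPTS = ["112441", "112442", "112443", "112444", "112445", "1122",
                     "112121", "1124713", "112471", "11211", "11245"]
_DEFICIT_CONCEPTS = ["1111", "132222", "1324", "1154", "11531", "113334"]


def _totals(ont, findings):
    k = score_katz(findings, ont).total
    b = score_barthel(findings, ont).total
    s = score_sf36(findings, ont).total
    return k, b, s


@st.composite
def _finding_sets(draw):
    n = draw(st.integers(1, 5))
    out = []
    for _ in range(n):
        if draw(st.booleans()):
            cid = draw(st.sampled_from(_ABILITY_CONCEPTS))
            lvl_idx = draw(st.integers(0, 2))
            out.append((cid, "ability", lvl_idx))
        else:
            cid = draw(st.sampled_from(_DEFICIT_CONCEPTS))
            lvl_idx = draw(st.integers(0, 2))
            out.append((cid, "frequency", lvl_idx))
    return out


class TestProperties:
    @given(_finding_sets(), st.data())
    @settings(max_examples=40, deadline=None)
    def test_qualifier_improvement_never_lowers_any_total(self, ont, fset, data):
        def realize(fs):
            return [
                F(cid, (_ABILITY if ax == "ability" else _FREQ_DEFICIT)[i])
                for cid, ax, i in fs
            ]

        idx = data.draw(st.integers(0, len(fset) - 1))
        cid, ax, lvl = fset[idx]
        if lvl == 2:
            return  # already at the best level
        improved = list(fset)
        improved[idx] = (cid, ax, lvl + 1)

        k0, b0, s0 = _totals(ont, realize(fset))
        k1, b1, s1 = _totals(ont, realize(improved))
        assert k1 >= k0 and b1 >= b0
        # SF-36 sections never decrease while the covered-block set is
        # unchanged.  The printed rules are a partial grid, so an
        # improvement can newly cover a block and legitimately shift the
        # evidence-weighted average; such sections are not compared.
        r0 = score_sf36(realize(fset), ont)
        r1 = score_sf36(realize(improved), ont)
        covered0 = {k for k, v in r0.item_points.items() if v is not None}
        covered1 = {k for k, v in r1.item_points.items() if v is not None}
        for section, before in s0.items():
            after = s1[section]
            blocks0 = {k for k in covered0 if k.startswith(f"{section}/")}
            blocks1 = {k for k in covered1 if k.startswith(f"{section}/")}
            if before is not None and after is not None and blocks0 == blocks1:
                assert after >= before, section

    def test_irrelevant_finding_changes_no_total(self, ont):
        base = INDEPENDENT_KATZ
        with_calm = base + [F("113331", "high-frequency")]
        assert score_katz(with_calm, ont).total == score_katz(base, ont).total
        assert score_barthel(with_calm, ont).total == score_barthel(base, ont).total

    def test_duplicate_findings_score_once(self, ont):
        once = [F("112441", "able")]
        thrice = once * 3
        assert score_katz(thrice, ont).total == score_katz(once, ont).total == 1

    def test_negated_findings_do_not_score_unless_absent(self, ont):
        negated = [F("112441", "able", assertion="negated")]
        assert score_katz(negated, ont).total == 0
        denied_deficit = [F("1111", "absent", assertion="negated")]
        assert score_sf36(denied_deficit, ont).total["pain"] == 100
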