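import datetime as dt

import pytest

from medcrosswalk.catalog_model import (
    FinancialTransaction,
    LabResult,
    MedicationOrder,
)
from medcrosswalk.cohort import (
    CohortCriteria,
    CohortMode,
    CohortResult,
    compare_cohorts,
    expand_cmt_query,
    select_cohort,
)
from medcrosswalk.crosswalk import MatchMethod, MethodConfig, integrate_via_hub
from medcrosswalk.enrichment import (
    EnrichmentStrategy,
    enrich_charge_codes,
    initial_match_financial,
)
from medcrosswalk.errors import ValidationError
from medcrosswalk.synthgen import FINANCIAL, INPATIENT, SynthConfig, generate_world

D = dt.date(2009, 6, 1)


def build_expansion(world, configs=None):
    configs = configs or [
        MethodConfig(MatchMethod.DISPENSE_CODE),
        MethodConfig(MatchMethod.PRIMARY_NDC),
    ]
    table = integrate_via_hub(
        list(world.snapshots.values()), INPATIENT, configs, world.graph
    )
    matches = initial_match_financial(
        world.snapshots[FINANCIAL], world.snapshots[INPATIENT]
    )
    enriched = enrich_charge_codes(
        matches, world.snapshots[INPATIENT], world.graph, EnrichmentStrategy.VIA_MMDC_CD
    )
    return expand_cmt_query(world.truth.target_concepts, table, enriched)


class TestCriteria:
    def test_exactly_one_specification(self):
        with pytest.raises(ValidationError):
            CohortCriteria(lab_test_code="INR")
        with pytest.raises(ValidationError):
            CohortCriteria(
                lab_test_code="INR",
                concepts={("RXNORM", "1")},
                description_pattern="warfarin",
            )

    def test_empty_concept_set_rejected(self):
        with pytest.raises(ValidationError):
            CohortCriteria(lab_test_code="INR", concepts=frozenset())


class TestExpansion:
    def test_worked_example_chain(self, fig34):
        table = integrate_via_hub(
            [fig34.inpatient, fig34.historical, fig34.financial],
            "INPATIENT_EHR",
            [MethodConfig(MatchMethod.DISPENSE_CODE)],
            fig34.graph,
        )
        matches = initial_match_financial(fig34.financial, fig34.inpatient)
        enriched = enrich_charge_codes(
            matches, fig34.inpatient, fig34.graph, EnrichmentStrategy.VIA_MMDC_CD
        )
        expansion = expand_cmt_query({("RXNORM", "855332")}, table, enriched)
        assert expansion["INPATIENT_EHR"] == {"17362344"}
        assert expansion["HISTORICAL_PM"] == {"WARF5TU"}
        assert expansion["FINANCIAL"] == {"7056345"}

    def test_unknown_concept_expands_to_nothing(self, fig34):
        table = integrate_via_hub(
            [fig34.inpatient, fig34.historical], "INPATIENT_EHR", [], fig34.graph
        )
        expansion = expand_cmt_query({("RXNORM", "000000")}, table, [])
        assert all(not codes for codes in expansion.values())

    def test_empty_query_rejected(self, fig34):
        table = integrate_via_hub([fig34.inpatient], "INPATIENT_EHR", [])
        with pytest.raises(ValidationError):
            expand_cmt_query(set(), table, [])


class TestSelection:
    expansion = {"SYS": frozenset({"item1"})}

    def crit(self, same_encounter=True):
        return CohortCriteria(
            lab_test_code="INR",
            concepts={("RXNORM", "855332")},
            same_encounter=same_encounter,
        )

    def test_order_plus_same_encounter_lab_included(self):
        orders = [MedicationOrder("SYS", "P1", "E1", "item1", D)]
        labs = [LabResult("P1", "E1", "INR", 2.4, D)]
        result = select_cohort(self.crit(), orders, [], labs, self.expansion)
        assert result.per_source["SYS"] == {"P1"}

    def test_lab_in_other_encounter_excluded_when_constrained(self):
        orders = [MedicationOrder("SYS", "P1", "E1", "item1", D)]
        labs = [LabResult("P1", "E2", "INR", 2.4, D)]
        strict = select_cohort(self.crit(), orders, [], labs, self.expansion)
        loose = select_cohort(self.crit(False), orders, [], labs, self.expansion)
        assert strict.combined == frozenset()
        assert loose.combined == {"P1"}

    def test_transaction_qualifies_through_financial_source(self):
        expansion = {"FINANCIAL": frozenset({"700"})}
        txns = [FinancialTransaction("P2", "E5", "700", D)]
        labs = [LabResult("P2", "E5", "INR", 3.0, D)]
        result = select_cohort(self.crit(), [], txns, labs, expansion)
        assert result.per_source["FINANCIAL"] == {"P2"}

    def test_empty_inputs_give_empty_cohort(self):
        result = select_cohort(self.crit(), [], [], [], self.expansion)
        assert result.combined == frozenset()

    def test_cmt_mode_requires_expansion(self):
        with pytest.raises(ValidationError):
            select_cohort(self.crit(), [], [], [], None)


@pytest.fixture(scope="module")
def world():
    """Clean crosswalk, but planted criteria violations and charge gaps."""
    return generate_world(
        SynthConfig.noiseless(
            n_drugs=60,
            n_patients=800,
            p_criteria_violation=0.08,
            p_charge_gap=0.15,
            seed=17,
        )
    )


class TestSyntheticCohorts:

    def test_cmt_cohort_equals_eligibility_ledger(self, world):
        expansion = build_expansion(world)
        crit = CohortCriteria(lab_test_code="INR", concepts=world.truth.target_concepts)
        result = select_cohort(
            crit, world.orders, world.transactions, world.labs, expansion
        )
        assert result.combined == world.truth.eligibility_ledger

    def test_same_encounter_constraint_strictly_shrinks(self, world):
        expansion = build_expansion(world)
        loose = CohortCriteria(
            lab_test_code="INR",
            concepts=world.truth.target_concepts,
            same_encounter=False,
        )
        strict = CohortCriteria(
            lab_test_code="INR", concepts=world.truth.target_concepts
        )
        loose_result = select_cohort(
            loose, world.orders, world.transactions, world.labs, expansion
        )
        strict_result = select_cohort(
            strict, world.orders, world.transactions, world.labs, expansion
        )
        assert strict_result.combined < loose_result.combined
        assert (
            loose_result.combined
            == world.truth.eligibility_ledger | world.truth.violation_ledger
        )

    def test_description_mode_agrees_with_cmt_mode(self, world):
        expansion = build_expansion(world)
        cmt = select_cohort(
            CohortCriteria(lab_test_code="INR", concepts=world.truth.target_concepts),
            world.orders, world.transactions, world.labs, expansion,
        )
        desc = select_cohort(
            CohortCriteria(lab_test_code="INR", description_pattern="warfarin"),
            world.orders, world.transactions, world.labs,
            snapshots=list(world.snapshots.values()),
        )
        assert desc.mode is CohortMode.DESCRIPTION
        assert desc.combined == cmt.combined

    def test_cohort_monotone_in_expansion(self, world):
        expansion = build_expansion(world)
        crit = CohortCriteria(lab_test_code="INR", concepts=world.truth.target_concepts)
        small = {INPATIENT: expansion[INPATIENT]}
        small_result = select_cohort(
            crit, world.orders, world.transactions, world.labs, small
        )
        full_result = select_cohort(
            crit, world.orders, world.transactions, world.labs, expansion
        )
        assert small_result.combined <= full_result.combined

    def test_financial_gap_measured_by_cohort_comparison(self, world):
        expansion = build_expansion(world)
        crit = CohortCriteria(lab_test_code="INR", concepts=world.truth.target_concepts)
        result = select_cohort(
            crit, world.orders, world.transactions, world.labs, expansion
        )
        clinical = CohortResult(
            CohortMode.CMT,
            {s: p for s, p in result.per_source.items() if s != FINANCIAL},
        )
        financial = CohortResult(CohortMode.CMT, {FINANCIAL: result.per_source[FINANCIAL]})
        overlap = compare_cohorts(clinical, financial)
        assert overlap.n_a_only == len(world.truth.gap_ledger)
        assert overlap.n_intersection == len(
            world.truth.eligibility_ledger - world.truth.gap_ledger
        )


class TestCohortResultInvariants:
    def test_combined_is_union_and_exclusive_disjoint(self):
        result = CohortResult(
            CohortMode.CMT,
            {"A": {"p1", "p2"}, "B": {"p2", "p3"}},
        )
        assert result.combined == {"p1", "p2", "p3"}
        assert result.exclusive == {"A": {"p1"}, "B": {"p3"}}

    def test_compare_identical_and_disjoint(self):
        a = CohortResult(CohortMode.CMT, {"A": {"p1", "p2"}})
        b = CohortResult(CohortMode.CMT, {"B": {"p3"}})
        same = compare_cohorts(a, a)
        assert same.pct_overlap == 100.0 and same.n_a_only == 0
        disjoint = compare_cohorts(a, b)
        assert disjoint.pct_overlap == 0.0 and disjoint.n_b_only == 1
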