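import dataclasses

import numpy as np
import pytest

import oracles
from medcrosswalk.catalog_model import CatalogEntry, CatalogSnapshot
from medcrosswalk.crosswalk import (
    ItemRef,
    MatchMethod,
    MatchRecord,
    MatchStatus,
    MethodConfig,
    detect_mismatches,
    integrate_via_hub,
    match_by_metadata,
    match_by_primary_ndc,
    match_by_related_ndc,
    read_crosswalk,
    write_crosswalk,
)
from medcrosswalk.errors import ConfigurationError
from medcrosswalk.synthgen import (
    FINANCIAL,
    HISTORICAL,
    INPATIENT,
    OUTPATIENT,
    SynthConfig,
    generate_world,
)


class TestRecordInvariants:
    def test_same_system_rejected(self):
        with pytest.raises(ConfigurationError):
            MatchRecord(ItemRef("A", "1"), ItemRef("A", "2"), MatchMethod.CHARGE_CODE)

    def test_related_ndc_requires_via(self):
        with pytest.raises(ConfigurationError):
            MatchRecord(ItemRef("A", "1"), ItemRef("B", "2"), MatchMethod.RELATED_NDC)


class TestWorkedExample:
    def test_dispense_code_links_historical_to_current_item(self, fig34):
        records = match_by_metadata(fig34.historical, fig34.inpatient, "DISPENSE_CODE")
        assert len(records) == 1
        assert records[0].right == ItemRef(INPATIENT, "17362344")
        assert records[0].status is MatchStatus.MATCH

    def test_related_ndc_crosses_package_codes(self, fig34):
        # historical carries 00832121601; the MMDC concept joins it to the
        # inpatient primary 00056017275
        records = match_by_related_ndc(
            fig34.historical, fig34.inpatient, fig34.graph, "MULTUM"
        )
        assert oracles.pairs_of(records) == {("WARF5TU", "17362344")}
        assert "MULTUM:3616" in records[0].via

    def test_transitive_chain_financial_to_historical(self, fig34):
        table = integrate_via_hub(
            [fig34.inpatient, fig34.historical, fig34.financial],
            INPATIENT,
            [MethodConfig(MatchMethod.CHARGE_CODE), MethodConfig(MatchMethod.DISPENSE_CODE)],
            fig34.graph,
        )
        pairs = {
            (r.left.system_id, r.left.local_item_id, r.right.system_id, r.right.local_item_id)
            for r in table.spoke_spoke
        }
        assert (FINANCIAL, "7056345", "HISTORICAL_PM", "WARF5TU") in pairs
        assert all("hub:" in r.via for r in table.spoke_spoke)


def snap(system, entries):
    return CatalogSnapshot(system, 2009, tuple(entries))


class TestMetadataMatching:
    def test_missing_attribute_produces_no_records(self):
        left = snap("A", [CatalogEntry("A", "1")])
        right = snap("B", [CatalogEntry("B", "2")])
        assert match_by_metadata(left, right, "CHARGE_CODE") == []

    def test_codes_compared_case_insensitively(self):
        left = snap("A", [CatalogEntry("A", "1", dispense_code="warf5tu ")])
        right = snap("B", [CatalogEntry("B", "2", dispense_code="WARF5TU")])
        assert len(match_by_metadata(left, right, "DISPENSE_CODE")) == 1

    def test_unsupported_attribute_rejected(self):
        left = snap("A", [])
        with pytest.raises(ConfigurationError):
            match_by_metadata(left, snap("B", []), "PRIMARY_NDC")


class TestPrimaryNdcMatching:
    def test_compounded_item_never_matched(self):
        left = snap("A", [CatalogEntry("A", "1")])  # no NDC
        right = snap("B", [CatalogEntry("B", "2", primary_ndc="00056017275")])
        assert match_by_primary_ndc(left, right) == []

    def test_equal_primary_matches(self):
        left = snap("A", [CatalogEntry("A", "1", primary_ndc="00056017275")])
        right = snap("B", [CatalogEntry("B", "2", primary_ndc="00056017275")])
        assert oracles.pairs_of(match_by_primary_ndc(left, right)) == {("1", "2")}


class TestMismatchDetection:
    def two_item_case(self, mmdc_b):
        left = snap(FINANCIAL, [CatalogEntry(FINANCIAL, "700", charge_code="700")])
        right = snap(
            INPATIENT,
            [
                CatalogEntry(INPATIENT, "i1", charge_code="700", mmdc="3616"),
                CatalogEntry(INPATIENT, "i2", charge_code="700", mmdc=mmdc_b),
            ],
        )
        return detect_mismatches(
            match_by_metadata(left, right, "CHARGE_CODE"), right
        )

    def test_two_distinct_mmdcs_flagged(self):
        records = self.two_item_case("9999")
        assert {r.status for r in records} == {MatchStatus.MISMATCH}

    def test_shared_mmdc_stays_match(self):
        records = self.two_item_case("3616")
        assert {r.status for r in records} == {MatchStatus.MATCH}

    def test_absent_discriminator_ignored(self):
        records = self.two_item_case(None)
        assert {r.status for r in records} == {MatchStatus.MATCH}

    def test_unknown_discriminator_rejected(self, fig34):
        records = match_by_metadata(fig34.financial, fig34.inpatient, "CHARGE_CODE")
        with pytest.raises(ConfigurationError):
            detect_mismatches(records, fig34.inpatient, discriminator="colour")

    def test_flagged_set_equals_injected_conflicts(self):
        world = generate_world(
            SynthConfig.noiseless(n_drugs=300, n_patients=0, p_conflict=0.04, seed=2)
        )
        records = detect_mismatches(
            match_by_metadata(
                world.snapshots[FINANCIAL], world.snapshots[INPATIENT], "CHARGE_CODE"
            ),
            world.snapshots[INPATIENT],
        )
        flagged = {
            r.left.local_item_id for r in records if r.status is MatchStatus.MISMATCH
        }
        assert flagged == world.truth.conflict_ledger


@pytest.mark.parametrize("seed", range(6))
class TestAgainstBruteForce:
    """Every matching method equals its nested-loop oracle on random worlds."""

    def world(self, seed):
        return generate_world(SynthConfig(n_drugs=80, n_patients=0, seed=seed))

    def test_metadata_methods(self, seed):
        w = self.world(seed)
        left, right = w.snapshots[HISTORICAL], w.snapshots[INPATIENT]
        for method, attr in (("CHARGE_CODE", "charge_code"), ("DISPENSE_CODE", "dispense_code")):
            assert oracles.pairs_of(
                match_by_metadata(left, right, method)
            ) == oracles.metadata_pairs(left, right, attr)

    def test_ndc_methods(self, seed):
        w = self.world(seed)
        for left_sys in (HISTORICAL, OUTPATIENT):
            left, right = w.snapshots[left_sys], w.snapshots[INPATIENT]
            assert oracles.pairs_of(
                match_by_primary_ndc(left, right)
            ) == oracles.primary_ndc_pairs(left, right)
            for vocab in ("MULTUM", "RXNORM", "MEDISPAN"):
                assert oracles.pairs_of(
                    match_by_related_ndc(left, right, w.graph, vocab)
                ) == oracles.related_ndc_pairs(left, right, w.graph, vocab)


class TestProperties:
    def test_primary_subset_of_related(self, noisy_world):
        w = noisy_world
        left, right = w.snapshots[HISTORICAL], w.snapshots[INPATIENT]
        primary = oracles.pairs_of(match_by_primary_ndc(left, right))
        for vocab in ("MULTUM", "RXNORM", "MEDISPAN"):
            related = oracles.pairs_of(match_by_related_ndc(left, right, w.graph, vocab))
            assert primary <= related

    def test_symmetry(self, noisy_world):
        w = noisy_world
        a, b = w.snapshots[HISTORICAL], w.snapshots[INPATIENT]
        fwd = oracles.pairs_of(match_by_metadata(a, b, "DISPENSE_CODE"))
        rev = oracles.pairs_of(match_by_metadata(b, a, "DISPENSE_CODE"))
        assert fwd == {(y, x) for x, y in rev}

    def test_determinism_under_row_shuffle(self, noisy_world):
        w = noisy_world
        left, right = w.snapshots[HISTORICAL], w.snapshots[INPATIENT]
        rng = np.random.default_rng(0)
        shuffled = dataclasses.replace(
            left, entries=tuple(rng.permutation(np.array(left.entries, dtype=object)))
        )
        assert match_by_metadata(left, right, "DISPENSE_CODE") == match_by_metadata(
            shuffled, right, "DISPENSE_CODE"
        )


class TestHubIntegration:
    def test_hub_missing_rejected(self, fig34):
        with pytest.raises(ConfigurationError):
            integrate_via_hub([fig34.financial], INPATIENT, [])

    def test_single_snapshot_yields_empty_crosswalk(self, fig34):
        table = integrate_via_hub(
            [fig34.inpatient], INPATIENT, [MethodConfig(MatchMethod.CHARGE_CODE)]
        )
        assert table.records == ()

    def test_cmt_concept_not_a_hub_route(self):
        with pytest.raises(ConfigurationError):
            MethodConfig(MatchMethod.CMT_CONCEPT)

    def test_noiseless_crosswalk_is_identity_relation(self, noiseless_world):
        w = noiseless_world
        table = integrate_via_hub(
            list(w.snapshots.values()),
            INPATIENT,
            [
                MethodConfig(MatchMethod.DISPENSE_CODE),
                MethodConfig(MatchMethod.PRIMARY_NDC),
            ],
            w.graph,
        )
        id_map = w.truth.item_to_drug
        for rec in table.records:
            assert id_map[(rec.left.system_id, rec.left.local_item_id)] == id_map[
                (rec.right.system_id, rec.right.local_item_id)
            ]
        # every historical/outpatient item is recovered
        for spoke in (HISTORICAL, OUTPATIENT):
            matched = {
                r.left.local_item_id
                for r in table.spoke_hub
                if r.left.system_id == spoke
            }
            assert matched == w.snapshots[spoke].item_ids


def test_crosswalk_tsv_round_trip(tmp_path, fig34):
    records = match_by_related_ndc(
        fig34.historical, fig34.inpatient, fig34.graph, "MULTUM"
    )
    path = tmp_path / "xwalk.tsv"
    write_crosswalk(records, path)
    assert read_crosswalk(path) == records
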