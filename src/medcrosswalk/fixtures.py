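"""The warfarin worked-example fixture.

A three-system micro-world built around one drug, warfarin 5 mg oral
tablet, wired exactly like the published worked example of financial
enrichment and clinical integration:

* the financial catalog bills it under charge code ``7056345``;
* the current inpatient catalog carries it as item ``17362344`` with that
  charge code, dispense code ``WARF5TU``, Multum drug code ``d00022``, main
  Multum drug code (MMDC) ``3616``, primary NDC ``00056-0172-75`` and an
  additional NDC ``00832-1216-01``;
* the historical pharmacy module carries the same drug with dispense code
  ``WARF5TU`` (its local id here; the historical id is not part of the
  example), and — synthetic by construction, since the example does not
  state it — primary NDC ``00832121601`` so the related-NDC route is
  exercisable;
* MMDC ``3616`` links to RxNorm clinical drug ``855332`` on basis CD.

Matching the financial code by charge code yields item 17362344; matching
the historical orderable by dispense code yields the same item; enriching
through the MMDC assigns RxNorm 855332 to charge code 7056345.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .catalog_model import CatalogEntry, CatalogSnapshot, write_catalog
from .enrichment import MULTUM, RXNORM
from .vocab_graph import (
    CrossVocabLink,
    LinkBasis,
    TermType,
    VocabGraph,
    VocabularyConcept,
    write_concept_table,
    write_link_table,
)

__all__ = ["Figures34", "figures34", "write_figures34"]

INPATIENT = "INPATIENT_EHR"
HISTORICAL = "HISTORICAL_PM"
FINANCIAL = "FINANCIAL"

WARFARIN_ITEM = "17362344"
WARFARIN_CHARGE = "7056345"
WARFARIN_DISPENSE = "WARF5TU"
WARFARIN_MMDC = "3616"
WARFARIN_DRUGCODE = "d00022"
WARFARIN_RXCUI = "855332"
WARFARIN_NDC_PRIMARY = "00056017275"
WARFARIN_NDC_OTHER = "00832121601"


@dataclass(frozen=True)
class Figures34:
    graph: VocabGraph
    inpatient: CatalogSnapshot
    historical: CatalogSnapshot
    financial: CatalogSnapshot

    @property
    def snapshots(self) -> dict[str, CatalogSnapshot]:
        return {
            INPATIENT: self.inpatient,
            HISTORICAL: self.historical,
            FINANCIAL: self.financial,
        }


def figures34(snapshot_year: int = 2009) -> Figures34:
    """Build the warfarin worked-example fixture."""
    inpatient = CatalogSnapshot(
        INPATIENT,
        snapshot_year,
        (
            CatalogEntry(
                system_id=INPATIENT,
                local_item_id=WARFARIN_ITEM,
                description="Warfarin 5 MG Oral Tablet",
                charge_code=WARFARIN_CHARGE,
                dispense_code=WARFARIN_DISPENSE,
                primary_ndc=WARFARIN_NDC_PRIMARY,
                additional_ndcs=frozenset({WARFARIN_NDC_OTHER}),
                multum_drug_code=WARFARIN_DRUGCODE,
                mmdc=WARFARIN_MMDC,
            ),
        ),
    )
    historical = CatalogSnapshot(
        HISTORICAL,
        snapshot_year,
        (
            CatalogEntry(
                system_id=HISTORICAL,
                local_item_id=WARFARIN_DISPENSE,
                description="Warfarin 5 MG Oral Tablet",
                dispense_code=WARFARIN_DISPENSE,
                primary_ndc=WARFARIN_NDC_OTHER,
            ),
        ),
    )
    financial = CatalogSnapshot(
        FINANCIAL,
        snapshot_year,
        (
            CatalogEntry(
                system_id=FINANCIAL,
                local_item_id=WARFARIN_CHARGE,
                description="Warfarin 5 MG Oral Tablet",
                charge_code=WARFARIN_CHARGE,
            ),
        ),
    )
    both_ndcs = frozenset({WARFARIN_NDC_PRIMARY, WARFARIN_NDC_OTHER})
    graph = VocabGraph(
        concepts=(
            VocabularyConcept(MULTUM, WARFARIN_MMDC, TermType.MMDC, both_ndcs),
            VocabularyConcept(MULTUM, WARFARIN_DRUGCODE, TermType.DRUGCODE, both_ndcs),
            VocabularyConcept(RXNORM, WARFARIN_RXCUI, TermType.CD, both_ndcs),
        ),
        links=(
            CrossVocabLink(
                (MULTUM, WARFARIN_MMDC), (RXNORM, WARFARIN_RXCUI), LinkBasis.CD
            ),
        ),
    )
    return Figures34(graph, inpatient, historical, financial)


def write_figures34(out_dir: Path | str) -> None:
    """Emit the fixture in the same TSV/pipe-delimited formats the loaders
    read (catalog_<system>.tsv, concepts.psv, links.psv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = figures34()
    for system, snap in fx.snapshots.items():
        write_catalog(snap, out / f"catalog_{system}.tsv")
    write_concept_table(fx.graph.concepts, out / "concepts.psv")
    write_link_table(fx.graph.links, out / "links.psv")
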