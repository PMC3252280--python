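"""Semantic enrichment of financial charge codes with CMT concepts.

Financial charge codes have no formal concept definitions.  Because the
inpatient EHR stores a copy of each item's charge code (for automated charge
capture) alongside pharmacy-vocabulary codes, a charge code can inherit a
controlled-terminology concept through the matched inpatient orderable:

    charge code -> inpatient item -> Multum code / NDC -> RxNorm concept

Four strategies are provided, mirroring the vocabulary routes available on
an inpatient orderable: its MMDC mapped to an RxNorm clinical drug (CD), its
Multum drug code mapped to an RxNorm generic name (GN), its primary NDC
resolved directly among RxNorm CD concepts, and its NDCs expanded through
Multum before resolving in RxNorm.  Every assignment carries an ordered
provenance path that can be replayed against the vocabulary graph.

Charge codes demoted to MISMATCH by the consistency rule receive no
assignments.  Patient-level financial transactions are enriched by joining
on charge code at query time; the catalog, not the transaction ledger, is
what gets enriched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalog_model import CatalogEntry, CatalogSnapshot
from .crosswalk import MatchRecord, MatchStatus, detect_mismatches, match_by_metadata
from .errors import ConfigurationError
from .vocab_graph import LinkBasis, TermType, VocabGraph

__all__ = [
    "EnrichmentStrategy",
    "Assignment",
    "EnrichedFinancialCode",
    "initial_match_financial",
    "enrich_charge_codes",
    "replay_path",
    "write_enrichments",
    "RXNORM",
    "MULTUM",
    "MEDISPAN",
]

RXNORM = "RXNORM"
MULTUM = "MULTUM"
MEDISPAN = "MEDISPAN"


class EnrichmentStrategy(str, enum.Enum):
    VIA_MMDC_CD = "VIA_MMDC_CD"
    VIA_DRUGCODE_GN = "VIA_DRUGCODE_GN"
    VIA_PRIMARY_NDC_CD = "VIA_PRIMARY_NDC_CD"
    VIA_RELATED_NDC_CD = "VIA_RELATED_NDC_CD"


@dataclass(frozen=True)
class Assignment:
    """One CMT concept assigned to a charge code, with full provenance."""

    strategy: EnrichmentStrategy
    vocabulary: str
    concept_id: str
    term_type: TermType
    path: tuple[str, ...]  # CC:<code>, <system>:<item>, intermediates..., final

    @property
    def concept(self) -> tuple[str, str, TermType]:
        return (self.vocabulary, self.concept_id, self.term_type)


@dataclass(frozen=True)
class EnrichedFinancialCode:
    charge_code: str
    assignments: tuple[Assignment, ...] = ()
    mismatch: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", tuple(self.assignments))
        if self.mismatch and self.assignments:
            raise ConfigurationError(
                f"mismatched charge code {self.charge_code!r} cannot carry "
                "assignments"
            )

    @property
    def concepts(self) -> frozenset[tuple[str, str, TermType]]:
        return frozenset(a.concept for a in self.assignments)

    @property
    def ambiguous(self) -> bool:
        """More than one distinct concept assigned (all retained for expert
        review rather than dropped)."""
        return len(self.concepts) > 1


def initial_match_financial(
    financial: CatalogSnapshot, inpatient: CatalogSnapshot
) -> list[MatchRecord]:
    """Initial charge-code match between the financial catalog and inpatient
    orderables, with MMDC-based mismatch detection applied.

    Financial entries use their charge code as local identity.
    """
    records = match_by_metadata(financial, inpatient, "CHARGE_CODE")
    return detect_mismatches(records, inpatient, discriminator="mmdc")


def _strategy_assignments(
    charge_code: str,
    item: CatalogEntry,
    graph: VocabGraph,
    strategy: EnrichmentStrategy,
) -> list[Assignment]:
    head = (f"CC:{charge_code}", f"{item.system_id}:{item.local_item_id}")
    out: list[Assignment] = []

    def rxnorm_concept(cid: str) -> TermType:
        return graph.concept((RXNORM, cid)).term_type

    if strategy is EnrichmentStrategy.VIA_MMDC_CD:
        if item.mmdc is None or (MULTUM, item.mmdc) not in graph:
            return []
        for cid in sorted(graph.map_concept((MULTUM, item.mmdc), RXNORM, {LinkBasis.CD})):
            out.append(
                Assignment(
                    strategy, RXNORM, cid, rxnorm_concept(cid),
                    head + (f"{MULTUM}:{item.mmdc}", f"{RXNORM}:{cid}"),
                )
            )
    elif strategy is EnrichmentStrategy.VIA_DRUGCODE_GN:
        if item.multum_drug_code is None or (MULTUM, item.multum_drug_code) not in graph:
            return []
        source = (MULTUM, item.multum_drug_code)
        for cid in sorted(graph.map_concept(source, RXNORM, {LinkBasis.GN})):
            out.append(
                Assignment(
                    strategy, RXNORM, cid, rxnorm_concept(cid),
                    head + (f"{MULTUM}:{item.multum_drug_code}", f"{RXNORM}:{cid}"),
                )
            )
    elif strategy is EnrichmentStrategy.VIA_PRIMARY_NDC_CD:
        if item.primary_ndc is None:
            return []
        for cid in sorted(graph.concept_for_ndc(item.primary_ndc, RXNORM)):
            if rxnorm_concept(cid) is not TermType.CD:
                continue
            out.append(
                Assignment(
                    strategy, RXNORM, cid, TermType.CD,
                    head + (f"NDC:{item.primary_ndc}", f"{RXNORM}:{cid}"),
                )
            )
    elif strategy is EnrichmentStrategy.VIA_RELATED_NDC_CD:
        if item.primary_ndc is None:
            return []
        seen: set[str] = set()
        for mediator in sorted(graph.concept_for_ndc(item.primary_ndc, MULTUM)) + [None]:
            if mediator is None:
                expanded = frozenset({item.primary_ndc})
                med_step = ()
            else:
                expanded = graph.concept((MULTUM, mediator)).ndcs
                med_step = (f"{MULTUM}:{mediator}",)
            for ndc in sorted(expanded):
                for cid in sorted(graph.concept_for_ndc(ndc, RXNORM)):
                    if cid in seen or rxnorm_concept(cid) is not TermType.CD:
                        continue
                    seen.add(cid)
                    if mediator is None:
                        steps = (f"NDC:{ndc}",)
                    else:
                        steps = (f"NDC:{item.primary_ndc}",) + med_step + (f"NDC:{ndc}",)
                    out.append(
                        Assignment(
                            strategy, RXNORM, cid, TermType.CD,
                            head + steps + (f"{RXNORM}:{cid}",),
                        )
                    )
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown strategy {strategy}")
    return out


def enrich_charge_codes(
    matches: Sequence[MatchRecord],
    inpatient: CatalogSnapshot,
    graph: VocabGraph,
    strategy: EnrichmentStrategy | str,
) -> list[EnrichedFinancialCode]:
    """Assign CMT concepts to every charge code with a surviving initial
    match, using one enrichment strategy.

    MISMATCH groups yield an :class:`EnrichedFinancialCode` with the
    ``mismatch`` flag set and no assignments.  Charge codes whose matched
    item lacks the strategy's source attribute (e.g. compounded items
    without NDC or MMDC) yield no assignment but still appear in the output,
    so match and enrichment denominators stay comparable.
    """
    strategy = EnrichmentStrategy(strategy)
    needed = (
        {RXNORM}
        if strategy is EnrichmentStrategy.VIA_PRIMARY_NDC_CD
        else {RXNORM, MULTUM}
    )
    missing = needed - graph.vocabularies
    if missing:
        raise ConfigurationError(
            f"strategy {strategy.value} requires vocabularies {sorted(missing)} "
            "absent from the graph"
        )

    groups: dict[str, list[MatchRecord]] = {}
    for rec in matches:
        groups.setdefault(rec.left.local_item_id, []).append(rec)

    out: list[EnrichedFinancialCode] = []
    for charge_code in sorted(groups):
        group = groups[charge_code]
        if any(rec.status is MatchStatus.MISMATCH for rec in group):
            out.append(EnrichedFinancialCode(charge_code, (), mismatch=True))
            continue
        assignments: list[Assignment] = []
        for rec in group:
            item = inpatient.entry(rec.right.local_item_id)
            assignments.extend(
                _strategy_assignments(charge_code, item, graph, strategy)
            )
        # de-duplicate concepts arising from multiple matched items
        unique: dict[tuple, Assignment] = {}
        for a in assignments:
            unique.setdefault(a.concept, a)
        out.append(
            EnrichedFinancialCode(
                charge_code, tuple(unique[k] for k in sorted(unique, key=str))
            )
        )
    return out


def replay_path(assignment: Assignment, graph: VocabGraph) -> bool:
    """Audit an assignment by replaying its provenance path through the
    vocabulary graph; True iff every hop is reproducible."""
    path = assignment.path
    final_vocab, final_id = path[-1].split(":", 1)
    if (final_vocab, final_id) != (assignment.vocabulary, assignment.concept_id):
        return False
    # path[0] is the charge code and path[1] the catalog item; those two hops
    # come from the catalog, not the graph, so replay starts at path[2].
    for prev, nxt in zip(path[2:-1], path[3:]):
        p_kind, p_val = prev.split(":", 1)
        n_kind, n_val = nxt.split(":", 1)
        if p_kind == "NDC" and n_kind != "NDC":
            if n_val not in graph.concept_for_ndc(p_val, n_kind):
                return False
        elif p_kind != "NDC" and n_kind == "NDC":
            if n_val not in graph.concept((p_kind, p_val)).ndcs:
                return False
        elif p_kind == "NDC" and n_kind == "NDC":
            return False  # NDC->NDC hop must pass through a concept
        else:
            if n_val not in graph.map_concept(
                (p_kind, p_val), n_kind, set(LinkBasis)
            ):
                return False
    return True


_ENRICH_COLUMNS = [
    "charge_code",
    "strategy",
    "vocabulary",
    "concept_id",
    "term_type",
    "path",
    "flags",
]


def write_enrichments(
    enriched: Iterable[EnrichedFinancialCode], path: Path | str
) -> None:
    rows = []
    for e in enriched:
        flags = ";".join(
            f for f, on in (("mismatch", e.mismatch), ("ambiguous", e.ambiguous)) if on
        )
        if not e.assignments:
            rows.append(
                {
                    "charge_code": e.charge_code,
                    "strategy": "",
                    "vocabulary": "",
                    "concept_id": "",
                    "term_type": "",
                    "path": "",
                    "flags": flags,
                }
            )
        for a in e.assignments:
            rows.append(
                {
                    "charge_code": e.charge_code,
                    "strategy": a.strategy.value,
                    "vocabulary": a.vocabulary,
                    "concept_id": a.concept_id,
                    "term_type": a.term_type.value,
                    "path": " -> ".join(a.path),
                    "flags": flags,
                }
            )
    pd.DataFrame(rows, columns=_ENRICH_COLUMNS).to_csv(path, sep="\t", index=False)
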