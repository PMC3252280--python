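"""Cross-system cohort selection by CMT concept or description search.

A cohort criterion pairs a medication specification — either a set of CMT
concepts (e.g. the RxNorm clinical drug for warfarin) or a free-text
description pattern — with a lab-test constraint (e.g. an INR measurement)
that may be required within the same encounter as the medication record.

CMT mode first expands the concept set to per-system local codes: charge
codes through the enrichment assignments, hub items through the assignment
provenance, and spoke items through the hub crosswalk.  Description mode
searches the catalog descriptions directly (case-insensitive substring) and
joins activity records through the catalog.  A patient qualifies from the
financial source through transactions; clinical sources qualify through
medication orders.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .catalog_model import (
    CatalogSnapshot,
    FinancialTransaction,
    LabResult,
    MedicationOrder,
    normalize_code,
)
from .crosswalk import CrosswalkTable, MatchStatus
from .enrichment import EnrichedFinancialCode
from .errors import ValidationError

__all__ = [
    "CohortMode",
    "CohortCriteria",
    "CohortResult",
    "CohortOverlap",
    "expand_cmt_query",
    "select_cohort",
    "compare_cohorts",
]


class CohortMode(str, enum.Enum):
    CMT = "CMT"
    DESCRIPTION = "DESCRIPTION"


@dataclass(frozen=True)
class CohortCriteria:
    """Medication + lab inclusion criteria.

    Exactly one of *concepts* (CMT mode) or *description_pattern*
    (description mode) must be given.
    """

    lab_test_code: str
    concepts: Optional[frozenset[tuple[str, str]]] = None
    description_pattern: Optional[str] = None
    same_encounter: bool = True

    def __post_init__(self) -> None:
        if (self.concepts is None) == (self.description_pattern is None):
            raise ValidationError(
                "exactly one of concepts / description_pattern must be set"
            )
        if self.concepts is not None:
            object.__setattr__(self, "concepts", frozenset(self.concepts))
            if not self.concepts:
                raise ValidationError("concept set must be non-empty")
        if not self.lab_test_code:
            raise ValidationError("lab_test_code must be non-empty")

    @property
    def mode(self) -> CohortMode:
        return CohortMode.CMT if self.concepts is not None else CohortMode.DESCRIPTION


@dataclass(frozen=True)
class CohortResult:
    mode: CohortMode
    per_source: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "per_source",
            {s: frozenset(p) for s, p in self.per_source.items()},
        )

    @property
    def combined(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for patients in self.per_source.values():
            out |= patients
        return out

    @property
    def exclusive(self) -> dict[str, frozenset[str]]:
        """Patients found in exactly one source."""
        out = {}
        for system, patients in self.per_source.items():
            others: frozenset[str] = frozenset()
            for other, p in self.per_source.items():
                if other != system:
                    others |= p
            out[system] = patients - others
        return out


def expand_cmt_query(
    concepts: Iterable[tuple[str, str]],
    crosswalk: CrosswalkTable,
    enrichments: Sequence[EnrichedFinancialCode],
    financial_system: str = "FINANCIAL",
) -> dict[str, frozenset[str]]:
    """Expand a CMT concept set to per-system local code sets.

    Charge codes come from enrichment assignments whose concept is queried;
    hub items are read off the assignments' provenance paths (the second
    path step is the matched hub item); spoke items are every crosswalk
    spoke-to-hub MATCH record pointing at one of those hub items.
    """
    query = {(v, c) for v, c in concepts}
    if not query:
        raise ValidationError("empty concept set")

    charge_codes: set[str] = set()
    hub_items: set[str] = set()
    for e in enrichments:
        if e.mismatch:
            continue
        for a in e.assignments:
            if (a.vocabulary, a.concept_id) in query:
                charge_codes.add(e.charge_code)
                system, item = a.path[1].split(":", 1)
                if system == crosswalk.hub:
                    hub_items.add(item)

    expansion: dict[str, set[str]] = {
        crosswalk.hub: set(hub_items),
        financial_system: charge_codes,
    }
    for rec in crosswalk.spoke_hub:
        if rec.status is not MatchStatus.MATCH:
            continue
        if rec.right.system_id == crosswalk.hub and rec.right.local_item_id in hub_items:
            expansion.setdefault(rec.left.system_id, set()).add(
                rec.left.local_item_id
            )
    return {s: frozenset(codes) for s, codes in expansion.items()}


def _lab_index(
    labs: Iterable[LabResult], test_code: str
) -> tuple[set[str], set[tuple[str, str]]]:
    code = normalize_code(test_code)
    patients: set[str] = set()
    encounters: set[tuple[str, str]] = set()
    for lab in labs:
        if normalize_code(lab.test_code) == code:
            patients.add(lab.patient_id)
            encounters.add((lab.patient_id, lab.encounter_id))
    return patients, encounters


def select_cohort(
    criteria: CohortCriteria,
    orders: Iterable[MedicationOrder],
    transactions: Iterable[FinancialTransaction],
    labs: Iterable[LabResult],
    expansion: Optional[Mapping[str, frozenset[str]]] = None,
    snapshots: Optional[Sequence[CatalogSnapshot]] = None,
    financial_system: str = "FINANCIAL",
) -> CohortResult:
    """Select the patient cohort satisfying *criteria* from each source.

    A patient qualifies from a clinical source when an order for an expanded
    item and a qualifying lab result share an encounter (same_encounter) or
    a patient id; from the financial source likewise through a transaction
    on an expanded charge code.  CMT mode requires *expansion* (from
    :func:`expand_cmt_query`); description mode requires *snapshots* and
    derives the expansion by case-insensitive substring search on catalog
    descriptions.
    """
    if criteria.mode is CohortMode.CMT:
        if expansion is None:
            raise ValidationError("CMT mode requires an expansion")
    else:
        if snapshots is None:
            raise ValidationError("DESCRIPTION mode requires catalog snapshots")
        pattern = criteria.description_pattern.casefold()
        expansion = {
            s.system_id: frozenset(
                e.local_item_id for e in s.entries if pattern in e.description.casefold()
            )
            for s in snapshots
        }

    lab_patients, lab_encounters = _lab_index(labs, criteria.lab_test_code)
    per_source: dict[str, set[str]] = {s: set() for s in expansion}

    for o in orders:
        codes = expansion.get(o.system_id)
        if not codes or o.local_item_id not in codes:
            continue
        if criteria.same_encounter:
            if (o.patient_id, o.encounter_id) in lab_encounters:
                per_source[o.system_id].add(o.patient_id)
        elif o.patient_id in lab_patients:
            per_source[o.system_id].add(o.patient_id)

    fin_codes = {normalize_code(c) for c in expansion.get(financial_system, ())}
    if fin_codes:
        for t in transactions:
            if normalize_code(t.charge_code) not in fin_codes:
                continue
            if criteria.same_encounter:
                if (t.patient_id, t.encounter_id) in lab_encounters:
                    per_source[financial_system].add(t.patient_id)
            elif t.patient_id in lab_patients:
                per_source[financial_system].add(t.patient_id)

    return CohortResult(criteria.mode, per_source)


@dataclass(frozen=True)
class CohortOverlap:
    """Set arithmetic between two cohorts; percentages are relative to the
    recorded denominator (the size of cohort *a*)."""

    n_a: int
    n_b: int
    n_intersection: int
    n_a_only: int
    n_b_only: int
    denominator: str = "a"

    @property
    def pct_overlap(self) -> Optional[float]:
        if self.n_a == 0:
            return None
        return 100.0 * self.n_intersection / self.n_a

    @property
    def pct_b_only(self) -> Optional[float]:
        if self.n_a == 0:
            return None
        return 100.0 * self.n_b_only / self.n_a


def compare_cohorts(a: CohortResult, b: CohortResult) -> CohortOverlap:
    sa, sb = a.combined, b.combined
    return CohortOverlap(
        n_a=len(sa),
        n_b=len(sb),
        n_intersection=len(sa & sb),
        n_a_only=len(sa - sb),
        n_b_only=len(sb - sa),
    )
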