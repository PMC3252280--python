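"""Cross-system item equivalences (crosswalks).

Two families of matching are supported.  *Metadata-based* matching compares
foreign-system code attributes (charge code, dispense code) that were copied
into each catalog to support automated charge capture and cabinet messaging.
*Vocabulary-based* matching compares NDCs, either exactly on the primary /
representative NDC of each item, or after expanding the left item's primary
NDC to its related-NDC closure through a pharmacy vocabulary.

A designated *hub* system (the current inpatient catalog, which carries the
most attributes) anchors multi-system integration: every spoke is matched to
the hub, and spoke-to-spoke equivalences are derived transitively through
shared hub items only.

Mismatch detection implements the consistency rule for duplicated financial
codes: when one left-side code matches hub items that carry more than one
distinct value of a discriminator attribute (by default the MMDC, i.e. more
than one distinct drug/dose/route/form), every record in that group is
demoted to MISMATCH and excluded from downstream enrichment and statistics.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalog_model import CODE_ATTRIBUTES, CatalogEntry, CatalogSnapshot, normalize_code
from .errors import ConfigurationError
from .vocab_graph import LinkBasis, VocabGraph

__all__ = [
    "MatchMethod",
    "MatchStatus",
    "ItemRef",
    "MatchRecord",
    "MethodConfig",
    "CrosswalkTable",
    "match_by_metadata",
    "match_by_primary_ndc",
    "match_by_related_ndc",
    "detect_mismatches",
    "integrate_via_hub",
    "write_crosswalk",
    "read_crosswalk",
]


class MatchMethod(str, enum.Enum):
    CHARGE_CODE = "CHARGE_CODE"
    DISPENSE_CODE = "DISPENSE_CODE"
    PRIMARY_NDC = "PRIMARY_NDC"
    RELATED_NDC = "RELATED_NDC"
    CMT_CONCEPT = "CMT_CONCEPT"


#: catalog attribute consulted by each metadata method
_METADATA_ATTRIBUTE = {
    MatchMethod.CHARGE_CODE: "charge_code",
    MatchMethod.DISPENSE_CODE: "dispense_code",
}


class MatchStatus(str, enum.Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"


@dataclass(frozen=True, order=True)
class ItemRef:
    system_id: str
    local_item_id: str


@dataclass(frozen=True)
class MatchRecord:
    """One cross-system equivalence assertion."""

    left: ItemRef
    right: ItemRef
    method: MatchMethod
    via: Optional[str] = None
    status: MatchStatus = MatchStatus.MATCH

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", MatchMethod(self.method))
        object.__setattr__(self, "status", MatchStatus(self.status))
        if self.left.system_id == self.right.system_id:
            raise ConfigurationError(
                f"match within one system {self.left.system_id!r}"
            )
        if self.method in (MatchMethod.RELATED_NDC, MatchMethod.CMT_CONCEPT) and not self.via:
            raise ConfigurationError(
                f"{self.method.value} records must carry path provenance (via)"
            )

    @property
    def sort_key(self):
        return (self.left, self.right, self.method.value, self.via or "")


def _canonical(records: Iterable[MatchRecord]) -> list[MatchRecord]:
    return sorted(set(records), key=lambda r: r.sort_key)


@dataclass(frozen=True)
class MethodConfig:
    """One matching route used during hub integration."""

    method: MatchMethod
    vocabulary: Optional[str] = None  # RELATED_NDC only
    discriminator: Optional[str] = None  # run mismatch detection when set
    bases: frozenset[LinkBasis] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", MatchMethod(self.method))
        if self.method is MatchMethod.RELATED_NDC and not self.vocabulary:
            raise ConfigurationError("RELATED_NDC config requires a vocabulary")
        if self.method is MatchMethod.CMT_CONCEPT:
            raise ConfigurationError(
                "CMT_CONCEPT is reserved for derived/enrichment records and is "
                "not a hub matching route"
            )


# ---------------------------------------------------------------------------
# pairwise matchers


def match_by_metadata(
    left: CatalogSnapshot,
    right: CatalogSnapshot,
    attribute: MatchMethod | str,
) -> list[MatchRecord]:
    """Match items whose charge or dispense codes are equal after
    normalization (whitespace-trimmed, case-folded).  Items lacking the
    attribute produce no records."""
    method = MatchMethod(attribute)
    try:
        attr = _METADATA_ATTRIBUTE[method]
    except KeyError:
        raise ConfigurationError(
            f"metadata matching supports CHARGE_CODE/DISPENSE_CODE, not {method.value}"
        ) from None
    index: dict[str, list[CatalogEntry]] = {}
    for e in right.entries:
        value = e.attribute(attr)
        if value is not None:
            index.setdefault(normalize_code(value), []).append(e)
    records = []
    for e in left.entries:
        value = e.attribute(attr)
        if value is None:
            continue
        for r in index.get(normalize_code(value), ()):
            records.append(
                MatchRecord(
                    ItemRef(left.system_id, e.local_item_id),
                    ItemRef(right.system_id, r.local_item_id),
                    method,
                )
            )
    return _canonical(records)


def match_by_primary_ndc(
    left: CatalogSnapshot, right: CatalogSnapshot
) -> list[MatchRecord]:
    """Match items with equal primary/representative NDC.  Items without a
    primary NDC (e.g. compounded preparations) are never matched."""
    index: dict[str, list[CatalogEntry]] = {}
    for e in right.entries:
        if e.primary_ndc is not None:
            index.setdefault(e.primary_ndc, []).append(e)
    records = []
    for e in left.entries:
        if e.primary_ndc is None:
            continue
        for r in index.get(e.primary_ndc, ()):
            records.append(
                MatchRecord(
                    ItemRef(left.system_id, e.local_item_id),
                    ItemRef(right.system_id, r.local_item_id),
                    MatchMethod.PRIMARY_NDC,
                )
            )
    return _canonical(records)


def match_by_related_ndc(
    left: CatalogSnapshot,
    right: CatalogSnapshot,
    graph: VocabGraph,
    vocabulary: str,
) -> list[MatchRecord]:
    """Match a left item to a right item when the related-NDC closure of the
    left primary NDC through *vocabulary* intersects the right item's raw
    NDC set (primary plus additional).

    Expansion is one-sided (left only), which keeps the recorded provenance
    a single concept.  Because the closure always contains the input NDC,
    the matched-pair set is a superset of :func:`match_by_primary_ndc`
    restricted to right primaries.
    """
    raw_index: dict[str, list[CatalogEntry]] = {}
    for e in right.entries:
        for ndc in e.all_ndcs:
            raw_index.setdefault(ndc, []).append(e)
    records = []
    for e in left.entries:
        if e.primary_ndc is None:
            continue
        expanded = graph.related_ndcs(e.primary_ndc, vocabulary)
        candidates: dict[str, CatalogEntry] = {}
        for ndc in expanded:
            for r in raw_index.get(ndc, ()):
                candidates[r.local_item_id] = r
        for r in candidates.values():
            overlap = expanded & r.all_ndcs
            mediators = sorted(
                cid
                for cid in graph.concept_for_ndc(e.primary_ndc, vocabulary)
                if graph.concept((vocabulary, cid)).ndcs & r.all_ndcs
            )
            tokens = [f"{vocabulary}:{cid}" for cid in mediators]
            if e.primary_ndc in r.all_ndcs:
                tokens.append(f"direct:{e.primary_ndc}")
            assert tokens and overlap, "matched pair must have provenance"
            records.append(
                MatchRecord(
                    ItemRef(left.system_id, e.local_item_id),
                    ItemRef(right.system_id, r.local_item_id),
                    MatchMethod.RELATED_NDC,
                    via=";".join(tokens),
                )
            )
    return _canonical(records)


# ---------------------------------------------------------------------------
# mismatch detection


def detect_mismatches(
    records: Sequence[MatchRecord],
    right_snapshot: CatalogSnapshot,
    discriminator: str = "mmdc",
) -> list[MatchRecord]:
    """Demote match groups whose right-side items disagree on a
    discriminator attribute.

    Records are grouped by their left item.  If the right items of a group
    carry more than one distinct non-absent value of *discriminator*, every
    record in the group is marked MISMATCH; groups whose right items share a
    single value (or carry none) keep status MATCH.
    """
    if discriminator not in CODE_ATTRIBUTES:
        raise ConfigurationError(
            f"unknown discriminator attribute {discriminator!r}; "
            f"expected one of {list(CODE_ATTRIBUTES)}"
        )
    groups: dict[ItemRef, list[MatchRecord]] = {}
    for rec in records:
        groups.setdefault(rec.left, []).append(rec)
    out: list[MatchRecord] = []
    for left, group in groups.items():
        values = set()
        for rec in group:
            if rec.right.system_id != right_snapshot.system_id:
                continue
            value = right_snapshot.entry(rec.right.local_item_id).attribute(
                discriminator
            )
            if value is not None:
                values.add(normalize_code(value))
        status = MatchStatus.MISMATCH if len(values) > 1 else MatchStatus.MATCH
        out.extend(dataclasses.replace(rec, status=status) for rec in group)
    return _canonical(out)


# ---------------------------------------------------------------------------
# hub integration


@dataclass(frozen=True)
class CrosswalkTable:
    """All spoke-to-hub records plus transitive spoke-to-spoke pairs."""

    hub: str
    spoke_hub: tuple[MatchRecord, ...]
    spoke_spoke: tuple[MatchRecord, ...] = ()

    @property
    def records(self) -> tuple[MatchRecord, ...]:
        return self.spoke_hub + self.spoke_spoke


def _run_config(
    spoke: CatalogSnapshot,
    hub_snapshot: CatalogSnapshot,
    config: MethodConfig,
    graph: Optional[VocabGraph],
) -> list[MatchRecord]:
    if config.method in _METADATA_ATTRIBUTE:
        recs = match_by_metadata(spoke, hub_snapshot, config.method)
    elif config.method is MatchMethod.PRIMARY_NDC:
        recs = match_by_primary_ndc(spoke, hub_snapshot)
    elif config.method is MatchMethod.RELATED_NDC:
        if graph is None:
            raise ConfigurationError("RELATED_NDC integration requires a VocabGraph")
        recs = match_by_related_ndc(spoke, hub_snapshot, graph, config.vocabulary)
    else:  # pragma: no cover - guarded in MethodConfig
        raise ConfigurationError(f"unsupported hub method {config.method}")
    if config.discriminator is not None:
        recs = detect_mismatches(recs, hub_snapshot, config.discriminator)
    return recs


def integrate_via_hub(
    snapshots: Sequence[CatalogSnapshot],
    hub: str,
    configs: Sequence[MethodConfig],
    graph: Optional[VocabGraph] = None,
) -> CrosswalkTable:
    """Match every spoke snapshot to the hub with each configured method and
    derive spoke-to-spoke equivalences through shared hub items.

    A spoke-to-spoke pair is asserted only when both legs are MATCH records
    to the same hub item; its provenance names the hub item and both leg
    methods.  No multi-hub chaining is performed.
    """
    by_id = {s.system_id: s for s in snapshots}
    if hub not in by_id:
        raise ConfigurationError(f"hub system {hub!r} not among snapshots")
    hub_snapshot = by_id[hub]
    spokes = [s for s in snapshots if s.system_id != hub]

    spoke_hub: list[MatchRecord] = []
    for spoke in spokes:
        for config in configs:
            spoke_hub.extend(_run_config(spoke, hub_snapshot, config, graph))
    spoke_hub = _canonical(spoke_hub)

    # hub item -> spoke system -> {(spoke item, leg method)}
    legs: dict[str, dict[str, set[tuple[str, MatchMethod]]]] = {}
    for rec in spoke_hub:
        if rec.status is not MatchStatus.MATCH:
            continue
        legs.setdefault(rec.right.local_item_id, {}).setdefault(
            rec.left.system_id, set()
        ).add((rec.left.local_item_id, rec.method))

    spoke_spoke: list[MatchRecord] = []
    for hub_item, per_system in legs.items():
        systems = sorted(per_system)
        for i, sys_a in enumerate(systems):
            for sys_b in systems[i + 1 :]:
                for item_a, m_a in per_system[sys_a]:
                    for item_b, m_b in per_system[sys_b]:
                        via = (
                            f"hub:{hub}:{hub_item};"
                            f"left:{m_a.value};right:{m_b.value}"
                        )
                        spoke_spoke.append(
                            MatchRecord(
                                ItemRef(sys_a, item_a),
                                ItemRef(sys_b, item_b),
                                m_a,
                                via=via,
                            )
                        )
    return CrosswalkTable(hub, tuple(spoke_hub), tuple(_canonical(spoke_spoke)))


# ---------------------------------------------------------------------------
# TSV I/O

_CROSSWALK_COLUMNS = [
    "left_system",
    "left_item",
    "right_system",
    "right_item",
    "method",
    "via",
    "status",
]


def write_crosswalk(records: Iterable[MatchRecord], path: Path | str) -> None:
    rows = [
        {
            "left_system": r.left.system_id,
            "left_item": r.left.local_item_id,
            "right_system": r.right.system_id,
            "right_item": r.right.local_item_id,
            "method": r.method.value,
            "via": r.via or "",
            "status": r.status.value,
        }
        for r in _canonical(records)
    ]
    pd.DataFrame(rows, columns=_CROSSWALK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_crosswalk(path: Path | str) -> list[MatchRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _canonical(
        MatchRecord(
            ItemRef(r.left_system, r.left_item),
            ItemRef(r.right_system, r.right_item),
            MatchMethod(r.method),
            via=r.via or None,
            status=MatchStatus(r.status),
        )
        for r in df.itertuples(index=False)
    )
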