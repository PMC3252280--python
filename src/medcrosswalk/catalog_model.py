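"""Domain types for medication catalogs and patient-level records, plus
delimited-file readers/writers.

A *catalog* (formulary, charge master, cabinet item list) is a snapshot of
the orderable/billable items one system knows about.  Each entry carries the
system's own local id plus whatever foreign-system attributes that system
stores: the financial charge code (CC), the dispensing-cabinet dispense code
(DC), NDCs, and pharmacy-vocabulary codes (Multum drug code, main Multum
drug code MMDC, MediSpan GPI).  Patient-level activity comes in three
streams: medication orders (clinical systems), financial transactions
(charge postings) and lab results.

All files are UTF-8 TSV with a header row; the NDC list column is
comma-separated within the cell; empty cells denote absent attributes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError
from .ndc import is_normalized_ndc, normalize_ndc

__all__ = [
    "CatalogEntry",
    "CatalogSnapshot",
    "MedicationOrder",
    "FinancialTransaction",
    "LabResult",
    "normalize_code",
    "read_catalog",
    "write_catalog",
    "read_orders",
    "write_orders",
    "read_transactions",
    "write_transactions",
    "read_labs",
    "write_labs",
    "mark_in_use",
]

#: CatalogEntry attribute names that hold foreign-system / vocabulary codes.
CODE_ATTRIBUTES = (
    "charge_code",
    "dispense_code",
    "primary_ndc",
    "multum_drug_code",
    "mmdc",
    "gpi",
)


def normalize_code(code: str) -> str:
    """Canonical form used for every exact code comparison: surrounding
    whitespace trimmed, alphabetic characters case-folded."""
    return code.strip().casefold()


@dataclass(frozen=True)
class CatalogEntry:
    """One orderable/billable item in one system."""

    system_id: str
    local_item_id: str
    description: str = ""
    charge_code: Optional[str] = None
    dispense_code: Optional[str] = None
    primary_ndc: Optional[str] = None
    additional_ndcs: frozenset[str] = field(default_factory=frozenset)
    multum_drug_code: Optional[str] = None
    mmdc: Optional[str] = None
    gpi: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.local_item_id:
            raise IntegrityError("local_item_id must be non-empty")
        object.__setattr__(self, "additional_ndcs", frozenset(self.additional_ndcs))
        if self.primary_ndc is not None and not is_normalized_ndc(self.primary_ndc):
            raise IntegrityError(
                f"primary_ndc {self.primary_ndc!r} of item "
                f"{self.local_item_id!r} is not a normalized 11-digit NDC"
            )
        for ndc in self.additional_ndcs:
            if not is_normalized_ndc(ndc):
                raise IntegrityError(
                    f"additional NDC {ndc!r} of item {self.local_item_id!r} "
                    "is not a normalized 11-digit NDC"
                )
        if self.primary_ndc is not None and self.primary_ndc in self.additional_ndcs:
            raise IntegrityError(
                f"primary_ndc {self.primary_ndc!r} repeated in additional_ndcs "
                f"of item {self.local_item_id!r}"
            )

    @property
    def all_ndcs(self) -> frozenset[str]:
        """Primary plus additional NDCs (the item's raw NDC set)."""
        if self.primary_ndc is None:
            return self.additional_ndcs
        return self.additional_ndcs | {self.primary_ndc}

    def attribute(self, name: str) -> Optional[str]:
        """Return the named code attribute, or None when absent."""
        if name not in CODE_ATTRIBUTES and name != "description":
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class CatalogSnapshot:
    """A system's catalog at one point in time, with an optional record of
    which items were actually in use (referenced by activity) that year."""

    system_id: str
    snapshot_year: int
    entries: tuple[CatalogEntry, ...] = ()
    in_use_item_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "in_use_item_ids", frozenset(self.in_use_item_ids))
        if self.snapshot_year < 1900:
            raise IntegrityError(f"snapshot_year {self.snapshot_year} < 1900")
        seen: set[str] = set()
        for e in self.entries:
            if e.system_id != self.system_id:
                raise IntegrityError(
                    f"entry {e.local_item_id!r} belongs to system "
                    f"{e.system_id!r}, not {self.system_id!r}"
                )
            if e.local_item_id in seen:
                raise IntegrityError(
                    f"duplicate local_item_id {e.local_item_id!r} "
                    f"in system {self.system_id!r}"
                )
            seen.add(e.local_item_id)
        unknown = self.in_use_item_ids - seen
        if unknown:
            raise IntegrityError(
                f"in_use_item_ids not in catalog {self.system_id!r}: "
                f"{sorted(unknown)[:5]}"
            )

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def item_ids(self) -> frozenset[str]:
        return frozenset(e.local_item_id for e in self.entries)

    def entry(self, local_item_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.local_item_id == local_item_id:
                return e
        raise KeyError(local_item_id)


@dataclass(frozen=True)
class MedicationOrder:
    system_id: str
    patient_id: str
    encounter_id: str
    local_item_id: str
    order_date: _dt.date


@dataclass(frozen=True)
class FinancialTransaction:
    patient_id: str
    encounter_id: str
    charge_code: str
    post_date: _dt.date

    def __post_init__(self) -> None:
        if not self.charge_code:
            raise IntegrityError("charge_code must be non-empty")


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    encounter_id: str
    test_code: str
    value: float
    result_date: _dt.date

    def __post_init__(self) -> None:
        if not self.test_code:
            raise IntegrityError("test_code must be non-empty")


# ---------------------------------------------------------------------------
# delimited-file I/O

_CATALOG_COLUMNS = [
    "local_item_id",
    "description",
    "charge_code",
    "dispense_code",
    "primary_ndc",
    "additional_ndcs",
    "multum_drug_code",
    "mmdc",
    "gpi",
]


def _read_tsv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _opt(cell: str) -> Optional[str]:
    # empty cells are absent attributes, not empty codes
    cell = cell.strip()
    return cell or None


def read_catalog(
    path: Path | str, system_id: str, snapshot_year: int = 2009
) -> CatalogSnapshot:
    """Read a catalog TSV into a :class:`CatalogSnapshot`.

    NDC columns may be in raw dashed/11-digit form; they are normalized on
    the way in.  Rows with a duplicate ``local_item_id`` are rejected.
    """
    df = _read_tsv(path, ["local_item_id"])
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        item_id = str(getattr(row, "local_item_id")).strip()
        if item_id in seen:
            raise IntegrityError(
                f"{path}: duplicate local_item_id {item_id!r} "
                f"in system {system_id!r}"
            )
        seen.add(item_id)

        def cell(name: str) -> Optional[str]:
            return _opt(str(getattr(row, name))) if name in df.columns else None

        primary = cell("primary_ndc")
        additional_raw = cell("additional_ndcs")
        additional = frozenset(
            normalize_ndc(tok)
            for tok in (additional_raw or "").split(",")
            if tok.strip()
        )
        primary_norm = normalize_ndc(primary) if primary else None
        if primary_norm is not None:
            additional -= {primary_norm}
        entries.append(
            CatalogEntry(
                system_id=system_id,
                local_item_id=item_id,
                description=cell("description") or "",
                charge_code=cell("charge_code"),
                dispense_code=cell("dispense_code"),
                primary_ndc=primary_norm,
                additional_ndcs=additional,
                multum_drug_code=cell("multum_drug_code"),
                mmdc=cell("mmdc"),
                gpi=cell("gpi"),
            )
        )
    return CatalogSnapshot(system_id, snapshot_year, tuple(entries))


def write_catalog(snapshot: CatalogSnapshot, path: Path | str) -> None:
    """Write a snapshot as a catalog TSV (inverse of :func:`read_catalog`)."""
    rows = []
    for e in snapshot.entries:
        rows.append(
            {
                "local_item_id": e.local_item_id,
                "description": e.description,
                "charge_code": e.charge_code or "",
                "dispense_code": e.dispense_code or "",
                "primary_ndc": e.primary_ndc or "",
                "additional_ndcs": ",".join(sorted(e.additional_ndcs)),
                "multum_drug_code": e.multum_drug_code or "",
                "mmdc": e.mmdc or "",
                "gpi": e.gpi or "",
            }
        )
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_orders(path: Path | str) -> list[MedicationOrder]:
    df = _read_tsv(
        path, ["system_id", "patient_id", "encounter_id", "local_item_id", "order_date"]
    )
    return [
        MedicationOrder(
            r.system_id, r.patient_id, r.encounter_id, r.local_item_id,
            _dt.date.fromisoformat(r.order_date),
        )
        for r in df.itertuples(index=False)
    ]


def write_orders(orders: Iterable[MedicationOrder], path: Path | str) -> None:
    rows = [
        {
            "system_id": o.system_id,
            "patient_id": o.patient_id,
            "encounter_id": o.encounter_id,
            "local_item_id": o.local_item_id,
            "order_date": o.order_date.isoformat(),
        }
        for o in orders
    ]
    pd.DataFrame(
        rows,
        columns=["system_id", "patient_id", "encounter_id", "local_item_id", "order_date"],
    ).to_csv(path, sep="\t", index=False)


def read_transactions(path: Path | str) -> list[FinancialTransaction]:
    df = _read_tsv(path, ["patient_id", "encounter_id", "charge_code", "post_date"])
    return [
        FinancialTransaction(
            r.patient_id, r.encounter_id, r.charge_code,
            _dt.date.fromisoformat(r.post_date),
        )
        for r in df.itertuples(index=False)
    ]


def write_transactions(
    transactions: Iterable[FinancialTransaction], path: Path | str
) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "encounter_id": t.encounter_id,
            "charge_code": t.charge_code,
            "post_date": t.post_date.isoformat(),
        }
        for t in transactions
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "encounter_id", "charge_code", "post_date"]
    ).to_csv(path, sep="\t", index=False)


def read_labs(path: Path | str) -> list[LabResult]:
    df = _read_tsv(
        path, ["patient_id", "encounter_id", "test_code", "value", "result_date"]
    )
    return [
        LabResult(
            r.patient_id, r.encounter_id, r.test_code, float(r.value),
            _dt.date.fromisoformat(r.result_date),
        )
        for r in df.itertuples(index=False)
    ]


def write_labs(labs: Iterable[LabResult], path: Path | str) -> None:
    rows = [
        {
            "patient_id": l.patient_id,
            "encounter_id": l.encounter_id,
            "test_code": l.test_code,
            "value": repr(l.value),
            "result_date": l.result_date.isoformat(),
        }
        for l in labs
    ]
    pd.DataFrame(
        rows, columns=["patient_id", "encounter_id", "test_code", "value", "result_date"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------


def mark_in_use(
    snapshot: CatalogSnapshot,
    orders: Iterable[MedicationOrder] = (),
    transactions: Iterable[FinancialTransaction] = (),
    year: int | None = None,
) -> CatalogSnapshot:
    """Return a copy of *snapshot* with ``in_use_item_ids`` computed from
    activity records dated within the given calendar *year*.

    An item is in use if at least one medication order in this system
    references it (clinical systems), or if its charge code appears in at
    least one financial transaction (financial system).  ``year`` defaults
    to the snapshot year.
    """
    if year is None:
        year = snapshot.snapshot_year
    in_use: set[str] = set()
    item_ids = snapshot.item_ids
    for o in orders:
        if (
            o.system_id == snapshot.system_id
            and o.order_date.year == year
            and o.local_item_id in item_ids
        ):
            in_use.add(o.local_item_id)
    by_charge: dict[str, list[str]] = {}
    for e in snapshot.entries:
        if e.charge_code is not None:
            by_charge.setdefault(normalize_code(e.charge_code), []).append(
                e.local_item_id
            )
    if by_charge:
        for t in transactions:
            if t.post_date.year != year:
                continue
            for item in by_charge.get(normalize_code(t.charge_code), ()):
                in_use.add(item)
    return dataclasses.replace(snapshot, in_use_item_ids=frozenset(in_use))
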