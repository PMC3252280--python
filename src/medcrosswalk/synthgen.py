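"""Ground-truthed synthetic multi-system medication world.

The generator emulates the data landscape the package integrates: a shared
universe of drugs, three synthetic pharmacy vocabularies with consistent
cross-links (a Multum-like, an RxNorm-like and a MediSpan-like layer), four
system catalogs (a hub inpatient EHR, a historical inpatient pharmacy
module, an outpatient EHR and a financial charge master), and patient-level
activity (orders, charge postings, lab results) with a planted cohort.

Configurable imperfections reproduce the failure modes seen in real
integrations:

* duplicated financial codes — a drug billed under more than one charge code;
* conflicts — a charge code wrongly attached to a second drug's orderable,
  which the MMDC consistency rule should flag as a mismatch;
* obsolete NDCs — package codes absent from a vocabulary's concept tables;
* compounded items — hub orderables with no NDC or Multum codes at all;
* divergent primary NDCs — a non-hub system recording a different package
  of the same drug as its representative NDC;
* charge-capture gaps — eligible patients whose qualifying order never
  posted a financial transaction;
* criteria violations — patients whose medication order and lab result fall
  in different encounters.

Every injected imperfection is recorded in a :class:`GroundTruth` ledger so
that detectors and cohort selectors can be scored exactly.  All randomness
flows from one generator seeded by ``SynthConfig.seed``, with the world
drawn before the activity, so enlarging the population never perturbs the
catalogs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .catalog_model import (
    CatalogEntry,
    CatalogSnapshot,
    FinancialTransaction,
    LabResult,
    MedicationOrder,
    mark_in_use,
)
from .enrichment import MEDISPAN, MULTUM, RXNORM
from .errors import ValidationError
from .vocab_graph import CrossVocabLink, LinkBasis, TermType, VocabGraph, VocabularyConcept

__all__ = [
    "INPATIENT",
    "HISTORICAL",
    "OUTPATIENT",
    "FINANCIAL",
    "SystemSpec",
    "SynthConfig",
    "GroundTruth",
    "SynthWorld",
    "generate_world",
]

INPATIENT = "INPATIENT_EHR"
HISTORICAL = "HISTORICAL_PM"
OUTPATIENT = "OUTPATIENT_EHR"
FINANCIAL = "FINANCIAL"

#: attributes each clinical system carries (mirrors which vocabularies and
#: metadata each real system supported)
_SYSTEM_ATTRIBUTES = {
    INPATIENT: ("charge_code", "dispense_code", "primary_ndc", "multum_drug_code", "mmdc"),
    HISTORICAL: ("charge_code", "dispense_code", "primary_ndc"),
    OUTPATIENT: ("primary_ndc", "gpi"),
}


@dataclass(frozen=True)
class SystemSpec:
    """Coverage and per-attribute missingness of one clinical system."""

    system_id: str
    coverage: float = 1.0
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "missingness", dict(self.missingness))
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError(f"coverage {self.coverage} outside [0, 1]")
        for attr, rate in self.missingness.items():
            if attr not in _SYSTEM_ATTRIBUTES.get(self.system_id, ()):
                raise ValidationError(
                    f"system {self.system_id!r} has no attribute {attr!r}"
                )
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"missingness {attr}={rate} outside [0, 1]")


def default_systems() -> tuple[SystemSpec, ...]:
    return (
        SystemSpec(INPATIENT, coverage=1.0),
        SystemSpec(
            HISTORICAL,
            coverage=0.85,
            missingness={"charge_code": 0.10, "dispense_code": 0.02, "primary_ndc": 0.05},
        ),
        SystemSpec(OUTPATIENT, coverage=0.75, missingness={"primary_ndc": 0.02}),
    )


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 500
    systems: tuple[SystemSpec, ...] = field(default_factory=default_systems)
    p_duplicate_financial: float = 0.10
    p_conflict: float = 0.01
    p_obsolete_ndc: float = 0.05
    p_compounded: float = 0.03
    p_alt_primary_ndc: float = 0.20
    p_charge_gap: float = 0.05
    p_criteria_violation: float = 0.05
    n_patients: int = 1000
    encounters_per_patient: int = 2
    orders_per_encounter: int = 2
    target_prevalence: float = 0.10
    target_drug: int = 0
    snapshot_year: int = 2009
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_duplicate_financial": self.p_duplicate_financial,
            "p_conflict": self.p_conflict,
            "p_obsolete_ndc": self.p_obsolete_ndc,
            "p_compounded": self.p_compounded,
            "p_alt_primary_ndc": self.p_alt_primary_ndc,
            "p_charge_gap": self.p_charge_gap,
            "p_criteria_violation": self.p_criteria_violation,
            "target_prevalence": self.target_prevalence,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        counts = {
            "n_drugs": self.n_drugs,
            "n_patients": self.n_patients,
            "encounters_per_patient": self.encounters_per_patient,
            "orders_per_encounter": self.orders_per_encounter,
        }
        for name, n in counts.items():
            if n < 0:
                raise ValidationError(f"{name}={n} must be >= 0")
        if self.n_drugs and not 0 <= self.target_drug < self.n_drugs:
            raise ValidationError(
                f"target_drug {self.target_drug} outside [0, {self.n_drugs})"
            )
        ids = [s.system_id for s in self.systems]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate system ids {ids}")

    @classmethod
    def noiseless(cls, **overrides) -> "SynthConfig":
        """All imperfection rates zero and full coverage everywhere: the
        limit in which every crosswalk should equal the identity relation."""
        systems = tuple(
            SystemSpec(s.system_id, coverage=1.0, missingness={})
            for s in overrides.pop("systems", default_systems())
        )
        zeros = dict(
            p_duplicate_financial=0.0,
            p_conflict=0.0,
            p_obsolete_ndc=0.0,
            p_compounded=0.0,
            p_alt_primary_ndc=0.0,
            p_charge_gap=0.0,
            p_criteria_violation=0.0,
        )
        zeros.update(overrides)
        return cls(systems=systems, **zeros)


@dataclass(frozen=True)
class GroundTruth:
    """Identity map and imperfection ledgers, used only for scoring."""

    item_to_drug: Mapping[tuple[str, str], int]
    charge_code_to_drug: Mapping[str, int]
    conflict_ledger: frozenset[str]
    duplicate_ledger: frozenset[str]
    obsolete_ndcs: frozenset[tuple[str, str]]  # (ndc, vocabulary)
    compounded_items: frozenset[tuple[str, str]]
    eligibility_ledger: frozenset[str]
    violation_ledger: frozenset[str]
    gap_ledger: frozenset[str]
    target_drug: int
    target_concepts: frozenset[tuple[str, str]]
    drug_names: Mapping[int, str] = field(default_factory=dict)

    def items_of(self, system_id: str) -> dict[str, int]:
        return {
            item: drug
            for (system, item), drug in self.item_to_drug.items()
            if system == system_id
        }

    def true_pairs(self, left_system: str, right_system: str) -> frozenset[tuple[str, str]]:
        """All (left item, right item) pairs denoting the same drug."""
        right_by_drug: dict[int, list[str]] = {}
        for item, drug in self.items_of(right_system).items():
            right_by_drug.setdefault(drug, []).append(item)
        pairs = set()
        for item, drug in self.items_of(left_system).items():
            for r in right_by_drug.get(drug, ()):
                pairs.add((item, r))
        return frozenset(pairs)


@dataclass(frozen=True)
class SynthWorld:
    config: SynthConfig
    graph: VocabGraph
    snapshots: Mapping[str, CatalogSnapshot]
    orders: tuple[MedicationOrder, ...]
    transactions: tuple[FinancialTransaction, ...]
    labs: tuple[LabResult, ...]
    truth: GroundTruth

    def marked_snapshots(self, year: Optional[int] = None) -> dict[str, CatalogSnapshot]:
        """Snapshots with in-use sets computed from this world's activity
        (orders for clinical systems, transactions for the financial one)."""
        out = {}
        for system, snap in self.snapshots.items():
            if system == FINANCIAL:
                out[system] = mark_in_use(snap, transactions=self.transactions, year=year)
            else:
                out[system] = mark_in_use(snap, orders=self.orders, year=year)
        return out


# ---------------------------------------------------------------------------


def _ndc(drug: int, package: int) -> str:
    labeler = (10000 + drug) % 100000
    return f"{labeler:05d}{package:04d}01"


def _drug_name(drug: int, target: int) -> str:
    return "WARFARIN" if drug == target else f"DRUG{drug:04d}"


def _description(drug: int, target: int) -> str:
    dose = (1, 2, 5, 10)[drug % 4]
    return f"{_drug_name(drug, target)} {dose} MG ORAL TABLET"


def _charge_code(drug: int) -> str:
    return f"{7000000 + drug}"


def _dup_charge_code(drug: int) -> str:
    return f"{7500000 + drug}"


def _dispense_code(drug: int, target: int) -> str:
    if drug == target:
        return "WARF5TU"
    return f"DC{drug:05d}"


def _mmdc(drug: int) -> str:
    return f"{3000 + drug}"


def _drugcode(drug: int) -> str:
    return f"d{drug:05d}"


def _rx_cd(drug: int) -> str:
    return f"{800000 + 2 * drug}"


def _rx_gn(drug: int) -> str:
    return f"{800001 + 2 * drug}"


def _gpi(drug: int) -> str:
    return f"{60000 + drug}"


def generate_world(config: SynthConfig) -> SynthWorld:
    """Generate vocabularies, catalogs, activity and ground truth.

    Fully reproducible for a given ``config.seed``; the draw order is
    vocabularies, catalogs, then activity.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_drugs
    target = config.target_drug
    year = config.snapshot_year

    # ---- drug universe and NDC pools -------------------------------------
    pools: list[tuple[str, ...]] = []
    for i in range(n):
        n_pkgs = 3 + int(rng.integers(0, 2))
        pools.append(tuple(_ndc(i, k) for k in range(n_pkgs)))

    # ---- vocabularies ------------------------------------------------------
    obsolete: set[tuple[str, str]] = set()
    vocab_ndcs: dict[str, list[frozenset[str]]] = {}
    for vocab in (MULTUM, RXNORM, MEDISPAN):
        per_drug = []
        for i in range(n):
            kept = set(pools[i])
            if config.p_obsolete_ndc > 0:
                for ndc in pools[i]:
                    if rng.random() < config.p_obsolete_ndc:
                        obsolete.add((ndc, vocab))
                        kept.discard(ndc)
            per_drug.append(frozenset(kept))
        vocab_ndcs[vocab] = per_drug

    concepts: list[VocabularyConcept] = []
    links: list[CrossVocabLink] = []
    for i in range(n):
        concepts += [
            VocabularyConcept(MULTUM, _mmdc(i), TermType.MMDC, vocab_ndcs[MULTUM][i]),
            VocabularyConcept(MULTUM, _drugcode(i), TermType.DRUGCODE, vocab_ndcs[MULTUM][i]),
            VocabularyConcept(RXNORM, _rx_cd(i), TermType.CD, vocab_ndcs[RXNORM][i]),
            VocabularyConcept(RXNORM, _rx_gn(i), TermType.GN, vocab_ndcs[RXNORM][i]),
            VocabularyConcept(MEDISPAN, _gpi(i), TermType.GPI, vocab_ndcs[MEDISPAN][i]),
        ]
        links += [
            CrossVocabLink((MULTUM, _mmdc(i)), (RXNORM, _rx_cd(i)), LinkBasis.CD),
            CrossVocabLink((MULTUM, _drugcode(i)), (RXNORM, _rx_gn(i)), LinkBasis.GN),
            CrossVocabLink((RXNORM, _rx_cd(i)), (MEDISPAN, _gpi(i)), LinkBasis.CD),
        ]
    graph = VocabGraph(concepts, links)

    # ---- financial charge codes: duplication and conflicts ----------------
    charge_code_to_drug: dict[str, int] = {}
    duplicate_ledger: set[str] = set()
    for i in range(n):
        charge_code_to_drug[_charge_code(i)] = i
        if rng.random() < config.p_duplicate_financial:
            charge_code_to_drug[_dup_charge_code(i)] = i
            duplicate_ledger.add(_dup_charge_code(i))
    conflict_ledger: set[str] = set()
    conflict_victims: dict[str, int] = {}
    if n > 1:
        for i in range(n):
            if rng.random() < config.p_conflict:
                cc = _charge_code(i)
                victim = int((i + 1 + rng.integers(0, n - 1)) % n)
                conflict_ledger.add(cc)
                conflict_victims[cc] = victim

    # ---- catalogs ----------------------------------------------------------
    item_to_drug: dict[tuple[str, str], int] = {}
    compounded_items: set[tuple[str, str]] = set()
    snapshots: dict[str, CatalogSnapshot] = {}

    def item_id(system: str, drug: int) -> str:
        prefix = {INPATIENT: "INP", HISTORICAL: "HIS", OUTPATIENT: "OUT"}[system]
        base = {INPATIENT: 17000000, HISTORICAL: 20000, OUTPATIENT: 30000}[system]
        return f"{prefix}{base + drug}"

    for spec in config.systems:
        system = spec.system_id
        attrs = _SYSTEM_ATTRIBUTES[system]
        entries: list[CatalogEntry] = []
        covered = rng.random(n) < spec.coverage
        if system == INPATIENT and n:
            covered[target] = True
        for i in range(n):
            if not covered[i]:
                continue
            # each system lists only a subset of the drug's package codes:
            # the hub records the first two, a spoke records a single one —
            # possibly a later package the hub does not list, in which case
            # only the vocabulary's related-NDC closure can bridge the two
            pool = pools[i]
            if system != INPATIENT and len(pool) > 2 and rng.random() < config.p_alt_primary_ndc:
                primary = pool[2 + int(rng.integers(0, len(pool) - 2))]
            else:
                primary = pool[0]
            additional = frozenset({pool[1]}) if system == INPATIENT else frozenset()
            values: dict[str, Optional[str]] = {
                "charge_code": _charge_code(i),
                "dispense_code": _dispense_code(i, target),
                "primary_ndc": primary,
                "multum_drug_code": _drugcode(i),
                "mmdc": _mmdc(i),
                "gpi": _gpi(i),
            }
            compounded = system == INPATIENT and rng.random() < config.p_compounded
            for attr in list(values):
                if attr not in attrs:
                    values[attr] = None
            for attr, rate in spec.missingness.items():
                if values.get(attr) is not None and rng.random() < rate:
                    values[attr] = None
            description = _description(i, target)
            if compounded:
                values["primary_ndc"] = None
                values["multum_drug_code"] = None
                values["mmdc"] = None
                additional = frozenset()
                description += " COMPOUNDED PREP"
            iid = item_id(system, i)
            entries.append(
                CatalogEntry(
                    system_id=system,
                    local_item_id=iid,
                    description=description,
                    charge_code=values["charge_code"],
                    dispense_code=values["dispense_code"],
                    primary_ndc=values["primary_ndc"],
                    additional_ndcs=additional if values["primary_ndc"] else frozenset(),
                    multum_drug_code=values["multum_drug_code"],
                    mmdc=values["mmdc"],
                    gpi=values["gpi"],
                )
            )
            item_to_drug[(system, iid)] = i
            if compounded:
                compounded_items.add((system, iid))
        if system == INPATIENT:
            # conflict extras: a second orderable wrongly carrying cc
            for k, cc in enumerate(sorted(conflict_ledger)):
                victim = conflict_victims[cc]
                iid = f"INPX{18000000 + k}"
                entries.append(
                    CatalogEntry(
                        system_id=system,
                        local_item_id=iid,
                        description=_description(victim, target),
                        charge_code=cc,
                        dispense_code=None,
                        primary_ndc=pools[victim][0],
                        additional_ndcs=frozenset({pools[victim][1]}),
                        multum_drug_code=_drugcode(victim),
                        mmdc=_mmdc(victim),
                    )
                )
                item_to_drug[(system, iid)] = victim
        snapshots[system] = CatalogSnapshot(system, year, tuple(entries))

    fin_entries = []
    for cc in sorted(charge_code_to_drug):
        drug = charge_code_to_drug[cc]
        fin_entries.append(
            CatalogEntry(
                system_id=FINANCIAL,
                local_item_id=cc,
                description=_description(drug, target),
                charge_code=cc,
            )
        )
        item_to_drug[(FINANCIAL, cc)] = drug
    snapshots[FINANCIAL] = CatalogSnapshot(FINANCIAL, year, tuple(fin_entries))

    # ---- patient-level activity -------------------------------------------
    orders: list[MedicationOrder] = []
    transactions: list[FinancialTransaction] = []
    labs: list[LabResult] = []
    eligibility: set[str] = set()
    violations: set[str] = set()
    gaps: set[str] = set()

    n_eligible = int(round(config.target_prevalence * config.n_patients))
    eligible_idx = set(
        int(i)
        for i in rng.choice(config.n_patients, size=n_eligible, replace=False)
    ) if config.n_patients else set()

    historical_has_target = (HISTORICAL, item_id(HISTORICAL, target)) in item_to_drug

    def rand_date() -> _dt.date:
        return _dt.date(year, 1 + int(rng.integers(0, 12)), 1 + int(rng.integers(0, 28)))

    def order_and_post(patient: str, encounter: str, system: str, drug: int,
                       post: bool = True) -> None:
        iid = item_id(system, drug)
        if (system, iid) not in item_to_drug:
            return
        d = rand_date()
        orders.append(MedicationOrder(system, patient, encounter, iid, d))
        if post:
            transactions.append(
                FinancialTransaction(patient, encounter, _charge_code(drug), d)
            )

    def background_drug() -> int:
        if n <= 1:
            return target
        return int((target + 1 + rng.integers(0, n - 1)) % n)

    for p in range(config.n_patients):
        patient = f"P{p:06d}"
        encounters = [f"E{p:06d}-{k}" for k in range(max(1, config.encounters_per_patient))]
        is_eligible = p in eligible_idx
        is_violator = (
            not is_eligible
            and len(encounters) > 1
            and rng.random() < config.p_criteria_violation
        )
        if is_eligible:
            enc = encounters[0]
            system = (
                HISTORICAL
                if historical_has_target and rng.random() < 0.5
                else INPATIENT
            )
            gap = rng.random() < config.p_charge_gap
            order_and_post(patient, enc, system, target, post=not gap)
            if gap:
                gaps.add(patient)
            labs.append(
                LabResult(patient, enc, "INR", float(np.round(rng.normal(2.5, 0.5), 2)),
                          rand_date())
            )
            eligibility.add(patient)
        elif is_violator:
            order_and_post(patient, encounters[0], INPATIENT, target)
            labs.append(
                LabResult(patient, encounters[1], "INR",
                          float(np.round(rng.normal(2.5, 0.5), 2)), rand_date())
            )
            violations.add(patient)
        # background activity in the remaining encounters
        start = 1 if (is_eligible or is_violator) else 0
        for enc in encounters[start:]:
            for _ in range(config.orders_per_encounter):
                if n > 1:
                    system = HISTORICAL if rng.random() < 0.3 else INPATIENT
                    drug = background_drug()
                    if (system, item_id(system, drug)) not in item_to_drug:
                        system = INPATIENT
                    order_and_post(patient, enc, system, drug)
            labs.append(
                LabResult(patient, enc, "GLU",
                          float(np.round(rng.normal(95.0, 10.0), 1)), rand_date())
            )

    truth = GroundTruth(
        item_to_drug=item_to_drug,
        charge_code_to_drug=charge_code_to_drug,
        conflict_ledger=frozenset(conflict_ledger),
        duplicate_ledger=frozenset(duplicate_ledger),
        obsolete_ndcs=frozenset(obsolete),
        compounded_items=frozenset(compounded_items),
        eligibility_ledger=frozenset(eligibility),
        violation_ledger=frozenset(violations),
        gap_ledger=frozenset(gaps),
        target_drug=target,
        target_concepts=frozenset({(RXNORM, _rx_cd(target))}),
        drug_names={i: _drug_name(i, target) for i in range(n)},
    )
    return SynthWorld(
        config=config,
        graph=graph,
        snapshots=snapshots,
        orders=tuple(orders),
        transactions=tuple(transactions),
        labs=tuple(labs),
        truth=truth,
    )
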