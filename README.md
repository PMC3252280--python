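# medcrosswalk

Hospitals that migrate between electronic health record (EHR) systems are
left with years of medication data in semantically poor formats: a financial
charge master whose codes have no formal drug definitions, a decommissioned
inpatient pharmacy module whose vocabulary codes were never exported, an
outpatient system on a different commercial vocabulary.  `medcrosswalk` is a
library + CLI for researchers and clinical-informatics teams who need to
integrate such catalogs and reuse the data for retrospective studies.

It implements two families of automated catalog integration, with a
designated *hub* system (the current inpatient EHR, the system carrying the
most attributes) anchoring all crosswalks:

* **Metadata-based matching** — exact matching on administrative codes that
  were copied between systems to support automated charge capture and
  cabinet messaging: the financial *charge code* (CC) and the dispensing
  system's *dispense code* (DC).
* **Vocabulary-based matching** — exact matching on the 11-digit normalized
  National Drug Code (NDC), either on each item's primary/representative
  NDC, or after expanding it to its *related-NDC closure* through a pharmacy
  vocabulary (Multum-, MediSpan- or RxNorm-style concept tables):
  `related(n) = {n} ∪ ⋃ {ndcs(c) : concept c contains n}`.

On top of the crosswalks it provides:

* **Semantic enrichment** of financial charge codes with controlled-
  terminology (CMT) concepts through the matched inpatient orderable
  (charge code → item → MMDC/drug code/NDC → RxNorm concept), with full
  provenance paths;
* **Mismatch detection** — a charge code whose matched orderables carry more
  than one distinct main Multum drug code (MMDC) denotes more than one
  drug/dose/route/form and is disqualified from enrichment;
* **Cohort selection** across systems by CMT concept set or description
  search, with a lab-test constraint that may be required within the same
  encounter (e.g. warfarin order + INR measurement);
* A **ground-truthed synthetic world generator** (drug universe,
  vocabularies, catalogs, patient-level activity) with configurable
  imperfections — duplicated and conflicting charge codes, obsolete NDCs,
  compounded items, charge-capture gaps — each recorded in a ledger so
  detectors and cohorts can be scored exactly;
* **Reporting**: per-method match percentages over the complete reference
  catalog vs the codes actually used in a calendar year, and
  precision/recall scoring against synthetic ground truth.

## Worked example

The bundled `figures34` fixture is a three-system micro-world around one
drug, *warfarin 5 mg oral tablet*: the financial system bills it under
charge code 7056345; the current inpatient catalog carries it as item
17362344 with that charge code, dispense code WARF5TU, Multum drug code
d00022, MMDC 3616 and NDCs 00056-0172-75 / 00832-1216-01; the historical
pharmacy module knows only the dispense code and an NDC.

```python
from medcrosswalk import (
    figures34, initial_match_financial, enrich_charge_codes,
    match_by_metadata, EnrichmentStrategy,
)

fx = figures34()
matches = initial_match_financial(fx.financial, fx.inpatient)
(code,) = enrich_charge_codes(matches, fx.inpatient, fx.graph,
                              EnrichmentStrategy.VIA_MMDC_CD)
(dc,) = match_by_metadata(fx.historical, fx.inpatient, "DISPENSE_CODE")
```

prints (via the assignments and records):

```text
charge 7056345 -> INPATIENT_EHR:17362344 [MATCH]
charge 7056345 enriched with RXNORM 855332 (CD)
path: CC:7056345 -> INPATIENT_EHR:17362344 -> MULTUM:3616 -> RXNORM:855332
historical WARF5TU -> 17362344 by DISPENSE_CODE
```

Reading it: the initial charge-code match ties the financial code 7056345
to the inpatient warfarin orderable; through that item's MMDC 3616 the
RxNorm clinical-drug concept 855332 is assigned to the charge code, so any
financial transaction posting 7056345 can now be queried by RxNorm concept;
and the historical orderable joins the same item by its shared dispense
code, so one concept query spans financial, historical and current data.

The same pipeline runs from the shell:

```bash
medcrosswalk simulate --out world/ --seed 1
medcrosswalk crosswalk --dir world/ --left HISTORICAL_PM \
    --hub INPATIENT_EHR --method dispense_code --out world/xwalk.tsv
medcrosswalk enrich --dir world/ --out world/enriched.tsv
medcrosswalk report --dir world/ --left HISTORICAL_PM
```

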