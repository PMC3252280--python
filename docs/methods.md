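# Methods

## The integration model

Each hospital system is modelled as a catalog of items (orderables in an
EHR formulary, billable line items in the charge master), where an item
carries the system's own local id plus *copies* of foreign-system
identifiers: the financial charge code, the dispensing-cabinet dispense
code, NDCs, and pharmacy-vocabulary codes (Multum drug code, main Multum
drug code MMDC, MediSpan GPI).  The modelling assumption — inherited from
how automated charge capture and HL7 cabinet messaging actually work — is
that each code has exactly one *source-of-truth* system, and every other
system stores a faithful copy of it as an attribute.  Matching is therefore
exact: two items are asserted equivalent when they reference the same
foreign entity.  No fuzzy or probabilistic linkage is attempted anywhere;
where the copies are unfaithful the right behaviour is to flag, not guess.

All multi-system integration goes through a hub (the current inpatient
catalog, which carries the most attributes).  Spoke-to-spoke equivalences
are derived only through a single shared hub item, never by multi-hub
chaining, so every derived pair has a two-leg provenance that can be
audited.

### NDC normalization

All NDC equality tests happen on the 11-digit 5-4-2 form.  Dashed 10-digit
codes (4-4-2, 5-3-2, 5-4-1) are zero-padded per segment, the HIPAA
convention.  Undashed 10-digit codes are *rejected* rather than guessed:
the deficient segment cannot be located, all three completions are distinct
valid codes, and a silent wrong guess would corrupt every downstream match.

### Related-NDC matching

`related(n)` through a vocabulary is `{n}` united with the NDC sets of
every concept containing `n`.  The input is always included, which makes
primary-NDC matches a provable subset of related-NDC matches — the
monotonicity the match-percentage tables exhibit.  Expansion is one-sided:
the left item's primary NDC is expanded and intersected with the right
item's raw NDC set.  Expanding both sides would match more pairs but the
provenance would no longer be a single mediating concept; one-sided
expansion keeps every match auditable and is cheaper.  Cross-vocabulary
links are traversed bidirectionally and one hop at a time; multi-hop chains
must be composed explicitly by the caller, again for provenance clarity.

### Mismatch rule

Records are grouped by left item (for the financial catalog, by charge
code).  A group whose hub items carry more than one distinct non-absent
discriminator value — MMDC by default, i.e. more than one distinct
drug/dose/route/form — is demoted wholesale to MISMATCH and excluded from
enrichment and from match-statistic numerators; the mismatch rate is
reported as its own row.  A group matching several hub items that share one
discriminator value stays matched and counts once (statistics are % of
items, not pairs).

### Enrichment

Four strategies assign CMT concepts to a charge code through its matched
inpatient orderable: MMDC → RxNorm CD link; Multum drug code → RxNorm GN
link; primary NDC resolved among RxNorm CD concepts; NDCs expanded through
Multum then resolved in RxNorm.  Every assignment stores an ordered path
(`CC:… -> system:item -> MULTUM:… -> RXNORM:…`) that `replay_path` can
re-verify against the vocabulary graph.  A charge code whose item lacks a
strategy's source attribute (compounded preparations have no single NDC or
MMDC) legitimately yields no assignment — this is why enriched percentages
sit below initial-match percentages.  When one strategy yields several
distinct concepts the code is flagged ambiguous and all candidates are
retained for expert review rather than dropped.

### Cohorts

A criterion pairs one medication specification — a CMT concept set, or a
case-insensitive substring of the catalog description (the minimal reading
of "search by description") — with a lab-test code and a same-encounter
flag.  Concept queries are expanded to per-system local codes: charge codes
via the enrichment assignments, hub items via the assignments' provenance
paths, spoke items via the hub crosswalk.  Clinical sources qualify a
patient through orders, the financial source through transactions joined to
enriched charge codes at query time (the catalog is enriched, never the
transaction ledger — transactions are voluminous and the join is cheap).
Encounter identity is a shared opaque key; no date-window fallback is
implemented.

### "Codes used"

An item is *in use* in a calendar year when at least one medication order
references it (clinical systems) or its charge code appears in at least one
posted transaction (financial system).  The year is an explicit parameter.
Orders — not dispenses or charges — define clinical use; this is an
interpretation, and the in-use machinery accepts whichever activity stream
the caller passes.  Codes are compared after whitespace trimming and
case-folding; empty cells in input tables are absent attributes, not empty
codes.

## The synthetic world

`synthgen.generate_world` builds a drug universe, three synthetic
vocabularies with consistent cross-links, four catalogs and patient-level
activity, with every imperfection recorded in a `GroundTruth` ledger.
Synthetic vocabulary and item identifiers use their own number ranges; only
the bundled `figures34` fixture uses the worked example's literal values.

What it emulates, and the defaults:

| knob | default | what it models |
|---|---|---|
| `n_drugs` | 500 | formulary size |
| coverage (historical / outpatient) | 0.85 / 0.75 | spokes carry a subset of the hub formulary |
| missingness (historical CC/DC/NDC) | 0.10 / 0.02 / 0.05 | attributes lost in the final decommission snapshot |
| `p_duplicate_financial` | 0.10 | one drug billed under several charge codes (revenue-line duplication) |
| `p_conflict` | 0.01 | a charge code wrongly attached to a second drug's orderable (the 0.69–1.15% regime) |
| `p_obsolete_ndc` | 0.05 | package codes absent from a vocabulary release |
| `p_compounded` | 0.03 | hub items with no NDC/Multum codes |
| `p_alt_primary_ndc` | 0.20 | a spoke records a package the hub does not list |
| `p_charge_gap` | 0.05 | qualifying orders that never posted a charge |
| `p_criteria_violation` | 0.05 | order and lab in different encounters |
| `n_patients`, `target_prevalence` | 1000, 0.10 | population and planted cohort fraction |

Each drug has 3–4 package NDCs; the hub lists the first two, a spoke lists
exactly one — under `p_alt_primary_ndc` a *later* package the hub does not
list, so only the vocabulary closure can bridge the pair and obsolete NDCs
genuinely depress vocabulary-method recall.  The per-system attribute
profiles mirror the integration setting: the hub carries everything, the
historical module has metadata and NDCs but no vocabulary codes, the
outpatient system has NDCs and GPI only, the financial catalog only charge
codes.

All randomness flows from one `numpy` generator seeded by `config.seed`,
drawn in a fixed order (vocabularies, catalogs, activity), so worlds are
bit-reproducible and enlarging the population never perturbs the catalogs.
The planted cohort is exact, not binomial: `round(prevalence·n_patients)`
patients receive a target-drug order with a same-encounter INR; violators
get the order and the lab in different encounters; gap patients are
eligible patients whose order posts no transaction.  Background patients
order non-target drugs and receive non-INR labs only, so the eligibility
ledger is exactly the qualifying set.

What the generator does **not** emulate: realistic pharmacologic
distributions, dose/route/form structure inside a drug, multi-ingredient
compounds with partial codes, coding drift over time, HL7 message
artifacts, or free-text idiosyncrasies in descriptions (descriptions are
deterministic functions of the drug, which is what makes the
description-vs-concept cohort agreement provable rather than merely
plausible).  Passing tests on this world therefore demonstrate the
*mechanics* — matching, detection, provenance, set arithmetic — not
performance on real catalogs, where description search and exact matching
degrade for reasons the generator deliberately excludes.

## Numerical and design choices

* Matching and detection are pure set operations; records are de-duplicated
  and canonically sorted, so outputs are independent of input row order.
* Percentages are reported to two decimals; zero denominators are flagged
  (`None` / `n/a`), never divided.  Precision of an empty crosswalk is
  undefined (`None`), its recall 0.
* Mismatch parameter-recovery checks run with all other imperfection rates
  at zero: MMDC missingness or compounding on a conflicted item hides the
  second MMDC from any detector, so exact ledger equality is only a
  meaningful target in the clean regime.
* Statistical calibration of the generator is asserted via 99% binomial
  intervals at `n_drugs ≥ 500`-scale worlds.
* Problem sizes in the test suite (worlds of 40–2000 drugs, populations up
  to 5000 patients, 50–100 random configurations per property) were chosen
  as the smallest scales at which the binomial checks are informative and
  the brute-force oracles stay trivially cheap.

## Known limitations

* The mismatch rule keys on a single discriminator attribute; real reviews
  also weigh dose/route/form fields separately.
* `expand_cmt_query` reaches clinical systems only through enrichment
  provenance plus the hub crosswalk; a hub item whose charge code is
  mismatched (or absent) cannot anchor a concept query even if its own
  vocabulary codes are intact.
* Description-mode cohort search is substring matching; no term lists,
  stemming or negation handling.
* Multi-hub chaining and transitive closure beyond one shared hub item are
  deliberately unsupported.
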