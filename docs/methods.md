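# Methods

## Scope and data model

`ddialert` operates on a deliberately minimal OMOP-CDM-v5-style store:
person, drug_exposure, measurement, condition_occurrence, visit_occurrence,
concept and concept_ancestor tables, read and written as comma-delimited text
with ISO-8601 timestamps.  All event times are kept at minute resolution;
date-only inputs are promoted to local midnight.  Minute-resolution
timestamps make the duplicate-order rule — two exposures of the same drug
started at the same instant with different sig directions count as separate
alerts — an exact equality test.  Daily dose is a stored field
(`daily_dose_value`/`daily_dose_unit`); free-text sig parsing is out of
scope.  Unknown extra columns in input tables are ignored with a warning so
that exports from slightly different CDM versions still load.

## Trigger semantics

Concomitant exposure uses closed intervals: a drug stopped on the day another
starts still counts as overlapping.  This is the conservative,
alert-retaining reading of "the start and stop periods overlap".  The trigger
is the start of the later-starting exposure (at a tie, the shared start),
emulating the order-entry moment a CDS hook would see.  Pair direction is
fixed per DDI (object vs precipitant), so each combination is counted once,
not twice; self-pairs are excluded, and pair enumeration is
order-insensitive (output sorted by person, trigger, exposure ids).

## Context extraction

Factors are declared per tree in a manifest and computed by a small extractor
library:

* `sex`, `age` — completed years by the birthday-anniversary convention (the
  anniversary day itself counts, so "age 68 or older" is true on the 68th
  birthday).
* `latest_lab` — greatest `taken_datetime ≤ trigger` within a lookback
  window; never peeks forward.  Defaults: serum potassium 72 h (an
  inpatient-style recency requirement in the spirit of restricting
  hyperkalemia alerts to a *recent* value), QTc 30 days; both live in
  `data/context_config.json` and can be overridden per tree.  mEq/L and
  mmol/L are declared numerically equivalent for potassium; measurements in
  non-equivalent units are ignored rather than misread.  Ties on the
  timestamp break by measurement id.
* `condition_present` — EVER ("history of …": any occurrence started on or
  before the trigger) vs ACTIVE ("has diagnosis of …": the occurrence
  interval contains the trigger).
* `concomitant_drug` — any exposure from the set, other than the pair's own
  two, whose interval contains the trigger.
* `drug_discontinued` — an exposure from the set ended within the window
  (default 7 days) and none is ongoing.  "Ongoing" is `start ≤ t < end`: an
  exposure ending exactly at the trigger counts as just-discontinued.  This
  boundary choice is load-bearing: clonidine withdrawal during β-blockade is
  detectable at a trigger only when the clonidine exposure ends exactly where
  the β-blocker exposure starts (inclusive overlap), so a half-open "ongoing"
  test is the only reading under which that branch is reachable at all.  The
  7-day window is a documented default, not an evidence-based constant.
* `drug_dose`, `drug_route`, `drug_in_set`, `dose_tier` — attributes of the
  pair's own exposures; `dose_tier` applies per-drug-set thresholds (e.g.
  oxycodone mg/day vs fentanyl mcg/hr scales), HIGH at or above the cut.
* `visit_context` — INPATIENT if any visit containing the trigger is flagged
  inpatient **or** lasts ≥ 24 h (the duration criterion matters because real
  extracts often lack encounter type); otherwise OUTPATIENT; MISSING outside
  any visit.
* Derived extractors (`equals_flag`, `threshold_flag`, `count_true`) are pure
  functions of earlier factors, so test suites and the coverage generator can
  recompute them on hypothetical assignments without a store.

MISSING policy: every predicate node declares the branch a MISSING value
takes.  Bundled trees route MISSING toward the more severe branch, and
`count_true` counts a MISSING component as present by default — unknown data
must not silence a warning.  The one deliberate exception is the potassium
rule (below).

## The eight bundled algorithms

The trees use exactly the published drug/patient factors per DDI; branch
thresholds are named constants inside the JSON documents and are the
package's own clinically-plausible defaults, intended to be reconciled
against institutional policy by editing data, not code.

* **citalopram_qt** (monotone): QTc > 480 ms → RED outright.  Otherwise a
  risk-factor count over {female sex, QTc > 480, age ≥ 68, concomitant loop
  diuretic, K < 3.5 mEq/L, history of MI, active sepsis, active heart
  failure}: ≥ 2 → RED, 1 → YELLOW, 0 with citalopram ≤ 40 mg/day → GREEN
  (> 40 mg/day → YELLOW).
* **clonidine_beta_blocker**: ophthalmic timolol or an alpha-blocking
  β-blocker (carvedilol, labetalol) → GREEN; clonidine discontinuation while
  a nonselective β-blocker is ongoing → RED (rebound hypertension with
  unopposed α-stimulation); otherwise YELLOW.
* **epinephrine_beta_blocker**: the local/dermatological-indication branch is
  omitted — the data model does not link a drug exposure to the condition it
  was given for — so the computable tree has **no GREEN leaf**: nonselective
  β-blocker with active anaphylaxis or systemic (IV/local-injection)
  epinephrine → RED, everything else YELLOW.
* **fluconazole_opioid**: fluconazole ≤ 200 mg/day during an inpatient
  (≥ 24 h) visit → GREEN; low dose outpatient → YELLOW; > 200 mg/day with a
  high-tier opioid (oxycodone ≥ 40 mg/day, fentanyl ≥ 50 mcg/hr) → RED, else
  YELLOW.
* **immunosuppressant_fluconazole**: topical/ophthalmic fluconazole → GREEN;
  systemic ≤ 200 mg/day → GREEN; > 200 mg/day with a narrow-therapeutic-index
  immunosuppressant (tacrolimus, cyclosporine, sirolimus) → RED, or age ≥ 65
  → RED, else YELLOW.
* **potassium_k_sparing_diuretic**: latest K ≥ 5.0 mEq/L → RED; K present and
  < 5.0 → GREEN; no recent K → YELLOW.  The threshold echoes published
  hyperkalemia-alert designs keyed to a recent value ≥ 5 mmol/L and is
  config-exposed.
* **warfarin_antidepressant** (monotone): serotonergic antidepressant
  (SSRI/SNRI/TCA) plus any bleeding co-risk (NSAID, aspirin, systemic
  corticosteroid, aldosterone antagonist, antiplatelet, age ≥ 65, history of
  UGIB/peptic ulcer) → RED; serotonergic alone → YELLOW;
  bupropion/mirtazapine with a co-risk → YELLOW, without → GREEN.
* **warfarin_salicylate**: topical salicylate → GREEN; nonacetylated
  salicylate ≤ 2000 mg/day → GREEN, above → YELLOW; aspirin with a
  thromboembolic indication → YELLOW (deliberate co-prescription); aspirin
  without one → RED.

### Monotonicity and the MISSING-conservative property

Trees flagged `monotone_severity` (citalopram_qt, warfarin_antidepressant)
satisfy two exhaustively tested lattice properties: turning any single
boolean risk factor on never lowers the classification, and replacing any
known base factor with MISSING never lowers it.  The potassium tree is
deliberately **not** flagged: it maps a missing potassium to YELLOW while a
known K ≥ 5.0 maps to RED, so blanking a known hyperkalemic value lowers
severity by design — the three-way present/absent structure is the rule's
point, and the property would be false for it.  The clonidine, epinephrine,
fluconazole and salicylate trees branch on drug class/formulation rather
than accumulating risk, so a global severity order over their factors does
not exist either.

## Synthetic data

The replica population fixes the census at 93 persons, 24 lab measurements,
12 condition occurrences and 208 drug exposures for every seed: 35 scripted
persons (one per reachable leaf across the eight trees), 8 negative controls
(a lone interacting drug each, which must alert nowhere), and 50 background
persons padded with drugs that belong to no object/precipitant set so they
can never create a pair.  Demographics and dates are invented; the seed
varies only those.

The branch-coverage generator enumerates factor assignments over a candidate
grid — booleans, each enum value, and numeric values straddling every
threshold the tree references (t−1, t, t+1, plus MISSING where the factor can
be missing) — with object/precipitant concepts as free variables so that
drug-class factors stay consistent.  The first assignment reaching each leaf
is materialized into CDM records producing exactly one pair at a fixed
trigger; exhausting the grid without reaching a leaf raises an error naming
it, which doubles as a lint for contradictory trees.  The grid is exact for
the bundled trees (≤ ~25k combinations); a hard cap guards pathological
documents.

Randomized populations draw per-person Poisson counts (defaults: 17.3 drug
exposures, 16.8 lab measurements, 1.27 visits, 1.0 conditions per person)
with a 53.5 % female and 15.6/55.7/28.7 % under-18/18–60/over-60 demographic
mix, matching summary statistics of a three-month tertiary-care extract.
Background exposures come only from non-interacting drugs; with probability
0.30 a person's first two exposures are replaced by a deliberately
overlapping object/precipitant pair of a random DDI, so co-exposure
prevalence 0 provably yields zero alerts.  Lab values are uniform within
normal/abnormal bands with 15 % hypokalemia, 10 % hyperkalemia and 10 %
prolonged-QTc prevalence.  What this does **not** emulate: longitudinal
disease progression, correlated prescribing, dose tapering, drug eras with
persistence gaps, or realistic per-drug prevalences — passing tests show the
engine's logic and counting are correct, not that the severity mix predicts
any real population's.

## Validation by independent recomputation

`ddialert.oracle` recomputes per-DDI daily alert counts (both basic pair
totals and per-leaf breakdowns, grouped by the calendar date of the trigger
in local time) by exhaustive nested scans over the raw rows and recursive
descent over the raw JSON documents.  It imports nothing from the
concept-set, exposure or rules modules — an AST-based test enforces the
boundary — so a bug would have to be made twice, independently, to go
unseen.  Concordance is checked on the replica, on every branch-coverage
fixture, and on twenty seeded 200-person random populations; the CLI
`validate` command exits nonzero on any discrepancy.

## Numerical and design choices

* Closed-interval overlap and inclusive thresholds ("24 hours or more",
  "age 68 or older", "K < 3.5") throughout.
* Day boundary for daily counts: local midnight of the trigger timestamp.
* Visit-duration filter (`filter_visits_min_duration`) uses an inclusive
  lower bound and, by default, retains events outside any visit; a flag
  restricts exposures/measurements to retained visits.
* Concept-set resolution is seeds ∪ transitive descendants (the ancestry
  table stores direct parent→child edges) minus exclusions, cached per
  store; empty resolutions and unknown seeds are errors.
* Determinism everywhere: identical inputs give byte-identical serialized
  reports; all generators are `numpy.random.default_rng(seed)`-driven.

Test problem sizes: the concordance gate uses twenty 200-person populations,
and the monotonicity/MISSING suites enumerate the full factor lattices of the
monotone trees (~25k and ~2k contexts) — sizes chosen so the entire suite
runs in seconds while the lattice checks stay exhaustive rather than sampled.

## Limitations

* Bundled concept sets are small synthetic stand-ins with stable ids; real
  terminology exports (VSAC-style) should replace them for any real use.
* Tree thresholds are defaults to be reconciled against institutional
  policy; no claim of clinical validation is made.
* The epinephrine/β-blocker indication branch is structurally out of reach
  of this data model; its computable form can only downgrade, never filter.
* No drug-era construction, dose-taper inference, or pharmacokinetics; the
  engine reasons over raw exposure intervals as recorded.
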