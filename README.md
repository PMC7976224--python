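# ddialert — contextualized drug–drug interaction alerting

Most drug–drug interaction (DDI) warnings in order-entry systems fire on the
drug pair alone, ignore the patient in front of the clinician, and get
overridden — the classic recipe for alert fatigue.  `ddialert` implements
eight contextualized DDI alert algorithms as a reusable rule engine over a
minimal OMOP-CDM-style patient store, for informaticists who want to evaluate
context-aware alert filtering on observational data or adapt the algorithms
to their own site.

## The model

A **basic concomitant exposure** — the event a conventional system would
always interrupt on — is a pair of drug exposures, one from the DDI's
*object* concept set and one from its *precipitant* set, whose `[start, end]`
periods overlap (inclusive endpoints).  The trigger time is the start of the
later-starting exposure, i.e. the order-entry moment.  Exposures to the same
drug entered at an identical timestamp but with different sig directions are
distinct exposures and are counted separately.

Each DDI algorithm is a declarative decision tree over patient-context
factors extracted at the trigger: demographics (sex, completed age),
most-recent lab values within a lookback window (serum potassium 72 h, QTc
30 days by default), historical/active conditions, concomitant drug classes,
recent discontinuations, dose/route of the paired exposures, and visit
setting.  Every path ends in an operational classification:

| Color  | Recommendation                              | Operational meaning  |
|--------|---------------------------------------------|----------------------|
| RED    | Avoid Combination                           | interruptive         |
| YELLOW | Usually Avoid Combination or Minimize Risk  | interruptive         |
| GREEN  | No Special Precautions                      | filtered (no interrupt) |

A factor that cannot be determined is `MISSING`, and every predicate node
declares which branch `MISSING` takes; the bundled trees route unknowns
toward the more severe branch so that absent data never silences a warning.

The eight bundled DDIs: citalopram/QT-prolonging agent, clonidine/β-blocker,
epinephrine/β-blocker, fluconazole/opioid, immunosuppressant/fluconazole,
potassium/potassium-sparing diuretic, warfarin/antidepressant,
warfarin/salicylate.  Trees, concept sets (synthetic stand-in memberships
with stable set ids) and lookback configuration are JSON documents under
`src/ddialert/data/` — reconciling thresholds against local policy is a data
edit, not a code change.

## Worked example

```sh
ddialert simulate replica --seed 7 --out-dir /tmp/replica
ddialert run /tmp/replica
```

```
                          ddi  basic  classified  red  yellow  green  green_pct
                citalopram_qt      5           5    2       2      1       20.0
       clonidine_beta_blocker      5           5    1       2      2       40.0
     epinephrine_beta_blocker      4           4    2       2      0        0.0
           fluconazole_opioid      4           4    1       2      1       25.0
immunosuppressant_fluconazole      5           5    2       1      2       40.0
 potassium_k_sparing_diuretic      3           3    1       1      1       33.3
      warfarin_antidepressant      4           4    1       2      1       25.0
          warfarin_salicylate      5           5    1       2      2       40.0
                      OVERALL     35          35   11      14     10       28.6
```

The `basic` column counts concomitant exposures (what an uncontextualized
system would interrupt on); `classified` re-counts them through each
algorithm's leaves, and the color columns break those down.  `green_pct` is
the share of alerts the contextualized algorithm filters outright.  The
replica population is built so that every leaf of every algorithm fires
exactly once — note the epinephrine/β-blocker row, whose computable tree has
no reachable GREEN leaf because the data model cannot link an epinephrine
exposure to a local/dermatological indication.

Validate engine output against the independent brute-force query oracle
(exit 0 iff every per-DDI daily count is concordant), and audit the bundled
artifacts:

```sh
ddialert validate /tmp/replica
ddialert audit
```

Library use mirrors the CLI:

```python
import ddialert as d

store = d.generate_paper_replica(seed=7)
report = d.run_all(store, d.load_bundled_trees(), d.ContextConfig())
print(report.per_ddi["potassium_k_sparing_diuretic"].leaf_counts)
# {'red_hyperkalemia': 1, 'green_normokalemia': 1, 'yellow_no_recent_potassium': 1}
```

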