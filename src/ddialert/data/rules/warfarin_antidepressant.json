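{
 "ddi_id": "warfarin_antidepressant",
 "name": "Warfarin / antidepressant",
 "object_set": "warfarin",
 "precipitant_set": "antidepressants",
 "monotone_severity": true,
 "factors": [
  {
   "name": "serotonergic",
   "type": "boolean",
   "extractor": "drug_in_set",
   "params": {
    "which": "precipitant",
    "set": "serotonergic_antidepressants"
   }
  },
  {
   "name": "nsaid",
   "type": "boolean",
   "extractor": "concomitant_drug",
   "params": {
    "set": "nsaids"
   }
  },
  {
   "name": "aspirin_use",
   "type": "boolean",
   "extractor": "concomitant_drug",
   "params": {
    "set": "aspirin"
   }
  },
  {
   "name": "corticosteroid",
   "type": "boolean",
   "extractor": "concomitant_drug",
   "params": {
    "set": "systemic_corticosteroids"
   }
  },
  {
   "name": "aldosterone_antagonist",
   "type": "boolean",
   "extractor": "concomitant_drug",
   "params": {
    "set": "aldosterone_antagonists"
   }
  },
  {
   "name": "antiplatelet",
   "type": "boolean",
   "extractor": "concomitant_drug",
   "params": {
    "set": "antiplatelets"
   }
  },
  {
   "name": "age_years",
   "type": "number",
   "extractor": "age",
   "params": {}
  },
  {
   "name": "hx_ugib",
   "type": "boolean",
   "extractor": "condition_present",
   "params": {
    "set": "ugib_or_peptic_ulcer",
    "mode": "EVER"
   }
  },
  {
   "name": "age_65_or_older",
   "type": "boolean",
   "extractor": "threshold_flag",
   "params": {
    "source": "age_years",
    "comparator": "GE",
    "threshold": 65
   }
  },
  {
   "name": "bleeding_risk_count",
   "type": "count",
   "extractor": "count_true",
   "params": {
    "sources": [
     "nsaid",
     "aspirin_use",
     "corticosteroid",
     "aldosterone_antagonist",
     "antiplatelet",
     "age_65_or_older",
     "hx_ugib"
    ],
    "count_missing": true
   }
  }
 ],
 "root": "n_ser",
 "nodes": {
  "n_ser": {
   "kind": "PREDICATE",
   "factor": "serotonergic",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "n_risk_s",
   "false_branch": "n_risk_n"
  },
  "n_risk_s": {
   "kind": "PREDICATE",
   "factor": "bleeding_risk_count",
   "comparator": "GE",
   "threshold": 1,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red",
   "false_branch": "leaf_yellow_ser"
  },
  "n_risk_n": {
   "kind": "PREDICATE",
   "factor": "bleeding_risk_count",
   "comparator": "GE",
   "threshold": 1,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_yellow_other",
   "false_branch": "leaf_green"
  },
  "leaf_red": {
   "kind": "LEAF",
   "leaf_id": "red_serotonergic_with_bleeding_risk",
   "color": "RED"
  },
  "leaf_yellow_ser": {
   "kind": "LEAF",
   "leaf_id": "yellow_serotonergic",
   "color": "YELLOW"
  },
  "leaf_yellow_other": {
   "kind": "LEAF",
   "leaf_id": "yellow_other_antidepressant_with_risk",
   "color": "YELLOW"
  },
  "leaf_green": {
   "kind": "LEAF",
   "leaf_id": "green_low_risk_antidepressant",
   "color": "GREEN"
  }
 }
}
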