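{
 "ddi_id": "warfarin_salicylate",
 "name": "Warfarin / salicylate",
 "object_set": "warfarin",
 "precipitant_set": "salicylates",
 "monotone_severity": false,
 "factors": [
  {
   "name": "sal_route",
   "type": "enum",
   "extractor": "drug_route",
   "params": {
    "which": "precipitant"
   }
  },
  {
   "name": "nonacetylated",
   "type": "boolean",
   "extractor": "drug_in_set",
   "params": {
    "which": "precipitant",
    "set": "nonacetylated_salicylates"
   }
  },
  {
   "name": "salicylate_dose",
   "type": "number",
   "extractor": "drug_dose",
   "params": {
    "which": "precipitant"
   }
  },
  {
   "name": "thromboembolic_indication",
   "type": "boolean",
   "extractor": "condition_present",
   "params": {
    "set": "thromboembolic_conditions",
    "mode": "EVER"
   }
  }
 ],
 "root": "n_route",
 "nodes": {
  "n_route": {
   "kind": "PREDICATE",
   "factor": "sal_route",
   "comparator": "EQ",
   "threshold": "TOPICAL",
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "leaf_green_topical",
   "false_branch": "n_nonacet"
  },
  "n_nonacet": {
   "kind": "PREDICATE",
   "factor": "nonacetylated",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "n_nadose",
   "false_branch": "n_indication"
  },
  "n_nadose": {
   "kind": "PREDICATE",
   "factor": "salicylate_dose",
   "comparator": "GT",
   "threshold": 2000,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_yellow_na",
   "false_branch": "leaf_green_na"
  },
  "n_indication": {
   "kind": "PREDICATE",
   "factor": "thromboembolic_indication",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "leaf_yellow_deliberate",
   "false_branch": "leaf_red"
  },
  "leaf_green_topical": {
   "kind": "LEAF",
   "leaf_id": "green_topical_salicylate",
   "color": "GREEN"
  },
  "leaf_yellow_na": {
   "kind": "LEAF",
   "leaf_id": "yellow_high_dose_nonacetylated",
   "color": "YELLOW"
  },
  "leaf_green_na": {
   "kind": "LEAF",
   "leaf_id": "green_low_dose_nonacetylated",
   "color": "GREEN"
  },
  "leaf_yellow_deliberate": {
   "kind": "LEAF",
   "leaf_id": "yellow_deliberate_combination",
   "color": "YELLOW"
  },
  "leaf_red": {
   "kind": "LEAF",
   "leaf_id": "red_aspirin_no_indication",
   "color": "RED"
  }
 }
}
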