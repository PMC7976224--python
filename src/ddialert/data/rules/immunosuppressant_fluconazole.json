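{
 "ddi_id": "immunosuppressant_fluconazole",
 "name": "Immunosuppressant / fluconazole",
 "object_set": "immunosuppressants",
 "precipitant_set": "fluconazole",
 "monotone_severity": false,
 "factors": [
  {
   "name": "fluc_route",
   "type": "enum",
   "extractor": "drug_route",
   "params": {
    "which": "precipitant"
   }
  },
  {
   "name": "fluc_dose",
   "type": "number",
   "extractor": "drug_dose",
   "params": {
    "which": "precipitant"
   }
  },
  {
   "name": "nti_immunosuppressant",
   "type": "boolean",
   "extractor": "drug_in_set",
   "params": {
    "which": "object",
    "set": "nti_immunosuppressants"
   }
  },
  {
   "name": "age_years",
   "type": "number",
   "extractor": "age",
   "params": {}
  }
 ],
 "root": "n_route",
 "nodes": {
  "n_route": {
   "kind": "PREDICATE",
   "factor": "fluc_route",
   "comparator": "IN_SET",
   "threshold": [
    "TOPICAL",
    "OPHTHALMIC"
   ],
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "leaf_green_nonsystemic",
   "false_branch": "n_dose"
  },
  "n_dose": {
   "kind": "PREDICATE",
   "factor": "fluc_dose",
   "comparator": "GT",
   "threshold": 200,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "n_nti",
   "false_branch": "leaf_green_low_dose"
  },
  "n_nti": {
   "kind": "PREDICATE",
   "factor": "nti_immunosuppressant",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_nti",
   "false_branch": "n_age"
  },
  "n_age": {
   "kind": "PREDICATE",
   "factor": "age_years",
   "comparator": "GE",
   "threshold": 65,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_age",
   "false_branch": "leaf_yellow"
  },
  "leaf_green_nonsystemic": {
   "kind": "LEAF",
   "leaf_id": "green_nonsystemic_fluconazole",
   "color": "GREEN"
  },
  "leaf_green_low_dose": {
   "kind": "LEAF",
   "leaf_id": "green_low_dose_fluconazole",
   "color": "GREEN"
  },
  "leaf_red_nti": {
   "kind": "LEAF",
   "leaf_id": "red_nti_high_dose",
   "color": "RED"
  },
  "leaf_red_age": {
   "kind": "LEAF",
   "leaf_id": "red_elderly_high_dose",
   "color": "RED"
  },
  "leaf_yellow": {
   "kind": "LEAF",
   "leaf_id": "yellow_high_dose_fluconazole",
   "color": "YELLOW"
  }
 }
}
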