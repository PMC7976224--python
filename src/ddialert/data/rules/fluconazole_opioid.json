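{
 "ddi_id": "fluconazole_opioid",
 "name": "Fluconazole / opioid",
 "object_set": "fluconazole",
 "precipitant_set": "opioids",
 "monotone_severity": false,
 "factors": [
  {
   "name": "fluconazole_dose",
   "type": "number",
   "extractor": "drug_dose",
   "params": {
    "which": "object"
   }
  },
  {
   "name": "opioid_dose_tier",
   "type": "enum",
   "extractor": "dose_tier",
   "params": {
    "which": "precipitant",
    "tiers": [
     {
      "set": "oxycodone",
      "high_at": 40
     },
     {
      "set": "fentanyl",
      "high_at": 50
     }
    ]
   }
  },
  {
   "name": "visit_setting",
   "type": "enum",
   "extractor": "visit_context",
   "params": {}
  }
 ],
 "root": "n_dose",
 "nodes": {
  "n_dose": {
   "kind": "PREDICATE",
   "factor": "fluconazole_dose",
   "comparator": "LE",
   "threshold": 200,
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "n_visit",
   "false_branch": "n_opioid"
  },
  "n_visit": {
   "kind": "PREDICATE",
   "factor": "visit_setting",
   "comparator": "EQ",
   "threshold": "INPATIENT",
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "leaf_green_inpatient",
   "false_branch": "leaf_yellow_outpatient"
  },
  "n_opioid": {
   "kind": "PREDICATE",
   "factor": "opioid_dose_tier",
   "comparator": "EQ",
   "threshold": "HIGH",
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_high",
   "false_branch": "leaf_yellow_fluc"
  },
  "leaf_green_inpatient": {
   "kind": "LEAF",
   "leaf_id": "green_inpatient_low_dose",
   "color": "GREEN"
  },
  "leaf_yellow_outpatient": {
   "kind": "LEAF",
   "leaf_id": "yellow_outpatient_low_dose",
   "color": "YELLOW"
  },
  "leaf_red_high": {
   "kind": "LEAF",
   "leaf_id": "red_high_dose_combination",
   "color": "RED"
  },
  "leaf_yellow_fluc": {
   "kind": "LEAF",
   "leaf_id": "yellow_high_dose_fluconazole",
   "color": "YELLOW"
  }
 }
}
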