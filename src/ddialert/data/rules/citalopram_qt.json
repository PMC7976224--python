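{
 "ddi_id": "citalopram_qt",
 "name": "Citalopram / QT-prolonging agent",
 "object_set": "citalopram",
 "precipitant_set": "qt_prolonging_agents",
 "monotone_severity": true,
 "factors": [
  {
   "name": "sex",
   "type": "enum",
   "extractor": "sex",
   "params": {}
  },
  {
   "name": "age_years",
   "type": "number",
   "extractor": "age",
   "params": {}
  },
  {
   "name": "qtc",
   "type": "number",
   "extractor": "latest_lab",
   "params": {
    "set": "qtc_interval",
    "unit": "ms"
   }
  },
  {
   "name": "serum_potassium",
   "type": "number",
   "extractor": "latest_lab",
   "params": {
    "set": "serum_potassium",
    "unit": "mEq/L"
   }
  },
  {
   "name": "loop_diuretic",
   "type": "boolean",
   "extractor": "concomitant_drug",
   "params": {
    "set": "loop_diuretics"
   }
  },
  {
   "name": "hx_mi",
   "type": "boolean",
   "extractor": "condition_present",
   "params": {
    "set": "myocardial_infarction",
    "mode": "EVER"
   }
  },
  {
   "name": "dx_sepsis",
   "type": "boolean",
   "extractor": "condition_present",
   "params": {
    "set": "sepsis",
    "mode": "ACTIVE"
   }
  },
  {
   "name": "dx_heart_failure",
   "type": "boolean",
   "extractor": "condition_present",
   "params": {
    "set": "heart_failure",
    "mode": "ACTIVE"
   }
  },
  {
   "name": "citalopram_dose",
   "type": "number",
   "extractor": "drug_dose",
   "params": {
    "which": "object"
   }
  },
  {
   "name": "female",
   "type": "boolean",
   "extractor": "equals_flag",
   "params": {
    "source": "sex",
    "value": "FEMALE"
   }
  },
  {
   "name": "qtc_over_480",
   "type": "boolean",
   "extractor": "threshold_flag",
   "params": {
    "source": "qtc",
    "comparator": "GT",
    "threshold": 480
   }
  },
  {
   "name": "age_68_or_older",
   "type": "boolean",
   "extractor": "threshold_flag",
   "params": {
    "source": "age_years",
    "comparator": "GE",
    "threshold": 68
   }
  },
  {
   "name": "k_below_3_5",
   "type": "boolean",
   "extractor": "threshold_flag",
   "params": {
    "source": "serum_potassium",
    "comparator": "LT",
    "threshold": 3.5
   }
  },
  {
   "name": "risk_factor_count",
   "type": "count",
   "extractor": "count_true",
   "params": {
    "sources": [
     "female",
     "qtc_over_480",
     "age_68_or_older",
     "loop_diuretic",
     "k_below_3_5",
     "hx_mi",
     "dx_sepsis",
     "dx_heart_failure"
    ],
    "count_missing": true
   }
  }
 ],
 "root": "n_qtc",
 "nodes": {
  "n_qtc": {
   "kind": "PREDICATE",
   "factor": "qtc_over_480",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_qtc",
   "false_branch": "n_count2"
  },
  "n_count2": {
   "kind": "PREDICATE",
   "factor": "risk_factor_count",
   "comparator": "GE",
   "threshold": 2,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_multi",
   "false_branch": "n_count1"
  },
  "n_count1": {
   "kind": "PREDICATE",
   "factor": "risk_factor_count",
   "comparator": "GE",
   "threshold": 1,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_yellow_one",
   "false_branch": "n_dose"
  },
  "n_dose": {
   "kind": "PREDICATE",
   "factor": "citalopram_dose",
   "comparator": "GT",
   "threshold": 40,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_yellow_dose",
   "false_branch": "leaf_green"
  },
  "leaf_red_qtc": {
   "kind": "LEAF",
   "leaf_id": "red_qtc_prolonged",
   "color": "RED"
  },
  "leaf_red_multi": {
   "kind": "LEAF",
   "leaf_id": "red_multiple_risk_factors",
   "color": "RED"
  },
  "leaf_yellow_one": {
   "kind": "LEAF",
   "leaf_id": "yellow_single_risk_factor",
   "color": "YELLOW"
  },
  "leaf_yellow_dose": {
   "kind": "LEAF",
   "leaf_id": "yellow_high_dose_citalopram",
   "color": "YELLOW"
  },
  "leaf_green": {
   "kind": "LEAF",
   "leaf_id": "green_no_risk_factors",
   "color": "GREEN"
  }
 }
}
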