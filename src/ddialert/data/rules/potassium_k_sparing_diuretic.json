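{
 "ddi_id": "potassium_k_sparing_diuretic",
 "name": "Potassium / potassium-sparing diuretic",
 "object_set": "potassium_supplements",
 "precipitant_set": "k_sparing_diuretics",
 "monotone_severity": false,
 "factors": [
  {
   "name": "serum_potassium",
   "type": "number",
   "extractor": "latest_lab",
   "params": {
    "set": "serum_potassium",
    "unit": "mEq/L"
   }
  }
 ],
 "root": "n_present",
 "nodes": {
  "n_present": {
   "kind": "PREDICATE",
   "factor": "serum_potassium",
   "comparator": "PRESENT",
   "threshold": null,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "n_level",
   "false_branch": "leaf_yellow_no_k"
  },
  "n_level": {
   "kind": "PREDICATE",
   "factor": "serum_potassium",
   "comparator": "GE",
   "threshold": 5.0,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_hyperk",
   "false_branch": "leaf_green_normok"
  },
  "leaf_red_hyperk": {
   "kind": "LEAF",
   "leaf_id": "red_hyperkalemia",
   "color": "RED"
  },
  "leaf_green_normok": {
   "kind": "LEAF",
   "leaf_id": "green_normokalemia",
   "color": "GREEN"
  },
  "leaf_yellow_no_k": {
   "kind": "LEAF",
   "leaf_id": "yellow_no_recent_potassium",
   "color": "YELLOW"
  }
 }
}
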