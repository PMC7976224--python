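{
 "ddi_id": "epinephrine_beta_blocker",
 "name": "Epinephrine / beta-blocker",
 "object_set": "epinephrine",
 "precipitant_set": "beta_blockers",
 "monotone_severity": false,
 "factors": [
  {
   "name": "bb_nonselective",
   "type": "boolean",
   "extractor": "drug_in_set",
   "params": {
    "which": "precipitant",
    "set": "nonselective_beta_blockers"
   }
  },
  {
   "name": "anaphylaxis",
   "type": "boolean",
   "extractor": "condition_present",
   "params": {
    "set": "anaphylaxis_conditions",
    "mode": "ACTIVE"
   }
  },
  {
   "name": "epi_route",
   "type": "enum",
   "extractor": "drug_route",
   "params": {
    "which": "object"
   }
  }
 ],
 "root": "n_nonsel",
 "nodes": {
  "n_nonsel": {
   "kind": "PREDICATE",
   "factor": "bb_nonselective",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "n_anaph",
   "false_branch": "leaf_yellow_selective"
  },
  "n_anaph": {
   "kind": "PREDICATE",
   "factor": "anaphylaxis",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_anaph",
   "false_branch": "n_route"
  },
  "n_route": {
   "kind": "PREDICATE",
   "factor": "epi_route",
   "comparator": "IN_SET",
   "threshold": [
    "IV",
    "LOCAL_INJECTION"
   ],
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_systemic",
   "false_branch": "leaf_yellow_nonsystemic"
  },
  "leaf_red_anaph": {
   "kind": "LEAF",
   "leaf_id": "red_anaphylaxis_nonselective",
   "color": "RED"
  },
  "leaf_red_systemic": {
   "kind": "LEAF",
   "leaf_id": "red_systemic_epinephrine_nonselective",
   "color": "RED"
  },
  "leaf_yellow_nonsystemic": {
   "kind": "LEAF",
   "leaf_id": "yellow_nonsystemic_epinephrine",
   "color": "YELLOW"
  },
  "leaf_yellow_selective": {
   "kind": "LEAF",
   "leaf_id": "yellow_selective_or_alpha_blocking",
   "color": "YELLOW"
  }
 }
}
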