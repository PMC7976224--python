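{
 "ddi_id": "clonidine_beta_blocker",
 "name": "Clonidine / beta-blocker",
 "object_set": "clonidine",
 "precipitant_set": "beta_blockers",
 "monotone_severity": false,
 "factors": [
  {
   "name": "bb_ophthalmic_timolol",
   "type": "boolean",
   "extractor": "drug_in_set",
   "params": {
    "which": "precipitant",
    "set": "ophthalmic_timolol"
   }
  },
  {
   "name": "bb_alpha_blocking",
   "type": "boolean",
   "extractor": "drug_in_set",
   "params": {
    "which": "precipitant",
    "set": "alpha_blocking_beta_blockers"
   }
  },
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
   "name": "clonidine_withdrawal",
   "type": "boolean",
   "extractor": "drug_discontinued",
   "params": {
    "set": "clonidine"
   }
  }
 ],
 "root": "n_oph",
 "nodes": {
  "n_oph": {
   "kind": "PREDICATE",
   "factor": "bb_ophthalmic_timolol",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "leaf_green_oph",
   "false_branch": "n_alpha"
  },
  "n_alpha": {
   "kind": "PREDICATE",
   "factor": "bb_alpha_blocking",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "FALSE_BRANCH",
   "true_branch": "leaf_green_alpha",
   "false_branch": "n_withdrawal"
  },
  "n_withdrawal": {
   "kind": "PREDICATE",
   "factor": "clonidine_withdrawal",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "n_nonsel",
   "false_branch": "leaf_yellow_continued"
  },
  "n_nonsel": {
   "kind": "PREDICATE",
   "factor": "bb_nonselective",
   "comparator": "EQ",
   "threshold": true,
   "missing_branch": "TRUE_BRANCH",
   "true_branch": "leaf_red_withdrawal",
   "false_branch": "leaf_yellow_withdrawal"
  },
  "leaf_green_oph": {
   "kind": "LEAF",
   "leaf_id": "green_ophthalmic_timolol",
   "color": "GREEN"
  },
  "leaf_green_alpha": {
   "kind": "LEAF",
   "leaf_id": "green_alpha_blocking",
   "color": "GREEN"
  },
  "leaf_red_withdrawal": {
   "kind": "LEAF",
   "leaf_id": "red_withdrawal_nonselective",
   "color": "RED"
  },
  "leaf_yellow_withdrawal": {
   "kind": "LEAF",
   "leaf_id": "yellow_withdrawal_selective",
   "color": "YELLOW"
  },
  "leaf_yellow_continued": {
   "kind": "LEAF",
   "leaf_id": "yellow_continued_combination",
   "color": "YELLOW"
  }
 }
}
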