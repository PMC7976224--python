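{
 "set_id": "ugib_or_peptic_ulcer",
 "name": "History of UGIB or peptic ulcer",
 "vocabulary": "SNOMED",
 "seed_concept_ids": [
  4005,
  4006
 ],
 "include_descendants": false,
 "excluded_concept_ids": []
}
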