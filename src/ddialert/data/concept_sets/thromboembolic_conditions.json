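{
 "set_id": "thromboembolic_conditions",
 "name": "Thromboembolic disorders",
 "vocabulary": "SNOMED",
 "seed_concept_ids": [
  4007
 ],
 "include_descendants": true,
 "excluded_concept_ids": []
}
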