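{
 "set_id": "nti_immunosuppressants",
 "name": "Narrow-therapeutic-index immunosuppressants",
 "vocabulary": "RXNORM",
 "seed_concept_ids": [
  2101,
  2102,
  2103
 ],
 "include_descendants": false,
 "excluded_concept_ids": []
}
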