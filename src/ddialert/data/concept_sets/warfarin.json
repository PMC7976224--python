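{
 "set_id": "warfarin",
 "name": "Warfarin",
 "vocabulary": "RXNORM",
 "seed_concept_ids": [
  1950
 ],
 "include_descendants": false,
 "excluded_concept_ids": []
}
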