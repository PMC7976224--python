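{
 "set_id": "serotonergic_antidepressants",
 "name": "Serotonergic antidepressants (SSRI/SNRI/TCA)",
 "vocabulary": "RXNORM",
 "seed_concept_ids": [
  1100,
  1200,
  1300
 ],
 "include_descendants": true,
 "excluded_concept_ids": []
}
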