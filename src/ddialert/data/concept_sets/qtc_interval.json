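{
 "set_id": "qtc_interval",
 "name": "Corrected QT interval (ECG)",
 "vocabulary": "LOINC",
 "seed_concept_ids": [
  3002
 ],
 "include_descendants": false,
 "excluded_concept_ids": []
}
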