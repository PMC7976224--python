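{
 "default_lab_lookback_days": 30,
 "lab_lookback_hours": {
  "serum_potassium": 72,
  "qtc_interval": 720
 },
 "discontinuation_window_days": 7,
 "unit_equivalences": [
  [
   "mEq/L",
   "mmol/L"
  ]
 ]
}
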