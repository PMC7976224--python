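{
 "citalopram_qt": [
  "citalopram",
  "qt_prolonging_agents",
  "loop_diuretics",
  "serum_potassium",
  "qtc_interval",
  "myocardial_infarction",
  "sepsis",
  "heart_failure"
 ],
 "clonidine_beta_blocker": [
  "clonidine",
  "beta_blockers",
  "nonselective_beta_blockers",
  "alpha_blocking_beta_blockers",
  "ophthalmic_timolol"
 ],
 "epinephrine_beta_blocker": [
  "epinephrine",
  "beta_blockers",
  "nonselective_beta_blockers",
  "anaphylaxis_conditions"
 ],
 "fluconazole_opioid": [
  "fluconazole",
  "opioids",
  "oxycodone",
  "fentanyl"
 ],
 "immunosuppressant_fluconazole": [
  "immunosuppressants",
  "fluconazole",
  "nti_immunosuppressants"
 ],
 "potassium_k_sparing_diuretic": [
  "potassium_supplements",
  "k_sparing_diuretics",
  "serum_potassium"
 ],
 "warfarin_antidepressant": [
  "warfarin",
  "antidepressants",
  "serotonergic_antidepressants",
  "nsaids",
  "aspirin",
  "systemic_corticosteroids",
  "aldosterone_antagonists",
  "antiplatelets",
  "ugib_or_peptic_ulcer"
 ],
 "warfarin_salicylate": [
  "warfarin",
  "salicylates",
  "nonacetylated_salicylates",
  "thromboembolic_conditions"
 ]
}
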