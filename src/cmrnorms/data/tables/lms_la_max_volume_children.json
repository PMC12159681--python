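{
 "table_id": "lms_la_max_volume_children",
 "parameter_id": "la_max_vol_bsa",
 "covariate": "age_years",
 "units": "mL/m^2",
 "population": "children",
 "title": "Maximal LA volume / BSA in children: LMS parameters and centiles by age",
 "centiles_discordant": [
  "female"
 ],
 "discordance_note": "In the female block the printed centile columns contradict the printed L/M/S under the table's own formula (printed 50th centile deviates from printed M by up to 4 units); those cells are excluded from model-vs-print verification.",
 "kind": "lms",
 "centile_columns": {
  "c3": -2.0,
  "c10": "p0.10",
  "c25": "p0.25",
  "c50": 0.0,
  "c75": "p0.75",
  "c90": "p0.90",
  "c97": 2.0
 }
}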