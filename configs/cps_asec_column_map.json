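{
  "_comment": "Column-name mapping from the canonical person-table fields to CPS ASEC person-file variable names. The ASEC files encode categories numerically; recode values to the canonical labels (race: 'White'/'Black', sex: 'Male'/'Female', nativity: 'Native'/'Foreign-born', employment: 'Full-time'/...) before or after loading. Pass to load_person_table or `synpid --column-map`.",
  "race": "PRDTRACE",
  "sex": "A_SEX",
  "age": "A_AGE",
  "nativity": "PRCITSHP",
  "employment": "A_WKSTAT",
  "income": "PTOTVAL",
  "health": "HEA"
}
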