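category,code_system,pattern
anemia,ICD9,280-285
anemia,ICD10,D50-D64
hypertension,ICD9,401-405
hypertension,ICD10,I10-I15
heart_disease,ICD9,410-429
heart_disease,ICD10,I20-I52
dyslipidemia,ICD9,272
dyslipidemia,ICD10,E78
urinary_system_disease,ICD9,580-599
urinary_system_disease,ICD10,N00-N39
other_gastrointestinal_disorders,ICD9,530-579
other_gastrointestinal_disorders,ICD10,K20-K64
other_hematologic_conditions,ICD9,286-289
other_hematologic_conditions,ICD10,D65-D77
neoplasms_unspecified_uncertain,ICD9,235-238
neoplasms_unspecified_uncertain,ICD10,D37-D48
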