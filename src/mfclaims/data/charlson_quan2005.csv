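condition,code_system,pattern,weight
mi,ICD9,410,1
mi,ICD9,412,1
mi,ICD10,I21,1
mi,ICD10,I22,1
mi,ICD10,I25.2,1
chf,ICD9,398.91,1
chf,ICD9,402.01,1
chf,ICD9,402.11,1
chf,ICD9,402.91,1
chf,ICD9,404.01,1
chf,ICD9,404.03,1
chf,ICD9,404.11,1
chf,ICD9,404.13,1
chf,ICD9,404.91,1
chf,ICD9,404.93,1
chf,ICD9,425.4-425.9,1
chf,ICD9,428,1
chf,ICD10,I09.9,1
chf,ICD10,I11.0,1
chf,ICD10,I13.0,1
chf,ICD10,I13.2,1
chf,ICD10,I25.5,1
chf,ICD10,I42.0,1
chf,ICD10,I42.5-I42.9,1
chf,ICD10,I43,1
chf,ICD10,I50,1
chf,ICD10,P29.0,1
pvd,ICD9,093.0,1
pvd,ICD9,437.3,1
pvd,ICD9,440,1
pvd,ICD9,441,1
pvd,ICD9,443.1-443.9,1
pvd,ICD9,447.1,1
pvd,ICD9,557.1,1
pvd,ICD9,557.9,1
pvd,ICD9,V43.4,1
pvd,ICD10,I70,1
pvd,ICD10,I71,1
pvd,ICD10,I73.1,1
pvd,ICD10,I73.8,1
pvd,ICD10,I73.9,1
pvd,ICD10,I77.1,1
pvd,ICD10,I79.0,1
pvd,ICD10,I79.2,1
pvd,ICD10,K55.1,1
pvd,ICD10,K55.8,1
pvd,ICD10,K55.9,1
pvd,ICD10,Z95.8,1
pvd,ICD10,Z95.9,1
cvd,ICD9,362.34,1
cvd,ICD9,430-438,1
cvd,ICD10,G45,1
cvd,ICD10,G46,1
cvd,ICD10,H34.0,1
cvd,ICD10,I60-I69,1
dementia,ICD9,290,1
dementia,ICD9,294.1,1
dementia,ICD9,331.2,1
dementia,ICD10,F00-F03,1
dementia,ICD10,F05.1,1
dementia,ICD10,G30,1
dementia,ICD10,G31.1,1
chronic_pulmonary,ICD9,416.8,1
chronic_pulmonary,ICD9,416.9,1
chronic_pulmonary,ICD9,490-505,1
chronic_pulmonary,ICD9,506.4,1
chronic_pulmonary,ICD9,508.1,1
chronic_pulmonary,ICD9,508.8,1
chronic_pulmonary,ICD10,I27.8,1
chronic_pulmonary,ICD10,I27.9,1
chronic_pulmonary,ICD10,J40-J47,1
chronic_pulmonary,ICD10,J60-J67,1
chronic_pulmonary,ICD10,J68.4,1
chronic_pulmonary,ICD10,J70.1,1
chronic_pulmonary,ICD10,J70.3,1
rheumatic,ICD9,446.5,1
rheumatic,ICD9,710.0-710.4,1
rheumatic,ICD9,714.0-714.2,1
rheumatic,ICD9,714.8,1
rheumatic,ICD9,725,1
rheumatic,ICD10,M05,1
rheumatic,ICD10,M06,1
rheumatic,ICD10,M31.5,1
rheumatic,ICD10,M32-M34,1
rheumatic,ICD10,M35.1,1
rheumatic,ICD10,M35.3,1
rheumatic,ICD10,M36.0,1
peptic_ulcer,ICD9,531-534,1
peptic_ulcer,ICD10,K25-K28,1
mild_liver,ICD9,070.22,1
mild_liver,ICD9,070.23,1
mild_liver,ICD9,070.32,1
mild_liver,ICD9,070.33,1
mild_liver,ICD9,070.44,1
mild_liver,ICD9,070.54,1
mild_liver,ICD9,070.6,1
mild_liver,ICD9,070.9,1
mild_liver,ICD9,570,1
mild_liver,ICD9,571,1
mild_liver,ICD9,573.3,1
mild_liver,ICD9,573.4,1
mild_liver,ICD9,573.8,1
mild_liver,ICD9,573.9,1
mild_liver,ICD9,V42.7,1
mild_liver,ICD10,B18,1
mild_liver,ICD10,K70.0-K70.3,1
mild_liver,ICD10,K70.9,1
mild_liver,ICD10,K71.3-K71.5,1
mild_liver,ICD10,K71.7,1
mild_liver,ICD10,K73,1
mild_liver,ICD10,K74,1
mild_liver,ICD10,K76.0,1
mild_liver,ICD10,K76.2-K76.4,1
mild_liver,ICD10,K76.8,1
mild_liver,ICD10,K76.9,1
mild_liver,ICD10,Z94.4,1
diabetes_uncomplicated,ICD9,250.0-250.3,1
diabetes_uncomplicated,ICD9,250.8,1
diabetes_uncomplicated,ICD9,250.9,1
diabetes_uncomplicated,ICD10,E10.0,1
diabetes_uncomplicated,ICD10,E10.1,1
diabetes_uncomplicated,ICD10,E10.6,1
diabetes_uncomplicated,ICD10,E10.8,1
diabetes_uncomplicated,ICD10,E10.9,1
diabetes_uncomplicated,ICD10,E11.0,1
diabetes_uncomplicated,ICD10,E11.1,1
diabetes_uncomplicated,ICD10,E11.6,1
diabetes_uncomplicated,ICD10,E11.8,1
diabetes_uncomplicated,ICD10,E11.9,1
diabetes_uncomplicated,ICD10,E13.0,1
diabetes_uncomplicated,ICD10,E13.1,1
diabetes_uncomplicated,ICD10,E13.6,1
diabetes_uncomplicated,ICD10,E13.8,1
diabetes_uncomplicated,ICD10,E13.9,1
diabetes_uncomplicated,ICD10,E14.0,1
diabetes_uncomplicated,ICD10,E14.1,1
diabetes_uncomplicated,ICD10,E14.6,1
diabetes_uncomplicated,ICD10,E14.8,1
diabetes_uncomplicated,ICD10,E14.9,1
diabetes_complicated,ICD9,250.4-250.7,2
diabetes_complicated,ICD10,E10.2-E10.5,2
diabetes_complicated,ICD10,E10.7,2
diabetes_complicated,ICD10,E11.2-E11.5,2
diabetes_complicated,ICD10,E11.7,2
diabetes_complicated,ICD10,E13.2-E13.5,2
diabetes_complicated,ICD10,E13.7,2
diabetes_complicated,ICD10,E14.2-E14.5,2
diabetes_complicated,ICD10,E14.7,2
hemiplegia,ICD9,334.1,2
hemiplegia,ICD9,342,2
hemiplegia,ICD9,343,2
hemiplegia,ICD9,344.0-344.6,2
hemiplegia,ICD9,344.9,2
hemiplegia,ICD10,G04.1,2
hemiplegia,ICD10,G11.4,2
hemiplegia,ICD10,G80.1,2
hemiplegia,ICD10,G80.2,2
hemiplegia,ICD10,G81,2
hemiplegia,ICD10,G82,2
hemiplegia,ICD10,G83.0-G83.4,2
hemiplegia,ICD10,G83.9,2
renal,ICD9,403.01,2
renal,ICD9,403.11,2
renal,ICD9,403.91,2
renal,ICD9,404.02,2
renal,ICD9,404.12,2
renal,ICD9,404.92,2
renal,ICD9,582,2
renal,ICD9,583.0-583.7,2
renal,ICD9,585,2
renal,ICD9,586,2
renal,ICD9,588.0,2
renal,ICD9,V42.0,2
renal,ICD9,V45.1,2
renal,ICD9,V56,2
renal,ICD10,I12.0,2
renal,ICD10,I13.1,2
renal,ICD10,N03.2-N03.7,2
renal,ICD10,N05.2-N05.7,2
renal,ICD10,N18,2
renal,ICD10,N19,2
renal,ICD10,N25.0,2
renal,ICD10,Z49.0-Z49.2,2
renal,ICD10,Z94.0,2
renal,ICD10,Z99.2,2
malignancy,ICD9,140-172,2
malignancy,ICD9,174-195,2
malignancy,ICD9,200-208,2
malignancy,ICD9,238.6,2
malignancy,ICD10,C00-C26,2
malignancy,ICD10,C30-C34,2
malignancy,ICD10,C37-C41,2
malignancy,ICD10,C43,2
malignancy,ICD10,C45-C58,2
malignancy,ICD10,C60-C76,2
malignancy,ICD10,C81-C85,2
malignancy,ICD10,C88,2
malignancy,ICD10,C90-C97,2
severe_liver,ICD9,456.0-456.2,3
severe_liver,ICD9,572.2-572.8,3
severe_liver,ICD10,I85.0,3
severe_liver,ICD10,I85.9,3
severe_liver,ICD10,I86.4,3
severe_liver,ICD10,I98.2,3
severe_liver,ICD10,K70.4,3
severe_liver,ICD10,K71.1,3
severe_liver,ICD10,K72.1,3
severe_liver,ICD10,K72.9,3
severe_liver,ICD10,K76.5,3
severe_liver,ICD10,K76.6,3
severe_liver,ICD10,K76.7,3
metastatic_tumor,ICD9,196-199,6
metastatic_tumor,ICD10,C77-C80,6
hiv,ICD9,042-044,6
hiv,ICD10,B20-B22,6
hiv,ICD10,B24,6
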