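condition,prefix,weight
myocardial_infarction,I21,1
myocardial_infarction,I22,1
myocardial_infarction,I252,1
congestive_heart_failure,I099,1
congestive_heart_failure,I110,1
congestive_heart_failure,I130,1
congestive_heart_failure,I132,1
congestive_heart_failure,I255,1
congestive_heart_failure,I420,1
congestive_heart_failure,I425,1
congestive_heart_failure,I426,1
congestive_heart_failure,I427,1
congestive_heart_failure,I428,1
congestive_heart_failure,I429,1
congestive_heart_failure,I43,1
congestive_heart_failure,I50,1
congestive_heart_failure,P290,1
peripheral_vascular_disease,I70,1
peripheral_vascular_disease,I71,1
peripheral_vascular_disease,I731,1
peripheral_vascular_disease,I738,1
peripheral_vascular_disease,I739,1
peripheral_vascular_disease,I771,1
peripheral_vascular_disease,I790,1
peripheral_vascular_disease,I792,1
peripheral_vascular_disease,K551,1
peripheral_vascular_disease,K558,1
peripheral_vascular_disease,K559,1
peripheral_vascular_disease,Z958,1
peripheral_vascular_disease,Z959,1
cerebrovascular_disease,G45,1
cerebrovascular_disease,G46,1
cerebrovascular_disease,H340,1
cerebrovascular_disease,I60,1
cerebrovascular_disease,I61,1
cerebrovascular_disease,I62,1
cerebrovascular_disease,I63,1
cerebrovascular_disease,I64,1
cerebrovascular_disease,I65,1
cerebrovascular_disease,I66,1
cerebrovascular_disease,I67,1
cerebrovascular_disease,I68,1
cerebrovascular_disease,I69,1
dementia,F00,1
dementia,F01,1
dementia,F02,1
dementia,F03,1
dementia,F051,1
dementia,G30,1
dementia,G311,1
chronic_pulmonary_disease,I278,1
chronic_pulmonary_disease,I279,1
chronic_pulmonary_disease,J40,1
chronic_pulmonary_disease,J41,1
chronic_pulmonary_disease,J42,1
chronic_pulmonary_disease,J43,1
chronic_pulmonary_disease,J44,1
chronic_pulmonary_disease,J45,1
chronic_pulmonary_disease,J46,1
chronic_pulmonary_disease,J47,1
chronic_pulmonary_disease,J60,1
chronic_pulmonary_disease,J61,1
chronic_pulmonary_disease,J62,1
chronic_pulmonary_disease,J63,1
chronic_pulmonary_disease,J64,1
chronic_pulmonary_disease,J65,1
chronic_pulmonary_disease,J66,1
chronic_pulmonary_disease,J67,1
chronic_pulmonary_disease,J684,1
chronic_pulmonary_disease,J701,1
chronic_pulmonary_disease,J703,1
rheumatic_disease,M05,1
rheumatic_disease,M06,1
rheumatic_disease,M315,1
rheumatic_disease,M32,1
rheumatic_disease,M33,1
rheumatic_disease,M34,1
rheumatic_disease,M351,1
rheumatic_disease,M353,1
rheumatic_disease,M360,1
peptic_ulcer_disease,K25,1
peptic_ulcer_disease,K26,1
peptic_ulcer_disease,K27,1
peptic_ulcer_disease,K28,1
mild_liver_disease,B18,1
mild_liver_disease,K700,1
mild_liver_disease,K701,1
mild_liver_disease,K702,1
mild_liver_disease,K703,1
mild_liver_disease,K709,1
mild_liver_disease,K713,1
mild_liver_disease,K714,1
mild_liver_disease,K715,1
mild_liver_disease,K717,1
mild_liver_disease,K73,1
mild_liver_disease,K74,1
mild_liver_disease,K760,1
mild_liver_disease,K762,1
mild_liver_disease,K763,1
mild_liver_disease,K764,1
mild_liver_disease,K768,1
mild_liver_disease,K769,1
mild_liver_disease,Z944,1
diabetes_uncomplicated,E100,1
diabetes_uncomplicated,E101,1
diabetes_uncomplicated,E106,1
diabetes_uncomplicated,E108,1
diabetes_uncomplicated,E109,1
diabetes_uncomplicated,E110,1
diabetes_uncomplicated,E111,1
diabetes_uncomplicated,E116,1
diabetes_uncomplicated,E118,1
diabetes_uncomplicated,E119,1
diabetes_uncomplicated,E120,1
diabetes_uncomplicated,E121,1
diabetes_uncomplicated,E126,1
diabetes_uncomplicated,E128,1
diabetes_uncomplicated,E129,1
diabetes_uncomplicated,E130,1
diabetes_uncomplicated,E131,1
diabetes_uncomplicated,E136,1
diabetes_uncomplicated,E138,1
diabetes_uncomplicated,E139,1
diabetes_uncomplicated,E140,1
diabetes_uncomplicated,E141,1
diabetes_uncomplicated,E146,1
diabetes_uncomplicated,E148,1
diabetes_uncomplicated,E149,1
diabetes_complicated,E102,2
diabetes_complicated,E103,2
diabetes_complicated,E104,2
diabetes_complicated,E105,2
diabetes_complicated,E107,2
diabetes_complicated,E112,2
diabetes_complicated,E113,2
diabetes_complicated,E114,2
diabetes_complicated,E115,2
diabetes_complicated,E117,2
diabetes_complicated,E122,2
diabetes_complicated,E123,2
diabetes_complicated,E124,2
diabetes_complicated,E125,2
diabetes_complicated,E127,2
diabetes_complicated,E132,2
diabetes_complicated,E133,2
diabetes_complicated,E134,2
diabetes_complicated,E135,2
diabetes_complicated,E137,2
diabetes_complicated,E142,2
diabetes_complicated,E143,2
diabetes_complicated,E144,2
diabetes_complicated,E145,2
diabetes_complicated,E147,2
hemiplegia_paraplegia,G041,2
hemiplegia_paraplegia,G114,2
hemiplegia_paraplegia,G801,2
hemiplegia_paraplegia,G802,2
hemiplegia_paraplegia,G81,2
hemiplegia_paraplegia,G82,2
hemiplegia_paraplegia,G830,2
hemiplegia_paraplegia,G831,2
hemiplegia_paraplegia,G832,2
hemiplegia_paraplegia,G833,2
hemiplegia_paraplegia,G834,2
hemiplegia_paraplegia,G839,2
renal_disease,I120,2
renal_disease,I131,2
renal_disease,N032,2
renal_disease,N033,2
renal_disease,N034,2
renal_disease,N035,2
renal_disease,N036,2
renal_disease,N037,2
renal_disease,N052,2
renal_disease,N053,2
renal_disease,N054,2
renal_disease,N055,2
renal_disease,N056,2
renal_disease,N057,2
renal_disease,N18,2
renal_disease,N19,2
renal_disease,N250,2
renal_disease,Z490,2
renal_disease,Z491,2
renal_disease,Z492,2
renal_disease,Z940,2
renal_disease,Z992,2
malignancy,C00,2
malignancy,C01,2
malignancy,C02,2
malignancy,C03,2
malignancy,C04,2
malignancy,C05,2
malignancy,C06,2
malignancy,C07,2
malignancy,C08,2
malignancy,C09,2
malignancy,C10,2
malignancy,C11,2
malignancy,C12,2
malignancy,C13,2
malignancy,C14,2
malignancy,C15,2
malignancy,C16,2
malignancy,C17,2
malignancy,C18,2
malignancy,C19,2
malignancy,C20,2
malignancy,C21,2
malignancy,C22,2
malignancy,C23,2
malignancy,C24,2
malignancy,C25,2
malignancy,C26,2
malignancy,C30,2
malignancy,C31,2
malignancy,C32,2
malignancy,C33,2
malignancy,C34,2
malignancy,C37,2
malignancy,C38,2
malignancy,C39,2
malignancy,C40,2
malignancy,C41,2
malignancy,C43,2
malignancy,C45,2
malignancy,C46,2
malignancy,C47,2
malignancy,C48,2
malignancy,C49,2
malignancy,C50,2
malignancy,C51,2
malignancy,C52,2
malignancy,C53,2
malignancy,C54,2
malignancy,C55,2
malignancy,C56,2
malignancy,C57,2
malignancy,C58,2
malignancy,C60,2
malignancy,C61,2
malignancy,C62,2
malignancy,C63,2
malignancy,C64,2
malignancy,C65,2
malignancy,C66,2
malignancy,C67,2
malignancy,C68,2
malignancy,C69,2
malignancy,C70,2
malignancy,C71,2
malignancy,C72,2
malignancy,C73,2
malignancy,C74,2
malignancy,C75,2
malignancy,C76,2
malignancy,C81,2
malignancy,C82,2
malignancy,C83,2
malignancy,C84,2
malignancy,C85,2
malignancy,C88,2
malignancy,C90,2
malignancy,C91,2
malignancy,C92,2
malignancy,C93,2
malignancy,C94,2
malignancy,C95,2
malignancy,C96,2
malignancy,C97,2
severe_liver_disease,I850,3
severe_liver_disease,I859,3
severe_liver_disease,I864,3
severe_liver_disease,I982,3
severe_liver_disease,K704,3
severe_liver_disease,K711,3
severe_liver_disease,K721,3
severe_liver_disease,K729,3
severe_liver_disease,K765,3
severe_liver_disease,K766,3
severe_liver_disease,K767,3
metastatic_cancer,C77,6
metastatic_cancer,C78,6
metastatic_cancer,C79,6
metastatic_cancer,C80,6
aids_hiv,B20,6
aids_hiv,B21,6
aids_hiv,B22,6
aids_hiv,B24,6
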