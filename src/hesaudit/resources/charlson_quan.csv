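group,stem,mode,weight
mi,I21,prefix,1
mi,I22,prefix,1
mi,I252,exact,1
chf,I099,exact,1
chf,I110,exact,1
chf,I130,exact,1
chf,I132,exact,1
chf,I255,exact,1
chf,I420,exact,1
chf,I425,exact,1
chf,I426,exact,1
chf,I427,exact,1
chf,I428,exact,1
chf,I429,exact,1
chf,P290,exact,1
chf,I43,prefix,1
chf,I50,prefix,1
pvd,I70,prefix,1
pvd,I71,prefix,1
pvd,I731,exact,1
pvd,I738,exact,1
pvd,I739,exact,1
pvd,I771,exact,1
pvd,I790,exact,1
pvd,I792,exact,1
pvd,K551,exact,1
pvd,K558,exact,1
pvd,K559,exact,1
pvd,Z958,exact,1
pvd,Z959,exact,1
cevd,G45,prefix,1
cevd,G46,prefix,1
cevd,I60,prefix,1
cevd,I61,prefix,1
cevd,I62,prefix,1
cevd,I63,prefix,1
cevd,I64,prefix,1
cevd,I65,prefix,1
cevd,I66,prefix,1
cevd,I67,prefix,1
cevd,I68,prefix,1
cevd,I69,prefix,1
cevd,H340,exact,1
dementia,F00,prefix,1
dementia,F01,prefix,1
dementia,F02,prefix,1
dementia,F03,prefix,1
dementia,G30,prefix,1
dementia,F051,exact,1
dementia,G311,exact,1
copd,J40,prefix,1
copd,J41,prefix,1
copd,J42,prefix,1
copd,J43,prefix,1
copd,J44,prefix,1
copd,J45,prefix,1
copd,J46,prefix,1
copd,J47,prefix,1
copd,J60,prefix,1
copd,J61,prefix,1
copd,J62,prefix,1
copd,J63,prefix,1
copd,J64,prefix,1
copd,J65,prefix,1
copd,J66,prefix,1
copd,J67,prefix,1
copd,I278,exact,1
copd,I279,exact,1
copd,J684,exact,1
copd,J701,exact,1
copd,J703,exact,1
rheum,M05,prefix,1
rheum,M06,prefix,1
rheum,M32,prefix,1
rheum,M33,prefix,1
rheum,M34,prefix,1
rheum,M315,exact,1
rheum,M351,exact,1
rheum,M353,exact,1
rheum,M360,exact,1
pud,K25,prefix,1
pud,K26,prefix,1
pud,K27,prefix,1
pud,K28,prefix,1
mild_liver,B18,prefix,1
mild_liver,K73,prefix,1
mild_liver,K74,prefix,1
mild_liver,K700,exact,1
mild_liver,K701,exact,1
mild_liver,K702,exact,1
mild_liver,K703,exact,1
mild_liver,K709,exact,1
mild_liver,K713,exact,1
mild_liver,K714,exact,1
mild_liver,K715,exact,1
mild_liver,K717,exact,1
mild_liver,K760,exact,1
mild_liver,K762,exact,1
mild_liver,K763,exact,1
mild_liver,K764,exact,1
mild_liver,K768,exact,1
mild_liver,K769,exact,1
mild_liver,Z944,exact,1
diabetes,E100,exact,1
diabetes,E101,exact,1
diabetes,E106,exact,1
diabetes,E108,exact,1
diabetes,E109,exact,1
diabetes,E110,exact,1
diabetes,E111,exact,1
diabetes,E116,exact,1
diabetes,E118,exact,1
diabetes,E119,exact,1
diabetes,E120,exact,1
diabetes,E121,exact,1
diabetes,E126,exact,1
diabetes,E128,exact,1
diabetes,E129,exact,1
diabetes,E130,exact,1
diabetes,E131,exact,1
diabetes,E136,exact,1
diabetes,E138,exact,1
diabetes,E139,exact,1
diabetes,E140,exact,1
diabetes,E141,exact,1
diabetes,E146,exact,1
diabetes,E148,exact,1
diabetes,E149,exact,1
diabetes_compl,E102,exact,2
diabetes_compl,E103,exact,2
diabetes_compl,E104,exact,2
diabetes_compl,E105,exact,2
diabetes_compl,E107,exact,2
diabetes_compl,E112,exact,2
diabetes_compl,E113,exact,2
diabetes_compl,E114,exact,2
diabetes_compl,E115,exact,2
diabetes_compl,E117,exact,2
diabetes_compl,E122,exact,2
diabetes_compl,E123,exact,2
diabetes_compl,E124,exact,2
diabetes_compl,E125,exact,2
diabetes_compl,E127,exact,2
diabetes_compl,E132,exact,2
diabetes_compl,E133,exact,2
diabetes_compl,E134,exact,2
diabetes_compl,E135,exact,2
diabetes_compl,E137,exact,2
diabetes_compl,E142,exact,2
diabetes_compl,E143,exact,2
diabetes_compl,E144,exact,2
diabetes_compl,E145,exact,2
diabetes_compl,E147,exact,2
paralysis,G81,prefix,2
paralysis,G82,prefix,2
paralysis,G041,exact,2
paralysis,G114,exact,2
paralysis,G801,exact,2
paralysis,G802,exact,2
paralysis,G830,exact,2
paralysis,G831,exact,2
paralysis,G832,exact,2
paralysis,G833,exact,2
paralysis,G834,exact,2
paralysis,G839,exact,2
renal,N18,prefix,2
renal,N19,prefix,2
renal,I120,exact,2
renal,I131,exact,2
renal,N032,exact,2
renal,N033,exact,2
renal,N034,exact,2
renal,N035,exact,2
renal,N036,exact,2
renal,N037,exact,2
renal,N052,exact,2
renal,N053,exact,2
renal,N054,exact,2
renal,N055,exact,2
renal,N056,exact,2
renal,N057,exact,2
renal,N250,exact,2
renal,Z490,exact,2
renal,Z491,exact,2
renal,Z492,exact,2
renal,Z940,exact,2
renal,Z992,exact,2
malignancy,C00,prefix,2
malignancy,C01,prefix,2
malignancy,C02,prefix,2
malignancy,C03,prefix,2
malignancy,C04,prefix,2
malignancy,C05,prefix,2
malignancy,C06,prefix,2
malignancy,C07,prefix,2
malignancy,C08,prefix,2
malignancy,C09,prefix,2
malignancy,C10,prefix,2
malignancy,C11,prefix,2
malignancy,C12,prefix,2
malignancy,C13,prefix,2
malignancy,C14,prefix,2
malignancy,C15,prefix,2
malignancy,C16,prefix,2
malignancy,C17,prefix,2
malignancy,C18,prefix,2
malignancy,C19,prefix,2
malignancy,C20,prefix,2
malignancy,C21,prefix,2
malignancy,C22,prefix,2
malignancy,C23,prefix,2
malignancy,C24,prefix,2
malignancy,C25,prefix,2
malignancy,C26,prefix,2
malignancy,C30,prefix,2
malignancy,C31,prefix,2
malignancy,C32,prefix,2
malignancy,C33,prefix,2
malignancy,C34,prefix,2
malignancy,C37,prefix,2
malignancy,C38,prefix,2
malignancy,C39,prefix,2
malignancy,C40,prefix,2
malignancy,C41,prefix,2
malignancy,C43,prefix,2
malignancy,C45,prefix,2
malignancy,C46,prefix,2
malignancy,C47,prefix,2
malignancy,C48,prefix,2
malignancy,C49,prefix,2
malignancy,C50,prefix,2
malignancy,C51,prefix,2
malignancy,C52,prefix,2
malignancy,C53,prefix,2
malignancy,C54,prefix,2
malignancy,C55,prefix,2
malignancy,C56,prefix,2
malignancy,C57,prefix,2
malignancy,C58,prefix,2
malignancy,C60,prefix,2
malignancy,C61,prefix,2
malignancy,C62,prefix,2
malignancy,C63,prefix,2
malignancy,C64,prefix,2
malignancy,C65,prefix,2
malignancy,C66,prefix,2
malignancy,C67,prefix,2
malignancy,C68,prefix,2
malignancy,C69,prefix,2
malignancy,C70,prefix,2
malignancy,C71,prefix,2
malignancy,C72,prefix,2
malignancy,C73,prefix,2
malignancy,C74,prefix,2
malignancy,C75,prefix,2
malignancy,C76,prefix,2
malignancy,C81,prefix,2
malignancy,C82,prefix,2
malignancy,C83,prefix,2
malignancy,C84,prefix,2
malignancy,C85,prefix,2
malignancy,C88,prefix,2
malignancy,C90,prefix,2
malignancy,C91,prefix,2
malignancy,C92,prefix,2
malignancy,C93,prefix,2
malignancy,C94,prefix,2
malignancy,C95,prefix,2
malignancy,C96,prefix,2
malignancy,C97,prefix,2
severe_liver,I850,exact,3
severe_liver,I859,exact,3
severe_liver,I864,exact,3
severe_liver,I982,exact,3
severe_liver,K704,exact,3
severe_liver,K711,exact,3
severe_liver,K721,exact,3
severe_liver,K729,exact,3
severe_liver,K765,exact,3
severe_liver,K766,exact,3
severe_liver,K767,exact,3
metastatic,C77,prefix,6
metastatic,C78,prefix,6
metastatic,C79,prefix,6
metastatic,C80,prefix,6
hiv,B20,prefix,6
hiv,B21,prefix,6
hiv,B22,prefix,6
hiv,B24,prefix,6
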