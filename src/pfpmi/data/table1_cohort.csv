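sample_id,sex,age_years,pmi_hours,cause_of_death
1,F,31,16,Haemorrhagic shock
2,M,20,20,Mechanical asphyxia (hanging)
3,M,35,25,Acute cardiac failure
4,M,21,32,Epidural hematoma
5,M,87,33,Subdural hematoma
6,F,52,33.5,Cardiogenic shock (myocardial infarction)
7,M,68,38,Haemorrhagic/traumatic shock
8,M,63,39,Mechanical asphyxia (positional)
9,F,81,41,Acute cardiac failure
10,M,32,46,Drug intoxication (cocaine)
11,M,38,46,Mechanical asphyxia (hanging)
12,F,60,62,Pulmonary embolism and cerebellar ischemia
13,M,42,63,Cerebral ischemia
14,M,37,66,Haemorrhagic shock
15,M,49,70.3,Mechanical asphyxia (ab ingestis)
16,F,39,77,Multiorgan failure
17,M,28,82,"Drug intoxication (cocaine, heroin)"
18,M,58,86,Acute bowel infarction
19,M,32,92,Hypoxic brain death
20,M,81,100,Haemorrhagic shock
21,F,77,120,Neoplastic cachexia
22,M,42,160,Drug intoxication (buprenorphine)
23,F,69,168,Neoplastic cachexia
24,M,80,170,Acute cardiac failure
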