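factor,level,count,exhaustive
age,40–49 years,51,true
age,50–59 years,69,true
age,60–69 years,55,true
age,70–79 years,17,true
age,≥80 years,8,true
gender,Male,105,true
gender,Female,95,true
education,Illiterate,5,true
education,Literate,195,true
comorbidity,Diabetes Mellitus,93,false
comorbidity,Hypertension,41,false
comorbidity,Asthma,4,false
comorbidity,CVD,2,false
comorbidity,Cataract,22,false
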