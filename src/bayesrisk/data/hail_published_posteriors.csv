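level,posterior,units
40–49 years,8.42,percent
50–59 years,22.78,percent
60–69 years,43.38,percent
70–79 years,35.52,percent
≥80 years,37.33,percent
Male,5.09,percent
Female,6.3,percent
Illiterate,22.58,percent
Literate,5.49,percent
Diabetes Mellitus,16.1,percent
Hypertension,4.59,percent
Asthma,2.77,percent
CVD,1.02,percent
Cataract,15.4,percent
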