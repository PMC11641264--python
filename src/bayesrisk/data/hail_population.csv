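level,proportion,units
40–49 years,16.95,percent
50–59 years,8.48,percent
60–69 years,3.55,percent
70–79 years,1.34,percent
≥80 years,0.6,percent
Male,57.78,percent
Female,42.22,percent
Illiterate,0.62,percent
Literate,99.38,percent
Diabetes Mellitus,16.17,percent
Hypertension,25,percent
Asthma,4.05,percent
CVD,5.5,percent
Cataract,4,percent
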