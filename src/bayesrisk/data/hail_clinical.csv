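factor,level,count,exhaustive
symptom,Blurry vision,20,false
symptom,Decreased vision,51,false
symptom,Headache/Pain,15,false
diagnostic_context,Developed during follow-up,54,false
diagnostic_context,Diagnosed in routine checkup,10,false
diagnostic_context,Other/NA,40,false
glaucoma_type,Primary,198,true
glaucoma_type,Secondary,2,true
duration,Newly diagnosed,144,true
duration,≤1 year,4,true
duration,2–5 year,12,true
duration,6–9 year,29,true
duration,≥10 year,11,true
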