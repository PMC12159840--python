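radiohapten,pretargeting_interval_h,tissue,dose_cGy_per_MBq,ti_published
ABD,24,tumor,32.88,
ABD,24,blood,2.14,15
ABD,24,heart,1.39,24
ABD,24,lungs,2.44,13
ABD,24,normal liver,3.14,10
ABD,24,spleen,2.28,14
ABD,24,stomach,0.49,67
ABD,24,small intestine,0.74,45
ABD,24,large intestine,2.14,15
ABD,24,kidneys,6.94,5
ABD,24,muscle,0.49,68
ABD,24,bone,2.42,14
ABD,24,ovaries,2.38,14
ABD,24,uterus,4.05,8
ABD,48,tumor,11.82,
ABD,48,blood,1.54,8
ABD,48,heart,0.65,18
ABD,48,lungs,1.00,12
ABD,48,normal liver,1.36,9
ABD,48,spleen,1.04,11
ABD,48,stomach,0.28,42
ABD,48,small intestine,1.08,11
ABD,48,large intestine,1.33,9
ABD,48,kidneys,6.80,2
ABD,48,muscle,0.19,62
ABD,48,bone,0.22,53
ABD,48,ovaries,1.03,11
ABD,48,uterus,1.78,7
Gemini,24,tumor,125.43,
Gemini,24,blood,3.50,36
Gemini,24,heart,3.76,33
Gemini,24,lungs,5.53,23
Gemini,24,normal liver,7.68,16
Gemini,24,spleen,6.24,20
Gemini,24,stomach,2.00,63
Gemini,24,small intestine,2.16,58
Gemini,24,large intestine,4.20,30
Gemini,24,kidneys,13.52,9
Gemini,24,muscle,1.00,125
Gemini,24,bone,1.61,78
Gemini,24,ovaries,6.83,18
Gemini,24,uterus,10.27,12
Gemini,48,tumor,119.88,
Gemini,48,blood,2.40,50
Gemini,48,heart,3.58,34
Gemini,48,lungs,8.87,14
Gemini,48,normal liver,5.85,20
Gemini,48,spleen,5.31,23
Gemini,48,stomach,0.81,147
Gemini,48,small intestine,1.36,88
Gemini,48,large intestine,1.72,70
Gemini,48,kidneys,13.23,9
Gemini,48,muscle,0.70,171
Gemini,48,bone,0.84,143
Gemini,48,ovaries,3.66,33
Gemini,48,uterus,6.21,19
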