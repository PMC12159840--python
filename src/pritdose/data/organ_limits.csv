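tissue,limit_Gy,kind,note
kidneys,23,hard-limit,lower edge of accepted 23-26 Gy radiopharmaceutical-therapy kidney limit
bone marrow,2.5,threshold,classical marrow toxicity threshold for radionuclide therapy
ovaries,4,threshold,human ovarian follicle LD50
uterus,4,threshold,uterine dose below which pregnancy function is not impaired
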