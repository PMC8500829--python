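# synthetic fixture disease gazetteer (term, tag, code, vocab)
Diabetes Mellitus Tipo 1	Disease	E10	ICD-10
Diabetes Mellitus Tipo 2	Disease	E11	ICD-10
Hipertensión Arterial	Disease	I10	ICD-10
Obesidad	Disease	E66	ICD-10
Insuficiencia Renal Crónica	Disease	N18	ICD-10
Retinopatía Diabética	Disease	H36	ICD-10
Neuropatía Diabética	Disease	G63.2	ICD-10
Pie Diabético	Disease	E11.5	ICD-10
Dislipidemia	Disease	E78	ICD-10
Hipotiroidismo	Disease	E03	ICD-10
Gastritis	Disease	K29	ICD-10
Infección de Vías Urinarias	Disease	N39.0	ICD-10
Hipoglucemia	Disease	E16.2	ICD-10
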