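# synthetic fixture symptom gazetteer (term, tag, code, vocab)
Poliuria	Symptom	28442001	SNOMED-CT
Polidipsia	Symptom	17173007	SNOMED-CT
Polifagia	Symptom	72405004	SNOMED-CT
Fatiga	Symptom	84229001	SNOMED-CT
Visión Borrosa	Symptom	246636008	SNOMED-CT
Cefalea	Symptom	25064002	SNOMED-CT
Mareo	Symptom	404640003	SNOMED-CT
Náusea	Symptom	422587007	SNOMED-CT
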