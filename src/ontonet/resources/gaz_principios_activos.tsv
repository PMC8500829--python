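# synthetic fixture active-pharmaceutical-ingredient gazetteer (term, tag, code, vocab)
Metformina	API	A10BA02	ATC
Insulina Glargina	API	A10AE04	ATC
Insulina Lispro	API	A10AB04	ATC
Glibenclamida	API	A10BB01	ATC
Glimepirida	API	A10BB12	ATC
Diosmina	API	C05CA03	ATC
Diosmina con Hesperidina	API	C05CA53	ATC
Losartán	API	C09CA01	ATC
Captopril	API	C09AA01	ATC
Enalapril	API	C09AA02	ATC
Atorvastatina	API	C10AA05	ATC
Bezafibrato	API	C10AB02	ATC
Ácido Acetilsalicílico	API	B01AC06	ATC
Omeprazol	API	A02BC01	ATC
Paracetamol	API	N02BE01	ATC
Hidroclorotiazida	API	C03AA03	ATC
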