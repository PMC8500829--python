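# synthetic fixture clinical-sign gazetteer (term, tag, code, vocab)
Glucosa	Sign		SIGNOS
Peso	Sign		SIGNOS
Talla	Sign		SIGNOS
Temperatura	Sign		SIGNOS
Frecuencia Cardiaca	Sign		SIGNOS
Frecuencia Respiratoria	Sign		SIGNOS
Cintura	Sign		SIGNOS
Cadera	Sign		SIGNOS
Presión Arterial	Sign		SIGNOS
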