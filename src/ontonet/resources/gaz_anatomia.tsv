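# synthetic fixture anatomy gazetteer (term, tag, code, vocab)
Riñón	Anatomy		ANATOMIA
Ojo	Anatomy		ANATOMIA
Retina	Anatomy		ANATOMIA
Pie	Anatomy		ANATOMIA
Hígado	Anatomy		ANATOMIA
Páncreas	Anatomy		ANATOMIA
Corazón	Anatomy		ANATOMIA
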