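# Gene-phenotype association flags (disease-database annotations supplied as
# an opaque input): hypertension, neurodegenerative, mental_disorders.
gene	flags
Pla2r1	mental_disorders
Yars	neurodegenerative
Csnk1e	neurodegenerative;mental_disorders
Zmym6	neurodegenerative
Trappc9	mental_disorders
Ephx1	hypertension;neurodegenerative;mental_disorders
Nqo2	neurodegenerative;mental_disorders
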