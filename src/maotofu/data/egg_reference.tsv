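code	mg_per_g_protein
Ile	54
Leu	86
Lys	70
Met+Cys	57
Phe+Tyr	93
Thr	47
Val	66
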