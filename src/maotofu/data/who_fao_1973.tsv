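code	mg_per_g_protein
Ile	40
Leu	70
Lys	55
Met+Cys	35
Phe+Tyr	60
Thr	40
Val	50
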