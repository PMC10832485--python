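code	threshold_mg_per_100g	taste_class
Asp	100	umami
Glu	30	umami
Ala	60	sweet
Gly	130	sweet
Ser	150	sweet
Thr	260	sweet
Pro	300	sweet
Arg	50	bitter
His	20	bitter
Ile	90	bitter
Leu	190	bitter
Lys	50	bitter
Met	30	bitter
Phe	90	bitter
Val	40	bitter
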