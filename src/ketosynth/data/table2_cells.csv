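species,KD_ln_mr,KD_sd,KDplus_ln_mr,KDplus_sd,CR_ln_mr,CR_sd,CRplus_ln_mr,CRplus_sd
Humans,0.3436,0.2842,0.2311,0.1972,,,0.5596,0.1532
Athymic mice,-0.0186,0.3529,0.1345,0.0305,0.3563,0.0376,,
C57BL mice,0.2261,0.0956,0.576,0.0961,0.5415,0.3219,,
SCID mice,0.6325,0.5048,,,0.3556,0.0501,,
Fisher rats,0.0117,0.3228,,,,,,
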