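pGUB_synth	95	96	dyad_1
pGUB_synth	285	286	dyad_2
nuc601_synth	95	96	dyad_1
nuc601_synth	285	286	dyad_2
fiveS_rDNA_A_synth	95	96	dyad_1
fiveS_rDNA_A_synth	285	286	dyad_2
fiveS_rDNA_B_synth	95	96	dyad_1
fiveS_rDNA_B_synth	285	286	dyad_2
chickenBG_synth	95	96	dyad_1
chickenBG_synth	285	286	dyad_2
mmtvA_synth	95	96	dyad_1
mmtvA_synth	285	286	dyad_2
litAFN_synth	95	96	dyad_1
litAFN_synth	285	286	dyad_2
seaUrchin5S_synth	95	96	dyad_1
seaUrchin5S_synth	285	286	dyad_2
promoterX_synth	95	96	dyad_1
promoterX_synth	285	286	dyad_2
telomericY_synth	95	96	dyad_1
telomericY_synth	285	286	dyad_2
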