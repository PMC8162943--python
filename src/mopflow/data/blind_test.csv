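# Reference blind-test set: 13 analytes evaluated prospectively against MOP.
# Transcribed published values: experimental outcome (Yes = diagnostic adduct
# formed), ensemble vote fractions (percent) for branching-ratio cutoffs
# 20-70% at fingerprint radius 1, DFT proton affinities (kcal/mol),
# pa_above_reagent = PA > 214.42 (the calculated MOP proton affinity), and
# novel_nitro = carries a nitro group absent from the 36-analyte training set
# (the scope of the hybrid PA verification filter).
id,outcome,p20,p30,p40,p50,p60,p70,proton_affinity,pa_above_reagent,novel_nitro
1,Yes,51,54,50,47,100,100,214.43,1,0
2,No,0,8,0,0,0,0,225.23,1,0
3,No,0,8,0,0,33,0,229.51,1,0
4,No,0,0,0,0,0,0,188.57,0,0
5,No,59,58,50,44,4,0,222.71,1,0
6,No,0,0,0,0,33,0,195.01,0,0
7,Yes,100,100,100,94,100,100,224.15,1,0
8,No,0,0,0,0,33,0,214.36,0,0
9,No,100,100,100,100,100,100,213.07,0,1
10,Yes,100,100,100,100,61,100,228.46,1,0
11,No,100,100,100,94,100,100,205.64,0,1
12,Yes,100,100,100,88,100,100,226.38,1,0
13,Yes,100,100,100,100,100,100,232.58,1,0
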