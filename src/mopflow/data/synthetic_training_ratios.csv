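# SYNTHETIC stand-in for the 36-analyte MOP training table, whose full
# structure/ratio listing is not redistributed here.  Constructed to satisfy
# every published distributional fact about that table: 36 analytes; largest
# branching-ratio gap spanning 65-83; second-largest gap just below 40;
# 8 analytes at or above the 70% cutoff (identically labeled at 80%);
# 13 at or above 40%; the named 40-70% compounds (TEMPO, DMPO, methyl phenyl
# sulfoxide, (ethenesulfinyl)benzene) in that band; tetrahydrothiophene
# 1-oxide the one sulfoxide below 40%; sulfones, alcohols and amines all
# unreactive.  Individual ratios and most structures are invented.
smiles,branching_ratio,name
CS(C)=O,100,dimethyl sulfoxide
CCS(C)=O,98,ethyl methyl sulfoxide
CCS(CC)=O,95,diethyl sulfoxide
CCCS(C)=O,92,methyl propyl sulfoxide
O=S1CCCCC1,90,tetrahydrothiopyran 1-oxide
[O-][n+]1ccccc1,88,pyridine N-oxide
C[N+](C)(C)[O-],85,trimethylamine N-oxide
Cc1cccc[n+]1[O-],83,2-methylpyridine N-oxide
CC1(C)CCC=[N+]1[O-],65,"5,5-dimethyl-1-pyrroline N-oxide"
C=CS(=O)c1ccccc1,58,(ethenesulfinyl)benzene
CS(=O)c1ccccc1,52,methyl phenyl sulfoxide
CC1(C)CCCC(C)(C)N1[O],45,TEMPO
O=S(c1ccccc1)c1ccccc1,40,diphenyl sulfoxide
O=S1CCCC1,25,tetrahydrothiophene 1-oxide
CS(=O)(=O)c1ccccc1,23,methyl phenyl sulfone
CC#N,21,acetonitrile
COc1ccccc1,20,anisole
Cc1ccccc1,18,toluene
CC(=O)Nc1ccccc1,16,acetanilide
CC(=O)N(C)C,15,"N,N-dimethylacetamide"
CC(=O)OCC,14,ethyl acetate
O=C1CCCCC1,13,cyclohexanone
CCC(C)=O,12,butan-2-one
CC(C)=O,11,acetone
C1CCOC1,10,tetrahydrofuran
CCOCC,9,diethyl ether
c1ccncc1,8,pyridine
CCCN,6,propylamine
CCN,5,ethylamine
OCc1ccccc1,4,benzyl alcohol
CC(C)O,3,propan-2-ol
CCCO,2,propan-1-ol
CCO,1,ethanol
O=S1(=O)CCCC1,0,sulfolane
CCS(C)(=O)=O,0,ethyl methyl sulfone
CS(C)(=O)=O,0,dimethyl sulfone
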