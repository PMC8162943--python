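# Compounds named in the reference study, with best-effort SMILES.
# role: train = member of the 36-analyte training set; test = among the 13
# blind-test analytes (the two nitro compounds map to test rows 9 and 11).
name,smiles,role
TEMPO,CC1(C)CCCC(C)(C)N1[O],train
"5,5-dimethyl-1-pyrroline N-oxide",CC1(C)CCC=[N+]1[O-],train
methyl phenyl sulfoxide,CS(=O)c1ccccc1,train
(ethenesulfinyl)benzene,C=CS(=O)c1ccccc1,train
tetrahydrothiophene 1-oxide,O=S1CCCC1,train
4-nitropyridine N-oxide,O=[N+]([O-])c1cc[n+]([O-])cc1,test
4-nitroquinoline N-oxide,O=[N+]([O-])c1cc[n+]([O-])c2ccccc12,test
"3,5-diiodo-4-pyridone-1-acetic acid",O=C(O)Cn1cc(I)c(=O)c(I)c1,test
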