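molecule_id,parent_id,endpoint,value
HHCB,,1A52,1.93
HHCB,,1A28,1.958
HHCB,,LC50,0.032
HHCB,,4ZRY,120.398
HHCB,,OR5AN1,111.766
D7,HHCB,1A52,1.883
D7,HHCB,1A28,1.962
D7,HHCB,LC50,8.387
D7,HHCB,4ZRY,116.022
D7,HHCB,OR5AN1,116.639
D8,HHCB,1A52,1.858
D8,HHCB,1A28,1.962
D8,HHCB,LC50,2.54
D8,HHCB,4ZRY,108.7
D8,HHCB,OR5AN1,101.292
D37,HHCB,1A52,1.869
D37,HHCB,1A28,1.934
D37,HHCB,LC50,0.154
D37,HHCB,4ZRY,113.439
D37,HHCB,OR5AN1,119.79
MK,,1A52,1.719
MK,,1A28,1.855
MK,,LC50,0.242
MK,,4ZRY,114.902
MK,,OR5AN1,105.461
D50,MK,1A52,1.751
D50,MK,1A28,1.833
D50,MK,LC50,0.198
D50,MK,4ZRY,109.97
D50,MK,OR5AN1,114.814
D51,MK,1A52,1.826
D51,MK,1A28,1.804
D51,MK,LC50,1.477
D51,MK,4ZRY,99.259
D51,MK,OR5AN1,108.348
D52,MK,1A52,1.687
D52,MK,1A28,1.839
D52,MK,LC50,6.214
D52,MK,4ZRY,119.211
D52,MK,OR5AN1,116.82
PHAN,,1A52,1.903
PHAN,,1A28,1.951
PHAN,,LC50,0.069
PHAN,,4ZRY,89.31
PHAN,,OR5AN1,139.604
D25,PHAN,1A52,1.917
D25,PHAN,1A28,1.95
D25,PHAN,LC50,0.582
D25,PHAN,4ZRY,73.57
D25,PHAN,OR5AN1,150.283
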