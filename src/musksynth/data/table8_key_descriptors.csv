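molecule_id,group,energy_gap,qh_plus,dipole_moment,e_homo
D7,synthesizable,0.174,0.173,2.279,-0.239
D8,synthesizable,0.164,0.178,5.101,-0.252
D25,synthesizable,0.184,0.184,2.594,-0.241
D37,synthesizable,0.222,0.162,2.827,-0.226
D50,synthesizable,0.178,0.213,1.192,-0.284
D51,synthesizable,0.173,0.213,3.018,-0.281
D52,synthesizable,0.161,0.21,4.471,-0.279
D39,non_synthesizable,0.168,0.41,2.679,-0.241
D49,non_synthesizable,0.222,0.394,2.892,-0.215
D57,non_synthesizable,0.178,0.221,4.548,-0.311
D61,non_synthesizable,0.158,0.431,4.313,-0.294
D62,non_synthesizable,0.16,0.217,5.726,-0.283
D67,non_synthesizable,0.139,0.415,5.915,-0.279
D76,non_synthesizable,0.16,0.222,5.055,-0.288
PHAN,positive,0.186,0.175,3.458,-0.232
ABDI,positive,0.184,0.181,3.213,-0.231
AHTN,positive,0.187,0.181,3.457,-0.233
HHCB,positive,0.22,0.164,1.551,-0.221
VER,positive,0.19,0.183,3.04,-0.234
MA,positive,0.162,0.212,4.276,-0.258
MC,positive,0.229,0.185,2.161,-0.241
MK,positive,0.173,0.193,3.034,-0.267
MMP,positive,0.169,0.195,1.542,-0.169
MUSCONE,positive,0.175,0.206,4.471,-0.269
MX,positive,0.178,0.213,1.192,-0.284
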