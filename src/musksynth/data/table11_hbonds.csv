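molecule_id,donor,hydrogen,acceptor,length_angstrom,rho_bcp_au,ehb_kcalmol,printed_strength
D7,C3,H23,O13,2.46,0.009,-1.237,very_weak
D8,C16,H29,O15,2.22,0.017,-3.13,weak_to_medium
D50,C10,H28,O17,2.22,0.015,-2.704,weak_to_medium
D50,C1,H24,O20,2.21,0.014,-2.336,very_weak
D50,C12,H36,O17,2.42,0.008,-1.102,very_weak
D50,C12,H35,O14,2.42,0.008,-1.101,very_weak
D50,C11,H33,O14,2.22,0.015,-2.707,weak_to_medium
D51,C10,H30,O19,2.36,0.021,-4.039,weak_to_medium
D51,C13,H35,O22,2.7,0.012,-1.96,very_weak
D51,C10,H30,O18,2.3,0.011,-1.602,very_weak
D51,C1,H25,O21,2.82,0.012,-1.919,very_weak
D51,C9,H27,O16,2.73,0.013,-2.1,very_weak
D51,C8,H31,O16,2.54,0.006,-0.677,very_weak
D52,C10,H31,O20,2.31,0.013,-2.182,very_weak
D52,C9,H30,O20,2.43,0.008,-1.091,very_weak
D52,C14,H38,O17,2.49,0.016,-2.885,weak_to_medium
D52,C12,H34,O23,2.34,0.022,-4.127,weak_to_medium
D57,C10,H33,O18,2.18,0.014,-2.28,very_weak
D57,C10,H33,O19,2.48,0.015,-2.576,weak_to_medium
D57,C1,H28,O21,2.45,0.013,-2.105,very_weak
D57,C9,H29,O15,2.67,0.013,-2.167,very_weak
D57,C9,H29,O16,2.34,0.013,-2.128,very_weak
D76,C10,H33,O21,2.22,0.013,-2.049,very_weak
D76,C12,H36,O24,2.51,0.016,-2.781,weak_to_medium
D76,C9,H30,O19,2.27,0.013,-2.2,very_weak
D76,C1,H28,O13,2.19,0.014,-2.485,very_weak
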