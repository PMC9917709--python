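molecule_id,synthesizability
D1,0.32
D2,0.47
D3,0.42
D4,0.30
D5,0.47
D6,0.63
D7,0.77
D8,0.61
D9,0.14
D10,0.49
D11,0.29
D12,0.36
D13,0.30
D14,0.13
D15,0.32
D16,0.17
D17,0.02
D18,0.14
D19,0.25
D20,0.11
D21,0.19
D22,0.34
D23,0.26
D24,0.18
D25,0.61
D26,0.06
D27,0.30
D28,0.44
D29,0.49
D30,0.05
D31,0.26
D32,0.50
D33,0.49
D34,0.49
D35,0.57
D36,0.13
D37,0.57
D38,0.25
D39,0.05
D40,0.10
D41,0.10
D42,0.15
D43,0.26
D44,0.13
D45,0.05
D46,0.11
D47,0.25
D48,0.20
D49,0.08
D50,0.70
D51,0.51
D52,0.50
D53,0.08
D54,0.31
D55,0.09
D56,0.20
D57,0.06
D58,0.06
D59,0.47
D60,0.29
D61,0.06
D62,0.04
D63,0.16
D64,0.14
D65,0.07
D66,0.15
D67,0.03
D68,0.11
D69,0.07
D70,0.34
D71,0.05
D72,0.03
D73,0.06
D74,0.05
D75,0.09
D76,0.06
D77,0.22
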