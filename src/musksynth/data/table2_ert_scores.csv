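molecule_id,synthesizability
D1,0.37
D2,0.37
D3,0.48
D4,0.51
D5,0.49
D6,0.44
D7,0.65
D8,0.58
D9,0.19
D10,0.59
D11,0.36
D12,0.37
D13,0.35
D14,0.23
D15,0.37
D16,0.37
D17,0.27
D18,0.24
D19,0.32
D20,0.22
D21,0.35
D22,0.52
D23,0.50
D24,0.28
D25,0.50
D26,0.25
D27,0.38
D28,0.52
D29,0.47
D30,0.19
D31,0.25
D32,0.42
D33,0.71
D34,0.52
D35,0.48
D36,0.29
D37,0.56
D38,0.42
D39,0.15
D40,0.22
D41,0.25
D42,0.30
D43,0.36
D44,0.32
D45,0.23
D46,0.27
D47,0.32
D48,0.31
D49,0.21
D50,0.79
D51,0.60
D52,0.56
D53,0.44
D54,0.44
D55,0.40
D56,0.54
D57,0.26
D58,0.34
D59,0.46
D60,0.40
D61,0.16
D62,0.24
D63,0.50
D64,0.37
D65,0.22
D66,0.28
D67,0.14
D68,0.31
D69,0.31
D70,0.45
D71,0.29
D72,0.14
D73,0.29
D74,0.29
D75,0.28
D76,0.27
D77,0.33
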