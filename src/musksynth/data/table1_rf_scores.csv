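molecule_id,synthesizability
D1,0.33
D2,0.41
D3,0.52
D4,0.46
D5,0.51
D6,0.49
D7,0.65
D8,0.61
D9,0.27
D10,0.45
D11,0.46
D12,0.43
D13,0.42
D14,0.26
D15,0.48
D16,0.42
D17,0.21
D18,0.29
D19,0.35
D20,0.30
D21,0.36
D22,0.57
D23,0.44
D24,0.45
D25,0.63
D26,0.37
D27,0.47
D28,0.55
D29,0.43
D30,0.36
D31,0.42
D32,0.43
D33,0.57
D34,0.50
D35,0.55
D36,0.38
D37,0.62
D38,0.55
D39,0.25
D40,0.27
D41,0.35
D42,0.33
D43,0.39
D44,0.36
D45,0.34
D46,0.38
D47,0.45
D48,0.37
D49,0.25
D50,0.62
D51,0.57
D52,0.50
D53,0.32
D54,0.39
D55,0.34
D56,0.46
D57,0.25
D58,0.31
D59,0.49
D60,0.50
D61,0.23
D62,0.21
D63,0.45
D64,0.36
D65,0.33
D66,0.41
D67,0.20
D68,0.25
D69,0.40
D70,0.48
D71,0.31
D72,0.23
D73,0.33
D74,0.30
D75,0.24
D76,0.29
D77,0.43
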