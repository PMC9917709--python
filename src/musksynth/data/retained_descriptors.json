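[
 "qH_plus",
 "E_HOMO",
 "EG",
 "DM",
 "Q_YY",
 "Q_ZZ",
 "Q_XY",
 "Q_XZ",
 "Q_YZ",
 "Freq",
 "Raman",
 "GE",
 "AATSC8c",
 "GATS5c",
 "GATS6c",
 "GATS3s"
]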