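{
 "rf": {
  "intercept": 0.64848,
  "coefficients": {
   "Raman": 0.00114,
   "EG": -0.61591,
   "qH_plus": -0.57966,
   "DM": -0.02471,
   "Freq": 8e-05,
   "Q_YY": -0.00701,
   "E_HOMO": 0.54305,
   "Q_XY": -0.00033,
   "AATSC8c": -7.8103
  }
 },
 "ert": {
  "intercept": 0.76458,
  "coefficients": {
   "Raman": 0.00133,
   "EG": -0.82302,
   "qH_plus": -0.98987,
   "DM": -0.04021,
   "Freq": 0.00014,
   "Q_YY": -0.01438,
   "E_HOMO": 0.49688,
   "Q_XY": -0.00017,
   "AATSC8c": -17.60495
  }
 },
 "gbc": {
  "intercept": 0.75092,
  "coefficients": {
   "Raman": 0.0017,
   "EG": -0.87826,
   "qH_plus": -1.19493,
   "DM": -0.04326,
   "Freq": 0.00015,
   "Q_YY": -0.01299,
   "E_HOMO": 0.82854,
   "Q_XY": -0.00036,
   "AATSC8c": -10.28994
  }
 }
}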