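# Blood-side reference values for the packaged 70-kg human physiology.
# Volumes are L per kg body weight; V_E is consistent with Hct/(1-Hct)*V_P.
version: 1
V_P: 0.0436
V_E: 0.035673
Hct: 0.45
pH_P: 7.4
plasma:
  f_NL: 0.0023
  f_NP: 0.0013
blood_cell:
  f_IW: 0.603
  f_NL: 0.0017
  f_NP: 0.0029
  AP: 0.5
  pH: 7.22
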