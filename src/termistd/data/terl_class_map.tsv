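reference_name	packaging_class
Sf6	headful_pac
933W	headful_pac
T4	headful_pac
P22	headful_pac
lambda	cos_5
P2	cos_5
HK97	cos_3
T7	dtr
N4	dtr
Mu	mu_like
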