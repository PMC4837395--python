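gene	p_value	direction
ABCC3	0.036	down
AKAP12	0.080	up
ANPEP	0.090	up
ANTXR1	0.039	up
BTG2	0.089	down
CAPN2	0.032	up
CAV2	0.047	up
CLIP4	0.071	up
CRLF1	0.004	down
CYBRD1	0.029	up
DKK3	0.076	up
MFI2	0.046	up
PHF10	0.070	down
PSAT1	0.010	up
PVR	0.038	up
TRHDE	0.094	up
TUSC3	0.027	up
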