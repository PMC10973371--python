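MYOM2	up
VEGFA	up
MUC1	up
IHH	up
GLI1	up
GRIA1	up
VCAM1	down
EGFR	down
GPC3	down
IGF2	down
GNG12	down
GNGT1	down
C3	down
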