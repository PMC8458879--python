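gene	coefficient
SLC30A1	0.65
RBM10	-0.84
PNPLA6	-0.27
DSG2	0.36
CHML	-0.21
DLGAP5	0.54
TTLL6	-0.02
PDE4DIPP5	-0.08
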