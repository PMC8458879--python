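# Watson-Crick RNA.RNA nearest-neighbor stacking free energies (kcal/mol,
# 37 C), Turner 2004 parameter set (10 unique WC/WC stacks expanded to all
# 16 top-strand dinucleotide steps by duplex symmetry). The step key is the
# 5'->3' dinucleotide on the target strand; both positions must be
# Watson-Crick paired for the stack to contribute.
step	delta_g
AA	-0.93
AC	-2.24
AG	-2.08
AU	-1.10
CA	-2.11
CC	-3.26
CG	-2.36
CU	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GU	-2.24
UA	-1.33
UC	-2.35
UG	-2.11
UU	-0.93
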