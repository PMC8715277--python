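# One-bead-per-nucleotide parameters for homopolymeric poly-U RNA
# (Regy-style HPS-compatible RNA bead).
# Columns: code  mass[g/mol]  charge[e]  sigma[nm]  lambda[0..1]
U	306.17	-1.0	0.820	0.320
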